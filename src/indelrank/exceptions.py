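"""Exception hierarchy shared across the package."""


class IndelRankError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IndelRankError):
    """A required resource (null distribution, network, config key) is missing or invalid."""


class InputError(IndelRankError, ValueError):
    """User-supplied data violates a precondition (non-finite score, malformed indel, ...)."""


class DegenerateNetworkError(IndelRankError):
    """A similarity network cannot be built (zero variance, empty edge list, isolated query)."""
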