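"""Empirical null distributions and the score -> p-value transform.

Every raw evidence score (functional predictor output, gene-level intolerance,
or random-walk association strength) is compared against an empirical null
collection for its source.  The p-value is the add-one-corrected proportion of
null points at least as damaging as the query,

    p = (#{i : s_i >= s} + 1) / (N + 1)

with ``>=`` replaced by ``<=`` for sources where *smaller* scores are more
damaging (SIFT, PinPor, RVIS).  The pseudo-count keeps p strictly positive so
that ``log p`` is finite downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, InputError

__all__ = [
    "Direction",
    "NullDistribution",
    "ScoredIndel",
    "Subtype",
    "empirical_pvalue",
    "pvalues_for_indel",
    "infer_subtype",
    "FUNCTIONAL_SOURCES",
    "INTOLERANCE_SOURCE",
    "ASSOCIATION_SOURCES",
    "PER_INDEL_SOURCES",
    "ALL_SOURCES",
    "DEFAULT_DIRECTIONS",
]


class Direction(str, enum.Enum):
    """Which tail of a score distribution is the damaging one."""

    LARGER = "larger_is_damaging"
    SMALLER = "smaller_is_damaging"


#: the five per-indel functional predictors consumed as raw scores
FUNCTIONAL_SOURCES: tuple[str, ...] = ("SIFT", "PinPor", "CADD", "DDIG", "VEST")
#: gene-level intolerance score (smaller = less tolerant)
INTOLERANCE_SOURCE: str = "RVIS"
#: the four disease-association evidence channels (one per gene network)
ASSOCIATION_SOURCES: tuple[str, ...] = ("gobp", "strg", "gexp", "tsfc")
#: sources whose raw scores travel with the indel record
PER_INDEL_SOURCES: tuple[str, ...] = FUNCTIONAL_SOURCES + (INTOLERANCE_SOURCE,)
#: all K = 10 evidence sources, in canonical order
ALL_SOURCES: tuple[str, ...] = PER_INDEL_SOURCES + ASSOCIATION_SOURCES

DEFAULT_DIRECTIONS: dict[str, Direction] = {
    "SIFT": Direction.SMALLER,
    "PinPor": Direction.SMALLER,
    "RVIS": Direction.SMALLER,
    "CADD": Direction.LARGER,
    "DDIG": Direction.LARGER,
    "VEST": Direction.LARGER,
    "gobp": Direction.LARGER,
    "strg": Direction.LARGER,
    "gexp": Direction.LARGER,
    "tsfc": Direction.LARGER,
}


class Subtype(str, enum.Enum):
    """Indel subtype: (non)frameshift x deletion/insertion."""

    ND = "ND"
    NI = "NI"
    FD = "FD"
    FI = "FI"


def infer_subtype(ref: str, alt: str) -> Subtype:
    """Classify an indel from its REF/ALT allele lengths."""
    delta = len(ref) - len(alt)
    if delta == 0:
        raise InputError(f"not an indel: len(ref) == len(alt) for {ref}>{alt}")
    deletion = delta > 0
    frameshift = abs(delta) % 3 != 0
    if deletion:
        return Subtype.FD if frameshift else Subtype.ND
    return Subtype.FI if frameshift else Subtype.NI


@dataclass(frozen=True)
class NullDistribution:
    """An empirical score collection for one source.

    Parameters
    ----------
    source
        Source label (e.g. ``"CADD"``).
    scores
        The null score collection, length N >= 1, all finite.
    direction
        Damaging direction of the source.
    """

    source: str
    scores: np.ndarray
    direction: Direction
    _sorted: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float).ravel()
        if arr.size == 0:
            raise ConfigurationError(f"empty null distribution for source {self.source!r}")
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError(f"non-finite scores in null distribution {self.source!r}")
        object.__setattr__(self, "scores", arr)
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "_sorted", np.sort(arr))

    def __len__(self) -> int:
        return int(self.scores.size)

    def pvalue(self, s: float) -> float:
        """Empirical p-value of one query score (add-one corrected)."""
        return float(self.pvalues(np.asarray([s]))[0])

    def pvalues(self, s: np.ndarray) -> np.ndarray:
        """Vectorized empirical p-values for an array of query scores."""
        s = np.asarray(s, dtype=float)
        if not np.all(np.isfinite(s)):
            raise InputError(f"non-finite query score(s) for source {self.source!r}")
        n = self._sorted.size
        if self.direction is Direction.LARGER:
            # count of null scores >= s (ties inclusive)
            count = n - np.searchsorted(self._sorted, s, side="left")
        else:
            count = np.searchsorted(self._sorted, s, side="right")
        return (count + 1.0) / (n + 1.0)


@dataclass
class ScoredIndel:
    """A candidate coding indel with a partially observed raw-score vector.

    ``raw_scores`` maps source name -> raw score; absent sources are simply
    absent (or ``NaN``, which is normalized to absent).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    subtype: Subtype | None = None
    raw_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"POS must be 1-based positive, got {self.pos}")
        inferred = infer_subtype(self.ref, self.alt)
        if self.subtype is None:
            self.subtype = inferred
        else:
            self.subtype = Subtype(self.subtype)
            if self.subtype is not inferred:
                raise InputError(
                    f"subtype {self.subtype.value} inconsistent with alleles "
                    f"{self.ref}>{self.alt} (expected {inferred.value})"
                )
        self.raw_scores = {
            k: float(v) for k, v in self.raw_scores.items() if v is not None and np.isfinite(v)
        }

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def empirical_pvalue(dist: NullDistribution, s: float) -> float:
    """p = (#{null at least as damaging as s} + 1) / (N + 1), in (0, 1]."""
    return dist.pvalue(s)


def pvalues_for_indel(
    indel: ScoredIndel, dists: Mapping[str, NullDistribution]
) -> dict[str, float]:
    """Transform every present raw score of ``indel`` into a p-value.

    Missing sources stay missing (absent from the result).  A present score
    with no registered null distribution is a configuration error.
    """
    out: dict[str, float] = {}
    for source, score in indel.raw_scores.items():
        if source not in dists:
            raise ConfigurationError(
                f"score for source {source!r} present but no null distribution registered"
            )
        out[source] = dists[source].pvalue(score)
    return out
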