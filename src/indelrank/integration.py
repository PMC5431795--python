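"""Combining up to K = 10 per-indel p-values into one integrated p-value.

The primary combiner is Fisher's method with a dependence correction in the
Brown/Kost style: the statistic ``U = sum_i -2 log p_i`` is referred to a
scaled chi-squared null whose scale and degrees of freedom are fitted by
moment matching,

    E[U] = 2K,   Var[U] = sum_ij cov(V_i, V_j),
    nu = 2 E[U]^2 / Var[U],   U * nu / E[U] ~ chi^2_nu,

with the pairwise covariances approximated from the correlation of
probit-transformed p-values via the quartic polynomial

    cov(V_i, V_j) ~= a1 r + a2 r^2 + a3 r^3 + a4 r^4,
    a1 = 3.263119, a2 = 0.709866, a3 = 0.026589, a4 = -0.709866/n,

where ``r`` is the (small-sample-adjusted) correlation of
``Z = Phi^{-1}(1 - p)`` across the candidate set and ``n`` the
pairwise-complete sample size.  Under independence the fit reduces exactly to
textbook Fisher (U ~ chi^2_{2K}).  Missing sources are dropped and the
degrees of freedom reduced accordingly.

Alternative combiners: minP (Sidak-corrected minimum), Stouffer's Z, and
robust rank aggregation (order-statistic binomial tails with a Bonferroni
factor K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .null_models import ALL_SOURCES

__all__ = [
    "KOST_COEFFICIENTS",
    "DependenceModel",
    "fit_dependence_model",
    "fisher_integrate",
    "minp_integrate",
    "stouffer_integrate",
    "rra_integrate",
    "integrate",
    "integrate_matrix",
    "INTEGRATION_METHODS",
]

#: quartic covariance approximation coefficients (a4 is -0.709866/n)
KOST_COEFFICIENTS = (3.263119, 0.709866, 0.026589)

#: probit clamp for p in {0, 1}
_P_CLAMP = 1e-15
#: guard against log(0) for p at the numerical floor
_LOG_FLOOR = 1e-300

INTEGRATION_METHODS = ("fisher_corrected", "fisher_plain", "minp", "stouffer", "rra")


def _present(pvalues: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    keys = [k for k, v in pvalues.items() if v is not None and np.isfinite(v)]
    vals = np.asarray([float(pvalues[k]) for k in keys])
    if ((vals <= 0) | (vals > 1)).any():
        raise InputError("p-values must lie in (0, 1]")
    return keys, vals


@dataclass
class DependenceModel:
    """Fitted inter-source dependence of probit-transformed p-values."""

    sources: list[str]
    rho_hat: pd.DataFrame
    rho_tilde: pd.DataFrame
    n_pairs: pd.DataFrame
    cov: pd.DataFrame  # cov(V_i, V_j); diagonal fixed at 4 = Var(-2 log p)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (source_i, source_j, rho_hat, rho_tilde, n) table."""
        rows = []
        for i, a in enumerate(self.sources):
            for b in self.sources[i + 1 :]:
                rows.append(
                    {
                        "source_i": a,
                        "source_j": b,
                        "rho_hat": self.rho_hat.loc[a, b],
                        "rho_tilde": self.rho_tilde.loc[a, b],
                        "n": self.n_pairs.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def fit_dependence_model(
    evidence: pd.DataFrame, min_pairs: int = 3
) -> DependenceModel:
    """Estimate the inter-source covariance of ``-2 log p`` across a candidate set.

    Parameters
    ----------
    evidence
        Indels x sources table of p-values with NaN for missing entries.
    min_pairs
        Source pairs observed together on fewer indels get covariance 0.
    """
    cols = [c for c in evidence.columns]
    P = evidence.to_numpy(dtype=float)
    Z = stats.norm.ppf(1.0 - np.clip(P, _P_CLAMP, 1.0 - _P_CLAMP))
    Z = pd.DataFrame(Z, columns=cols, index=evidence.index)
    mask = evidence.notna()
    n_pairs = mask.astype(float).T @ mask.astype(float)
    rho_hat = Z.corr(min_periods=min_pairs)
    thin = (n_pairs < min_pairs) & ~np.eye(len(cols), dtype=bool)
    if thin.to_numpy().any():
        warnings.warn(
            "source pair(s) with fewer than "
            f"{min_pairs} shared observations; covariance fixed to 0",
            stacklevel=2,
        )
    rho_hat = rho_hat.fillna(0.0).clip(-1.0, 1.0)
    n_eff = n_pairs.clip(lower=2.0)
    rho_tilde = rho_hat * (1.0 + (1.0 - rho_hat**2) / (2.0 * n_eff - 1.0))
    rho_tilde = rho_tilde.clip(-1.0, 1.0)
    a1, a2, a3 = KOST_COEFFICIENTS
    a4 = -0.709866 / n_eff
    cov = a1 * rho_tilde + a2 * rho_tilde**2 + a3 * rho_tilde**3 + a4 * rho_tilde**4
    cov = cov.where(~thin, 0.0)
    np.fill_diagonal(cov.to_numpy(), 4.0)
    cov_arr = cov.to_numpy()
    np.fill_diagonal(cov_arr, 4.0)
    cov = pd.DataFrame(cov_arr, index=cols, columns=cols)
    return DependenceModel(
        sources=list(cols), rho_hat=rho_hat, rho_tilde=rho_tilde, n_pairs=n_pairs, cov=cov
    )


def _scaled_chi2_sf(U: np.ndarray | float, var: np.ndarray | float, K: int) -> np.ndarray | float:
    """Upper tail of U under the moment-matched scaled chi-squared null."""
    E = 2.0 * K
    var = np.maximum(var, 0.1 * 4.0 * K)  # floor keeps nu finite with negative covs
    nu = 2.0 * E**2 / var
    c = var / (2.0 * E)  # U / c ~ chi^2_nu
    return stats.chi2.sf(np.asarray(U) / c, nu)


def fisher_integrate(
    pvalues: Mapping[str, float],
    model: DependenceModel | None = None,
    variant: str = "corrected",
) -> float:
    """Fisher combination with optional dependence correction.

    ``variant='corrected'`` (default) uses the Brown/Kost moment match from a
    fitted :class:`DependenceModel`; ``'plain'`` assumes independence;
    ``'literal'`` applies the as-published moment equations verbatim
    (eta = sum(cov)/K, nu = 2K/eta), kept for comparison.
    """
    keys, vals = _present(pvalues)
    K = len(keys)
    if K == 0:
        return float("nan")
    U = float(-2.0 * np.log(np.maximum(vals, _LOG_FLOOR)).sum())
    if variant == "plain" or model is None:
        return float(stats.chi2.sf(U, 2 * K))
    sub = model.cov.loc[keys, keys].to_numpy()
    total = float(sub.sum())
    if variant == "corrected":
        return float(_scaled_chi2_sf(U, total, K))
    if variant == "literal":
        eta = total / K
        nu = 2.0 * K / eta
        return float(stats.chi2.sf(U / eta, nu))
    raise InputError(f"unknown Fisher variant {variant!r}")


def minp_integrate(pvalues: Mapping[str, float], correct: bool = True) -> float:
    """Minimum-p combination.

    By default the minimum is Sidak-corrected, ``1 - (1 - p_min)^K``, so the
    result is itself a valid p-value; ``correct=False`` returns the raw
    minimum.  Both orderings coincide, so rankings are unaffected.
    """
    _, vals = _present(pvalues)
    if vals.size == 0:
        return float("nan")
    pmin = float(vals.min())
    if not correct:
        return pmin
    return float(-np.expm1(vals.size * np.log1p(-min(pmin, 1.0 - _P_CLAMP))))


def stouffer_integrate(pvalues: Mapping[str, float]) -> float:
    """Stouffer's Z: ``Z = sum Phi^{-1}(1 - p_i) / sqrt(K)``, p = 1 - Phi(Z)."""
    _, vals = _present(pvalues)
    if vals.size == 0:
        return float("nan")
    z = stats.norm.ppf(1.0 - np.clip(vals, _P_CLAMP, 1.0 - _P_CLAMP))
    Z = z.sum() / np.sqrt(vals.size)
    return float(stats.norm.sf(Z))


def rra_integrate(pvalues: Mapping[str, float]) -> float:
    """Robust rank aggregation over the order statistics of the p-values.

    For the sorted values p_(1) <= ... <= p_(K), the m-th binomial tail
    ``beta_m = P(Binomial(K, p_(m)) >= m)`` asks how surprising it is that m
    of K uniform draws fall at or below p_(m); the smallest tail is
    Bonferroni-corrected by K.
    """
    _, vals = _present(pvalues)
    K = vals.size
    if K == 0:
        return float("nan")
    p_sorted = np.sort(vals)
    m = np.arange(1, K + 1)
    beta = stats.binom.sf(m - 1, K, p_sorted)
    return float(min(K * beta.min(), 1.0))


def integrate(
    pvalues: Mapping[str, float],
    method: str = "fisher_corrected",
    model: DependenceModel | None = None,
) -> float:
    """Dispatch to one of the registered combination methods."""
    if method == "fisher_corrected":
        return fisher_integrate(pvalues, model, variant="corrected")
    if method == "fisher_plain":
        return fisher_integrate(pvalues, None, variant="plain")
    if method == "fisher_literal":
        return fisher_integrate(pvalues, model, variant="literal")
    if method == "minp":
        return minp_integrate(pvalues)
    if method == "stouffer":
        return stouffer_integrate(pvalues)
    if method == "rra":
        return rra_integrate(pvalues)
    raise InputError(f"unknown integration method {method!r}")


def integrate_matrix(
    P: np.ndarray,
    method: str,
    model: DependenceModel | None = None,
    sources: Sequence[str] | None = None,
) -> np.ndarray:
    """Vectorized integration of a fully observed replicate-by-source matrix.

    Used for calibration simulations; matches the scalar path row by row.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise InputError("P must be 2-D (replicates x sources)")
    n_rep, K = P.shape
    if sources is None:
        sources = list(ALL_SOURCES[:K]) if K <= len(ALL_SOURCES) else [str(i) for i in range(K)]
    if method in ("fisher_corrected", "fisher_plain", "fisher_literal"):
        U = -2.0 * np.log(np.maximum(P, _LOG_FLOOR)).sum(axis=1)
        if method == "fisher_plain" or model is None:
            return stats.chi2.sf(U, 2 * K)
        total = float(model.cov.loc[list(sources), list(sources)].to_numpy().sum())
        if method == "fisher_literal":
            eta = total / K
            return stats.chi2.sf(U / eta, 2.0 * K / eta)
        return np.asarray(_scaled_chi2_sf(U, total, K))
    if method == "minp":
        pmin = P.min(axis=1)
        return -np.expm1(K * np.log1p(-np.minimum(pmin, 1.0 - _P_CLAMP)))
    if method == "stouffer":
        z = stats.norm.ppf(1.0 - np.clip(P, _P_CLAMP, 1.0 - _P_CLAMP))
        return stats.norm.sf(z.sum(axis=1) / np.sqrt(K))
    if method == "rra":
        p_sorted = np.sort(P, axis=1)
        m = np.arange(1, K + 1)
        beta = stats.binom.sf(m - 1, K, p_sorted)
        return np.minimum(K * beta.min(axis=1), 1.0)
    raise InputError(f"unknown integration method {method!r}")
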