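"""Spike-in benchmark harness and ranking metrics (MRR, TOP, rank ROC).

A spike-in experiment inserts one known causal indel into a neutral control
set of the same subtype, prioritizes the union, and records the causal
indel's rank and rank ratio (rank divided by candidate-set size).  Within a
tie block the worst rank is reported, a conservative choice.  Aggregates:

* ``mrr`` -- mean rank ratio over causal indels (random guessing gives 50%);
* ``top_k`` -- number of causal indels ranked within the top k (default 20);
* ``rank_roc`` -- ROC curve obtained by thresholding rank ratios (inclusive),
  TPR over causal indels, FPR over neutral ones, AUC by trapezoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InputError
from .null_models import NullDistribution, ScoredIndel
from .prioritize import prioritize
from .rwr import AssociationScorer

__all__ = [
    "SpikeInResult",
    "run_spike_in",
    "run_spike_in_grouped",
    "mrr",
    "top_k",
    "rank_roc",
    "random_rank_ratios",
]


@dataclass
class SpikeInResult:
    """Per-causal-indel ranks from a batch of spike-in simulations."""

    records: pd.DataFrame  # causal_label, disease, rank, rank_ratio, set_size
    neutral_ratios: np.ndarray  # pooled rank ratios of the co-ranked neutral indels

    def summary(self, k: int = 20) -> dict[str, float]:
        ranks = self.records["rank"].to_numpy()
        ratios = self.records["rank_ratio"].to_numpy()
        out = {"MRR": mrr(ratios), "TOP": float(top_k(ranks, k=k)), "n_causal": float(len(ranks))}
        if self.neutral_ratios.size:
            _, _, out["AUC"] = rank_roc(ratios, self.neutral_ratios)
        return out


def run_spike_in(
    causal_set: Sequence[ScoredIndel],
    control_set: Sequence[ScoredIndel],
    disease_map: Mapping[str, str] | Sequence[str],
    nulls: Mapping[str, NullDistribution],
    assoc_scorers: Mapping[str, AssociationScorer],
    method: str = "fisher_corrected",
    mask_sources: Sequence[str] = (),
) -> SpikeInResult:
    """Spike each causal indel into the control set and record its rank.

    ``disease_map`` gives the query disease per causal indel (by label, or as
    a sequence parallel to ``causal_set``).  ``mask_sources`` hides the named
    raw-score sources from the causal indels before ranking, for
    missing-data robustness experiments.
    """
    if not causal_set:
        raise InputError("need at least one causal indel")
    subtypes = {c.subtype for c in causal_set} | {c.subtype for c in control_set}
    if len(subtypes) > 1:
        raise InputError(f"spike-in sets mix subtypes: {sorted(s.value for s in subtypes)}")
    if not isinstance(disease_map, Mapping):
        disease_map = {c.label: d for c, d in zip(causal_set, disease_map)}
    rows = []
    neutral_ratios: list[np.ndarray] = []
    for causal in causal_set:
        if mask_sources:
            causal = ScoredIndel(
                chrom=causal.chrom, pos=causal.pos, ref=causal.ref, alt=causal.alt,
                gene=causal.gene, subtype=causal.subtype,
                raw_scores={
                    k: v for k, v in causal.raw_scores.items() if k not in mask_sources
                },
            )
        disease = disease_map[causal.label]
        result = prioritize(
            list(control_set) + [causal], disease, nulls, assoc_scorers, method=method
        )
        M = result.n_candidates
        rank = result.pessimistic_rank(causal.label)
        rows.append(
            {
                "causal_label": causal.label,
                "disease": disease,
                "rank": rank,
                "rank_ratio": rank / M,
                "set_size": M,
            }
        )
        neutral = result.table[result.table["label"] != causal.label]
        neutral_ratios.append(neutral["rank_ratio"].to_numpy())
    return SpikeInResult(
        records=pd.DataFrame(rows),
        neutral_ratios=np.concatenate(neutral_ratios) if neutral_ratios else np.empty(0),
    )


def run_spike_in_grouped(
    causal_set: Sequence[ScoredIndel],
    control_set: Sequence[ScoredIndel],
    disease_map: Mapping[str, str] | Sequence[str],
    nulls: Mapping[str, NullDistribution],
    assoc_scorers: Mapping[str, AssociationScorer],
    method: str = "fisher_corrected",
    mask_sources: Sequence[str] = (),
) -> SpikeInResult:
    """Spike-in over mixed subtypes: each causal indel is ranked against the
    controls of its own subtype, and per-subtype results are pooled."""
    if not isinstance(disease_map, Mapping):
        disease_map = {c.label: d for c, d in zip(causal_set, disease_map)}
    frames, neutral = [], []
    for subtype in sorted({c.subtype for c in causal_set}, key=lambda s: s.value):
        causal = [c for c in causal_set if c.subtype is subtype]
        controls = [n for n in control_set if n.subtype is subtype]
        res = run_spike_in(
            causal, controls, disease_map, nulls, assoc_scorers,
            method=method, mask_sources=mask_sources,
        )
        frames.append(res.records)
        neutral.append(res.neutral_ratios)
    return SpikeInResult(
        records=pd.concat(frames, ignore_index=True),
        neutral_ratios=np.concatenate(neutral) if neutral else np.empty(0),
    )


def mrr(rank_ratios: Sequence[float]) -> float:
    """Mean rank ratio; 0.5 is chance level, smaller is better."""
    arr = np.asarray(rank_ratios, dtype=float)
    if arr.size == 0:
        raise InputError("no rank ratios to average")
    return float(arr.mean())


def top_k(ranks: Sequence[int], k: int = 20) -> int:
    """Number of causal indels ranked within the top k."""
    arr = np.asarray(ranks)
    if arr.size == 0:
        raise InputError("no ranks to count")
    return int((arr <= k).sum())


def rank_roc(
    causal_ratios: Sequence[float], neutral_ratios: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over rank-ratio thresholds (inclusive); returns (FPR, TPR, AUC)."""
    causal = np.asarray(causal_ratios, dtype=float)
    neutral = np.asarray(neutral_ratios, dtype=float)
    if causal.size == 0 or neutral.size == 0:
        raise InputError("both causal and neutral rank ratios are required")
    y = np.concatenate([np.ones(causal.size), np.zeros(neutral.size)])
    # score = -ratio so that "score >= threshold" means "ratio <= threshold"
    fpr, tpr, _ = _sk_roc_curve(y, -np.concatenate([causal, neutral]))
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def random_rank_ratios(
    set_sizes: Sequence[int], n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Rank ratios of a uniform-random ranker over repeated spike-ins.

    Each simulation draws the causal indel's rank uniformly from 1..M where M
    cycles through ``set_sizes``.
    """
    sizes = np.asarray(set_sizes, dtype=int)
    M = sizes[np.arange(n_sim) % sizes.size]
    ranks = rng.integers(1, M + 1)
    return ranks / M
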