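"""End-to-end ranking of candidate indels for a query disease.

For every candidate the pipeline assembles up to ten p-values -- five
functional predictors and the intolerance score via empirical nulls, plus
four association channels via the random walk -- fuses them with the chosen
combiner, and sorts ascending.  Candidates with no usable source at all are
placed last as a block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .integration import DependenceModel, fit_dependence_model, integrate
from .null_models import (
    ALL_SOURCES,
    ASSOCIATION_SOURCES,
    NullDistribution,
    PER_INDEL_SOURCES,
    ScoredIndel,
    pvalues_for_indel,
)
from .rwr import AssociationScorer

__all__ = ["RankingResult", "assemble_evidence", "prioritize"]


@dataclass
class RankingResult:
    """Prioritized candidate table for one query disease.

    ``table`` is sorted by rank and carries per-source p-values (NaN for
    missing), the integrated p-value (NaN when every source is missing),
    ``n_sources``, ``rank`` (1..M) and ``rank_ratio`` (rank/M).
    """

    table: pd.DataFrame
    query_disease: str
    method: str
    model: DependenceModel | None = None

    @property
    def n_candidates(self) -> int:
        return len(self.table)

    def pessimistic_rank(self, label: str) -> int:
        """Worst rank within the candidate's tie block (equal integrated p).

        Fully missing candidates tie with the whole all-missing tail block, so
        their pessimistic rank is M.
        """
        rows = self.table[self.table["label"] == label]
        if rows.empty:
            raise InputError(f"candidate {label!r} not in the ranking")
        p = rows["integrated_p"].iloc[0]
        if np.isnan(p):
            return len(self.table)
        return int((self.table["integrated_p"] <= p).sum())


def assemble_evidence(
    indels: Sequence[ScoredIndel],
    disease: str,
    nulls: Mapping[str, NullDistribution],
    assoc_scorers: Mapping[str, AssociationScorer],
) -> pd.DataFrame:
    """Indels-by-sources table of p-values (NaN = missing source)."""
    rows = []
    for indel in indels:
        row = dict.fromkeys(ALL_SOURCES, np.nan)
        row.update(pvalues_for_indel(indel, nulls))
        for kind in ASSOCIATION_SOURCES:
            scorer = assoc_scorers.get(kind)
            if scorer is None:
                continue
            p = scorer.association_pvalue(disease, indel.gene)
            if p is not None:
                row[kind] = p
        rows.append(row)
    return pd.DataFrame(rows, columns=list(ALL_SOURCES))


def prioritize(
    indels: Sequence[ScoredIndel],
    disease: str,
    nulls: Mapping[str, NullDistribution],
    assoc_scorers: Mapping[str, AssociationScorer],
    method: str = "fisher_corrected",
    model: DependenceModel | None = None,
) -> RankingResult:
    """Rank candidate indels by integrated p-value for one query disease.

    Ties in the integrated p-value are broken deterministically: candidates
    with more present sources come first, then input order.  The dependence
    model for the corrected Fisher combiner is fitted on the candidate set
    itself unless one is supplied.
    """
    if not indels:
        raise InputError("need at least one candidate indel")
    for kind in assoc_scorers:
        if kind not in ASSOCIATION_SOURCES:
            raise InputError(f"unknown association channel {kind!r}")
    evidence = assemble_evidence(indels, disease, nulls, assoc_scorers)
    if method == "fisher_corrected" and model is None and len(indels) >= 3:
        model = fit_dependence_model(evidence)
    integrated = np.array(
        [
            integrate(evidence.iloc[i].to_dict(), method=method, model=model)
            for i in range(len(indels))
        ]
    )
    n_sources = evidence.notna().sum(axis=1).to_numpy()
    meta = pd.DataFrame(
        {
            "label": [iv.label for iv in indels],
            "CHROM": [iv.chrom for iv in indels],
            "POS": [iv.pos for iv in indels],
            "REF": [iv.ref for iv in indels],
            "ALT": [iv.alt for iv in indels],
            "GENE": [iv.gene for iv in indels],
            "SUBTYPE": [iv.subtype.value for iv in indels],
        }
    )
    table = pd.concat([meta, evidence], axis=1)
    table["integrated_p"] = integrated
    table["n_sources"] = n_sources
    # missing-integrated candidates sort last; ties -> more sources first, then input order
    order = np.lexsort(
        (np.arange(len(indels)), -n_sources, np.nan_to_num(integrated, nan=np.inf),
         np.isnan(integrated).astype(int))
    )
    table = table.iloc[order].reset_index(drop=True)
    M = len(table)
    table["rank"] = np.arange(1, M + 1)
    table["rank_ratio"] = table["rank"] / M
    return RankingResult(table=table, query_disease=disease, method=method, model=model)
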