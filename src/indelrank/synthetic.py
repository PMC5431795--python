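"""Self-contained synthetic fixtures with the statistical structure the method assumes.

The generator builds a modular world: diseases and genes are partitioned into
matched modules, within-module feature similarity is elevated in every layer
(phenotype concepts, expression, ontology terms, PPI edges, TF-binding
counts), and known associations connect diseases to genes of their own
module.  Candidate indels carry block-correlated raw scores drawn through a
Gaussian copula; causal indels are shifted by ``effect_size`` standard
deviations in each source's damaging direction and are hosted in genes of
their disease's module.  Missingness is applied per source, and frameshift
subtypes are enriched among causal indels.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InputError
from .networks import (
    GENE_NETWORK_KINDS,
    K_DISEASE,
    K_GENE,
    SimilarityNetwork,
    build_disease_network,
    build_gene_network,
)
from .null_models import (
    DEFAULT_DIRECTIONS,
    Direction,
    NullDistribution,
    PER_INDEL_SOURCES,
    ScoredIndel,
    Subtype,
)
from .rwr import AssociationScorer, HeterogeneousNetwork, RWRParams

__all__ = [
    "SyntheticConfig",
    "World",
    "SyntheticIndels",
    "generate_world",
    "generate_indels",
    "world_networks",
    "association_scorers",
]

_SUBTYPE_ALLELES = {
    Subtype.ND: ("AGCT", "A"),
    Subtype.NI: ("A", "AGCT"),
    Subtype.FD: ("AG", "A"),
    Subtype.FI: ("A", "AG"),
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world and spike-in fixture."""

    m_diseases: int = 50
    n_genes: int = 200
    n_modules: int = 5
    n_causal: int = 20
    n_neutral: int = 200
    effect_size: float = 3.0
    source_correlation: float = 0.3
    missing_rate: float | Mapping[str, float] = 0.1
    n_null: int = 1000
    n_tissues: int = 40
    n_go_terms_per_module: int = 12
    n_background_concepts: int = 20
    n_concepts_per_module: int = 6
    n_tfs: int = 30
    ppi_within: float = 0.30
    ppi_between: float = 0.02
    assoc_per_disease: int = 2
    causal_frameshift_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m_diseases, self.n_genes, self.n_modules, self.n_causal, self.n_neutral) < 1:
            raise InputError("all counts must be >= 1")
        if self.n_modules > min(self.m_diseases, self.n_genes):
            raise InputError("n_modules cannot exceed min(m_diseases, n_genes)")
        if self.effect_size < 0:
            raise InputError("effect_size must be >= 0")
        if not (0.0 <= self.source_correlation < 1.0):
            raise InputError("source_correlation must be in [0, 1)")

    def missing_rate_for(self, source: str) -> float:
        if isinstance(self.missing_rate, Mapping):
            return float(self.missing_rate.get(source, 0.0))
        return float(self.missing_rate)


@dataclass
class World:
    """Generated feature tables plus ground-truth module structure."""

    disease_ids: list[str]
    gene_ids: list[str]
    disease_module: np.ndarray
    gene_module: np.ndarray
    annotations: pd.DataFrame  # entity_id, concept_id
    expression: pd.DataFrame  # genes x tissues
    go_membership: pd.DataFrame  # genes x GO terms (binary)
    ppi_edges: pd.DataFrame  # gene_a, gene_b
    tf_counts: pd.DataFrame  # genes x TFs (counts)
    associations: pd.DataFrame  # disease_id, gene_id

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in zip(self.gene_ids, self.gene_module) if m == module]

    def disease_genes(self, disease: str) -> list[str]:
        hits = self.associations[self.associations["disease_id"] == disease]
        return list(hits["gene_id"])


@dataclass
class SyntheticIndels:
    """Spike-in fixture: labelled indel sets plus per-source null tables."""

    causal: list[ScoredIndel]
    neutral: list[ScoredIndel]
    causal_diseases: list[str]
    nulls: dict[str, NullDistribution]

    @property
    def disease_map(self) -> dict[str, str]:
        return {c.label: d for c, d in zip(self.causal, self.causal_diseases)}


def generate_world(cfg: SyntheticConfig) -> World:
    """Build the modular disease/gene world (deterministic under cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    m, n, B = cfg.m_diseases, cfg.n_genes, cfg.n_modules
    disease_ids = [f"D{i:04d}" for i in range(m)]
    gene_ids = [f"G{j:04d}" for j in range(n)]
    disease_module = np.arange(m) % B
    gene_module = np.arange(n) % B

    # phenotype concepts: module-specific blocks + shared background noise
    records = []
    for i, d in enumerate(disease_ids):
        mod = disease_module[i]
        own = [
            f"C{mod}_{t}" for t in range(cfg.n_concepts_per_module) if rng.random() < 0.9
        ]
        if not own:  # every disease keeps at least one phenotype concept
            own = [f"C{mod}_0"]
        bg = [f"B{t}" for t in range(cfg.n_background_concepts) if rng.random() < 0.15]
        records += [{"entity_id": d, "concept_id": c} for c in own + bg]
    annotations = pd.DataFrame(records)

    # expression: module base profile + per-gene noise
    base = rng.normal(size=(B, cfg.n_tissues))
    expr = base[gene_module] + 0.6 * rng.normal(size=(n, cfg.n_tissues))
    expression = pd.DataFrame(
        expr, index=gene_ids, columns=[f"tissue_{t}" for t in range(cfg.n_tissues)]
    )

    # GO membership: module term block (p=0.7) + off-module leakage (p=0.05)
    n_terms = cfg.n_go_terms_per_module * B
    term_module = np.arange(n_terms) % B
    prob = np.where(term_module[None, :] == gene_module[:, None], 0.7, 0.05)
    go = (rng.random((n, n_terms)) < prob).astype(int)
    empty = go.sum(axis=1) == 0
    go[empty, (gene_module[empty] * cfg.n_go_terms_per_module) % n_terms] = 1
    go_membership = pd.DataFrame(
        go, index=gene_ids, columns=[f"GO_{t}" for t in range(n_terms)]
    )

    # PPI: dense within modules, sparse across
    prob = np.where(gene_module[:, None] == gene_module[None, :], cfg.ppi_within, cfg.ppi_between)
    adj = np.triu(rng.random((n, n)) < prob, k=1)
    ii, jj = np.nonzero(adj)
    ppi_edges = pd.DataFrame(
        {"gene_a": [gene_ids[i] for i in ii], "gene_b": [gene_ids[j] for j in jj]}
    )

    # TF-binding counts: Poisson around a module-specific rate per TF
    lam = rng.uniform(0.5, 6.0, size=(B, cfg.n_tfs))
    tf = rng.poisson(lam[gene_module])
    tf_counts = pd.DataFrame(tf, index=gene_ids, columns=[f"TF_{t}" for t in range(cfg.n_tfs)])

    # planted associations: each disease points at genes of its own module
    rows = []
    for i, d in enumerate(disease_ids):
        pool = np.flatnonzero(gene_module == disease_module[i])
        picked = rng.choice(pool, size=min(cfg.assoc_per_disease, pool.size), replace=False)
        rows += [{"disease_id": d, "gene_id": gene_ids[j]} for j in picked]
    associations = pd.DataFrame(rows)

    return World(
        disease_ids=disease_ids,
        gene_ids=gene_ids,
        disease_module=disease_module,
        gene_module=gene_module,
        annotations=annotations,
        expression=expression,
        go_membership=go_membership,
        ppi_edges=ppi_edges,
        tf_counts=tf_counts,
        associations=associations,
    )


def _draw_scores(
    rng: np.random.Generator, n: int, rho: float, effect: float
) -> np.ndarray:
    """Equicorrelated Gaussian raw scores, shifted by ``effect`` toward damage."""
    k = len(PER_INDEL_SOURCES)
    common = rng.normal(size=(n, 1))
    z = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * rng.normal(size=(n, k))
    sign = np.array(
        [1.0 if DEFAULT_DIRECTIONS[s] is Direction.LARGER else -1.0 for s in PER_INDEL_SOURCES]
    )
    return z + effect * sign[None, :]


def generate_indels(cfg: SyntheticConfig, world: World) -> SyntheticIndels:
    """Generate causal and neutral indel sets plus per-source null tables."""
    rng = np.random.default_rng(cfg.seed + 1)
    f = cfg.causal_frameshift_frac
    subtype_order = (Subtype.ND, Subtype.NI, Subtype.FD, Subtype.FI)
    causal_subtypes = [
        subtype_order[i]
        for i in rng.choice(4, size=cfg.n_causal, p=[(1 - f) / 2, (1 - f) / 2, f / 2, f / 2])
    ]
    neutral_subtypes = [subtype_order[i % 4] for i in range(cfg.n_neutral)]

    causal_scores = _draw_scores(rng, cfg.n_causal, cfg.source_correlation, cfg.effect_size)
    neutral_scores = _draw_scores(rng, cfg.n_neutral, cfg.source_correlation, 0.0)

    # per-indel query disease and module-consistent host gene for causal indels
    causal_diseases = [
        world.disease_ids[i]
        for i in rng.integers(0, len(world.disease_ids), size=cfg.n_causal)
    ]
    causal_genes = []
    for d in causal_diseases:
        mod = world.disease_module[world.disease_ids.index(d)]
        known = world.disease_genes(d)
        if known and rng.random() < 0.5:  # exercise the leave-one-out path
            causal_genes.append(str(rng.choice(known)))
        else:
            causal_genes.append(str(rng.choice(world.module_genes(mod))))
    neutral_genes = [
        world.gene_ids[j] for j in rng.integers(0, len(world.gene_ids), size=cfg.n_neutral)
    ]

    def make(idx, subtype, gene, scores, is_causal) -> ScoredIndel:
        ref, alt = _SUBTYPE_ALLELES[subtype]
        raw = {}
        for s, v in zip(PER_INDEL_SOURCES, scores):
            if rng.random() >= cfg.missing_rate_for(s):
                raw[s] = float(v)
        return ScoredIndel(
            chrom="1",
            pos=1000 + 50 * idx,
            ref=ref,
            alt=alt,
            gene=gene,
            subtype=subtype,
            raw_scores=raw,
        )

    causal = [
        make(i, causal_subtypes[i], causal_genes[i], causal_scores[i], True)
        for i in range(cfg.n_causal)
    ]
    neutral = [
        make(cfg.n_causal + i, neutral_subtypes[i], neutral_genes[i], neutral_scores[i], False)
        for i in range(cfg.n_neutral)
    ]

    nulls = {
        s: NullDistribution(
            source=s, scores=rng.normal(size=cfg.n_null), direction=DEFAULT_DIRECTIONS[s]
        )
        for s in PER_INDEL_SOURCES
    }
    return SyntheticIndels(
        causal=causal, neutral=neutral, causal_diseases=causal_diseases, nulls=nulls
    )


def world_networks(
    world: World, k_disease: int = K_DISEASE, k_gene: int = K_GENE
) -> tuple[SimilarityNetwork, dict[str, SimilarityNetwork]]:
    """Build the disease network and all four gene networks from world tables."""
    disease_net = build_disease_network(world.annotations, k=k_disease)
    gene_nets = {
        "gexp": build_gene_network("gexp", world.expression, k=k_gene),
        "gobp": build_gene_network("gobp", world.go_membership, k=k_gene),
        "strg": build_gene_network("strg", world.ppi_edges, k=k_gene),
        "tsfc": build_gene_network("tsfc", world.tf_counts, k=k_gene),
    }
    return disease_net, gene_nets


def save_fixture(out_dir, world: World, indels: SyntheticIndels) -> None:
    """Write a generated fixture as the plain-text files the pipeline reads."""
    from pathlib import Path

    from . import io as _io_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.annotations.to_csv(out / "disease_annotations.tsv", sep="\t", index=False)
    _io_mod.write_matrix(world.expression, out / "expression.tsv")
    _io_mod.write_matrix(world.go_membership, out / "go_membership.tsv")
    world.ppi_edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
    _io_mod.write_matrix(world.tf_counts, out / "tf_counts.tsv")
    world.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    pd.DataFrame({"disease_id": world.disease_ids, "module": world.disease_module}).to_csv(
        out / "disease_modules.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene_id": world.gene_ids, "module": world.gene_module}).to_csv(
        out / "gene_modules.tsv", sep="\t", index=False
    )
    _io_mod.write_indels(indels.causal, out / "causal_indels.tsv")
    _io_mod.write_indels(indels.neutral, out / "neutral_indels.tsv")
    pd.DataFrame(
        {
            "causal_label": [c.label for c in indels.causal],
            "disease_id": indels.causal_diseases,
        }
    ).to_csv(out / "causal_diseases.tsv", sep="\t", index=False)
    for source, dist in indels.nulls.items():
        _io_mod.write_null_distribution(dist, out / f"null_{source}.tsv")


def load_fixture(in_dir) -> tuple[World, SyntheticIndels]:
    """Read back a fixture written by :func:`save_fixture`."""
    from pathlib import Path

    from . import io as _io_mod

    src = Path(in_dir)
    dm = pd.read_csv(src / "disease_modules.tsv", sep="\t")
    gm = pd.read_csv(src / "gene_modules.tsv", sep="\t")
    world = World(
        disease_ids=list(dm["disease_id"].astype(str)),
        gene_ids=list(gm["gene_id"].astype(str)),
        disease_module=dm["module"].to_numpy(),
        gene_module=gm["module"].to_numpy(),
        annotations=pd.read_csv(src / "disease_annotations.tsv", sep="\t"),
        expression=_io_mod.read_matrix(src / "expression.tsv"),
        go_membership=_io_mod.read_matrix(src / "go_membership.tsv"),
        ppi_edges=pd.read_csv(src / "ppi_edges.tsv", sep="\t"),
        tf_counts=_io_mod.read_matrix(src / "tf_counts.tsv"),
        associations=pd.read_csv(src / "associations.tsv", sep="\t", dtype=str),
    )
    causal = _io_mod.read_indels(src / "causal_indels.tsv")
    neutral = _io_mod.read_indels(src / "neutral_indels.tsv")
    truth = pd.read_csv(src / "causal_diseases.tsv", sep="\t", dtype=str)
    by_label = dict(zip(truth["causal_label"], truth["disease_id"]))
    nulls = {
        s: _io_mod.read_null_distribution(src / f"null_{s}.tsv") for s in PER_INDEL_SOURCES
    }
    indels = SyntheticIndels(
        causal=causal,
        neutral=neutral,
        causal_diseases=[by_label[c.label] for c in causal],
        nulls=nulls,
    )
    return world, indels


def association_scorers(
    world: World,
    disease_net: SimilarityNetwork,
    gene_nets: Mapping[str, SimilarityNetwork],
    params: RWRParams | None = None,
    seed: int = 0,
) -> dict[str, AssociationScorer]:
    """One cached random-walk scorer (with its own null) per gene-network kind."""
    pairs = list(world.associations.itertuples(index=False, name=None))
    scorers = {}
    for kind in GENE_NETWORK_KINDS:
        net = HeterogeneousNetwork.from_networks(disease_net, gene_nets[kind], pairs)
        scorers[kind] = AssociationScorer(net, params, seed=seed)
    return scorers
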