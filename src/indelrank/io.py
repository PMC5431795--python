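"""Plain-text readers and writers (TSV with '#' comment headers, optional VCF).

Every writer's output round-trips through its reader.  Coordinates are
1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .networks import SimilarityNetwork
from .null_models import (
    DEFAULT_DIRECTIONS,
    Direction,
    NullDistribution,
    PER_INDEL_SOURCES,
    ScoredIndel,
)

__all__ = [
    "read_null_distribution",
    "write_null_distribution",
    "read_indels",
    "write_indels",
    "read_indels_vcf",
    "read_network",
    "write_network",
    "read_associations",
    "write_associations",
    "read_matrix",
    "write_matrix",
    "write_ranking",
]

_INDEL_COLS = ["CHROM", "POS", "REF", "ALT", "GENE", "SUBTYPE"]


def _header_lines(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def write_null_distribution(dist: NullDistribution, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# source: {dist.source}\n")
        fh.write(f"# direction: {dist.direction.value}\n")
        for s in dist.scores:
            fh.write(f"{float(s)!r}\n")


def read_null_distribution(path: str | Path, source: str | None = None) -> NullDistribution:
    path = Path(path)
    meta = _header_lines(path)
    direction = meta.get("direction")
    if direction is None:
        raise ConfigurationError(f"{path}: missing '# direction:' header")
    scores = (
        pd.read_csv(path, comment="#", header=None, float_precision="round_trip")
        .iloc[:, 0]
        .to_numpy(dtype=float)
    )
    return NullDistribution(
        source=source or meta.get("source", path.stem),
        scores=scores,
        direction=Direction(direction),
    )


def write_indels(
    indels: Sequence[ScoredIndel], path: str | Path, sources: Sequence[str] = PER_INDEL_SOURCES
) -> None:
    rows = []
    for iv in indels:
        row = {
            "CHROM": iv.chrom, "POS": iv.pos, "REF": iv.ref, "ALT": iv.alt,
            "GENE": iv.gene, "SUBTYPE": iv.subtype.value,
        }
        for s in sources:
            row[s] = iv.raw_scores.get(s, np.nan)
        rows.append(row)
    pd.DataFrame(rows, columns=_INDEL_COLS + list(sources)).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_indels(path: str | Path) -> list[ScoredIndel]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = [c for c in _INDEL_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    sources = [c for c in df.columns if c not in _INDEL_COLS]
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            out.append(
                ScoredIndel(
                    chrom=str(rec["CHROM"]),
                    pos=int(rec["POS"]),
                    ref=str(rec["REF"]),
                    alt=str(rec["ALT"]),
                    gene=str(rec["GENE"]),
                    subtype=rec["SUBTYPE"],
                    raw_scores={
                        s: rec[s] for s in sources if pd.notna(rec[s])
                    },
                )
            )
        except (InputError, ValueError) as exc:
            raise InputError(f"{path}: line {idx}: {exc}") from exc
    return out


def read_indels_vcf(
    path: str | Path, info_map: Mapping[str, str], gene_tag: str = "GENE"
) -> list[ScoredIndel]:
    """Read candidates from a VCF; ``info_map`` maps source name -> INFO tag."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = rec.info.get(gene_tag)
            if gene is None:
                raise InputError(f"{path}: record {rec.chrom}:{rec.pos} lacks INFO/{gene_tag}")
            if isinstance(gene, tuple):
                gene = gene[0]
            scores = {}
            for source, tag in info_map.items():
                val = rec.info.get(tag)
                if val is None:
                    continue
                if isinstance(val, tuple):
                    val = val[0]
                scores[source] = float(val)
            for alt in rec.alts or ():
                out.append(
                    ScoredIndel(
                        chrom=str(rec.chrom), pos=int(rec.pos), ref=str(rec.ref),
                        alt=str(alt), gene=str(gene), raw_scores=dict(scores),
                    )
                )
    return out


def write_network(net: SimilarityNetwork, path: str | Path) -> None:
    path = Path(path)
    edges = net.to_edge_frame()
    with open(path, "w") as fh:
        fh.write(f"# kind: {net.kind}\n")
        fh.write(f"# nodes: {','.join(net.nodes)}\n")
        edges.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_network(path: str | Path) -> SimilarityNetwork:
    path = Path(path)
    meta = _header_lines(path)
    if "nodes" not in meta:
        raise ConfigurationError(f"{path}: missing '# nodes:' header")
    nodes = meta["nodes"].split(",")
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    edges = pd.read_csv(path, sep="\t", comment="#")
    for a, b, w in edges.itertuples(index=False, name=None):
        i, j = idx[str(a)], idx[str(b)]
        W[i, j] = W[j, i] = float(w)
    return SimilarityNetwork(kind=meta.get("kind", "generic"), nodes=nodes, weights=W)


def write_associations(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(list(pairs), columns=["disease_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["disease_id", "gene_id"]:
        raise InputError(f"{path}: expected columns disease_id, gene_id")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_ranking(result, path: str | Path, provenance: Sequence[str] = ()) -> None:
    """Ranking table with per-source p-values, integrated p, rank and rank ratio."""
    path = Path(path)
    buf = _io.StringIO()
    for line in provenance:
        buf.write(f"# {line}\n")
    buf.write(f"# query_disease: {result.query_disease}\n")
    buf.write(f"# method: {result.method}\n")
    cols = [c for c in result.table.columns if c != "label"]
    result.table[cols].to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%.8g")
    path.write_text(buf.getvalue())
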