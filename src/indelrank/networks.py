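"""Similarity-network construction for the disease layer and the four gene layers.

The disease network compares diseases through phenotype-concept vectors
(entry ``-log h_i`` for each annotated concept, ``h_i`` the concept's corpus
frequency) with cosine similarity and 10-nearest-neighbour sparsification.

Gene networks come in four flavours:

==========  =============================  ==================  =======
kind        feature                        raw similarity      k-NN
==========  =============================  ==================  =======
``gexp``    expression across tissues      Pearson r           100
``gobp``    binary ontology membership     cosine              100
``strg``    PPI shortest-path distance     1 - d/max(d)        100
``tsfc``    TF binding-site count vector   cosine              100
==========  =============================  ==================  =======

All gene raw similarities pass through the exponential kernel
``phi = exp(-((1-w)/sigma)^2)`` (sigma = SD of the off-diagonal raw scores)
before sparsification; the disease network does not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .exceptions import DegenerateNetworkError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityNetwork",
    "cosine_similarity_matrix",
    "pearson_similarity_matrix",
    "pairwise_sigma",
    "exponential_transform",
    "shortest_path_similarity",
    "knn_sparsify",
    "build_disease_network",
    "build_gene_network",
    "GENE_NETWORK_KINDS",
    "K_DISEASE",
    "K_GENE",
]

GENE_NETWORK_KINDS = ("gexp", "gobp", "strg", "tsfc")
K_DISEASE = 10
K_GENE = 100


@dataclass
class SimilarityNetwork:
    """A sparsified, symmetric similarity network with weights in [0, 1]."""

    kind: str
    nodes: list[str]
    weights: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise InputError("weights shape does not match node count")
        self.index = {n: i for i, n in enumerate(self.nodes)}

    def __contains__(self, node: str) -> bool:
        return node in self.index

    def neighbors(self, node: str) -> list[str]:
        i = self.index[node]
        return [self.nodes[j] for j in np.flatnonzero(self.weights[i] > 0)]

    def to_edge_frame(self) -> pd.DataFrame:
        """Upper-triangle weighted edge list (node_a, node_b, weight)."""
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "node_a": [self.nodes[i] for i in ii],
                "node_b": [self.nodes[j] for j in jj],
                "weight": self.weights[ii, jj],
            }
        )


def _warn_zero_rows(X: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero {what} vector(s); similarity set to 0", stacklevel=3)
    return zero


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of row vectors; zero rows score 0 everywhere."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need >= 2 profiles of equal dimension")
    zero = _warn_zero_rows(X, "feature")
    if zero.all():
        raise InputError("all profiles are zero vectors")
    S = _sk_cosine(X)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    return np.clip(S, -1.0, 1.0)


def pearson_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of row vectors; zero-variance rows score 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InputError("profiles need dimension >= 2 for a correlation")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profile(s); similarity set to 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.corrcoef(X)
    S = np.nan_to_num(S, nan=0.0)
    S[flat, :] = 0.0
    S[:, flat] = 0.0
    return np.clip(S, -1.0, 1.0)


def pairwise_sigma(raw: np.ndarray) -> float:
    """Standard deviation of the off-diagonal raw similarity scores."""
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    off = raw[~np.eye(n, dtype=bool)]
    return float(off.std())


def exponential_transform(w: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """Noise-suppressing kernel ``phi = exp(-((1-w)/sigma)^2)``, monotone in w."""
    if sigma <= 0:
        raise DegenerateNetworkError("sigma must be > 0 (all raw similarities identical?)")
    return np.exp(-(((1.0 - np.asarray(w, dtype=float)) / sigma) ** 2))


def shortest_path_similarity(
    ppi_edges: Iterable[tuple[str, str]], nodes: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Similarity ``w_ab = 1 - delta_ab / max(delta)`` from unweighted BFS distances.

    ``max(delta)`` is taken over connected pairs only; disconnected pairs get
    similarity 0.  Returns the node order and the raw similarity matrix.
    """
    edges = [(str(a), str(b)) for a, b in ppi_edges]
    if not edges:
        raise InputError("empty PPI edge list")
    if nodes is None:
        seen: dict[str, None] = {}
        for a, b in edges:
            seen.setdefault(a)
            seen.setdefault(b)
        nodes = list(seen)
    else:
        nodes = [str(n) for n in nodes]
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for a, b in edges:
        if a in idx and b in idx and a != b:
            rows.append(idx[a])
            cols.append(idx[b])
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)
    delta = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    finite = np.isfinite(delta) & (delta > 0)
    if not finite.any():
        raise InputError("PPI network has no connected pair")
    max_delta = delta[finite].max()
    W = np.zeros((n, n))
    W[finite] = 1.0 - delta[finite] / max_delta
    np.fill_diagonal(W, 1.0)
    return nodes, W


def knn_sparsify(
    raw: np.ndarray, k: int, nodes: Sequence[str] | None = None, kind: str = "generic"
) -> SimilarityNetwork:
    """Keep each node's k strongest off-diagonal similarities; symmetrize by union.

    Ties at the k-th position are all retained, so the result is deterministic
    and independent of node order.  Weights never increase; the diagonal is
    zeroed; negative weights are floored at 0.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if k < 1:
        raise InputError("k must be >= 1")
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    R = raw.copy().astype(float)
    np.fill_diagonal(R, -np.inf)
    if k >= n:
        warnings.warn(f"k={k} >= node count {n}; keeping all edges", stacklevel=2)
        keep = np.isfinite(R)
    else:
        # ascending partition: the k-th largest of each row sits at index n-k
        thr = np.partition(R, n - k, axis=1)[:, n - k]
        keep = R >= thr[:, None]
    keep |= keep.T
    W = np.where(keep, raw, 0.0)
    np.fill_diagonal(W, 0.0)
    W = np.clip(W, 0.0, None)
    return SimilarityNetwork(kind=kind, nodes=list(nodes), weights=W)


def build_disease_network(
    annotations: pd.DataFrame, k: int = K_DISEASE
) -> SimilarityNetwork:
    """Disease network from a phenotype-annotation table.

    ``annotations`` columns: ``entity_id``, ``concept_id`` and optionally
    ``frequency`` (corpus frequency of the concept).  When absent, frequency is
    the fraction of annotated diseases carrying the concept.  Concept weights
    are ``-log h_i`` with ``h_i`` clamped to ``[1/n_diseases, 1]``.
    """
    required = {"entity_id", "concept_id"}
    if not required.issubset(annotations.columns):
        raise InputError(f"annotation table needs columns {sorted(required)}")
    diseases = list(pd.unique(annotations["entity_id"].astype(str)))
    concepts = list(pd.unique(annotations["concept_id"].astype(str)))
    n_dis = len(diseases)
    member = pd.crosstab(
        annotations["entity_id"].astype(str), annotations["concept_id"].astype(str)
    ).reindex(index=diseases, columns=concepts, fill_value=0)
    member = (member.to_numpy() > 0).astype(float)
    if "frequency" in annotations.columns:
        freq = (
            annotations.groupby(annotations["concept_id"].astype(str))["frequency"]
            .first()
            .reindex(concepts)
            .to_numpy(dtype=float)
        )
        h = np.clip(freq, 1.0 / max(n_dis, 2), 1.0 - 1.0 / (n_dis + 1))
    else:
        # add-one estimate keeps -log h > 0 even for ubiquitous concepts
        freq = member.sum(axis=0) / (n_dis + 1)
        h = np.clip(freq, 1.0 / (n_dis + 1), 1.0)
    X = member * (-np.log(h))[None, :]
    S = cosine_similarity_matrix(X)
    return knn_sparsify(S, k=k, nodes=diseases, kind="disease")


def build_gene_network(kind: str, data, k: int = K_GENE) -> SimilarityNetwork:
    """Build one gene network of the requested kind.

    Parameters
    ----------
    kind
        One of ``gexp`` (expression DataFrame genes x tissues), ``gobp``
        (binary DataFrame genes x GO terms), ``strg`` (PPI edge DataFrame with
        two columns, or an iterable of pairs), ``tsfc`` (count DataFrame genes
        x transcription factors).
    """
    if kind not in GENE_NETWORK_KINDS:
        raise InputError(f"unknown gene network kind {kind!r}")
    featureless = None
    if kind == "strg":
        if isinstance(data, pd.DataFrame):
            pairs = list(data.itertuples(index=False, name=None))
        else:
            pairs = list(data)
        nodes, raw = shortest_path_similarity(pairs)
    else:
        if not isinstance(data, pd.DataFrame):
            raise InputError(f"{kind} expects a genes-by-features DataFrame")
        nodes = [str(g) for g in data.index]
        X = data.to_numpy(dtype=float)
        if kind == "gexp":
            raw = pearson_similarity_matrix(X)
            featureless = X.std(axis=1) == 0
        else:  # gobp, tsfc: cosine on binary / count vectors
            raw = cosine_similarity_matrix(X)
            featureless = np.linalg.norm(X, axis=1) == 0
    sigma = pairwise_sigma(raw)
    phi = np.asarray(exponential_transform(raw, sigma))
    if featureless is not None and featureless.any():
        # the kernel maps raw 0 to a small positive value; genes with no
        # features must stay isolated rather than picking up kernel noise
        phi[featureless, :] = 0.0
        phi[:, featureless] = 0.0
    return knn_sparsify(phi, k=k, nodes=nodes, kind=kind)
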