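"""Random walk with restart on the two-layered disease-gene network.

The heterogeneous network is the triple H = (D, G, A): a disease similarity
matrix, a gene similarity matrix, and a binary disease-gene association
matrix.  Row-normalizing D, G, A and A^T gives the intra- and inter-layer
transition blocks U, V, R, S, which are composed with the layer-switch
probability tau into

    T = [[(1-tau) U, tau R], [tau S, (1-tau) V]]

and row-normalized again into the overall transition matrix W.  The walker
iterates

    p(t+1) = (1-pi) W^T p(t) + pi p(0)

from a start distribution concentrated on the query disease's neighbours
until the squared L2 change drops below eps.  The steady-state gene
sub-vector v(inf) measures disease-gene association strength; comparing it
against the steady-state scores of non-associated pairs yields an empirical
association p-value.  Known links between query disease and query gene are
removed (leave-one-out) before the walk that scores them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateNetworkError, InputError
from .networks import SimilarityNetwork
from .null_models import Direction, NullDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneousNetwork",
    "RWRParams",
    "TransitionSystem",
    "RWRState",
    "build_transition_system",
    "initial_distribution",
    "random_walk",
    "AssociationScorer",
    "association_null",
]


@dataclass
class RWRParams:
    """Random-walk parameters (defaults follow the published configuration)."""

    tau: float = 0.5
    pi: float = 0.5
    eps: float = 1e-4
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise InputError("tau must be in [0, 1]")
        if not (0.0 < self.pi <= 1.0):
            raise InputError("pi must be in (0, 1]")
        if self.eps <= 0 or self.max_iter < 1:
            raise InputError("eps must be > 0 and max_iter >= 1")


@dataclass
class HeterogeneousNetwork:
    """Disease layer D (m x m), gene layer G (n x n), associations A (m x n)."""

    D: np.ndarray
    G: np.ndarray
    A: np.ndarray
    disease_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        m, n = len(self.disease_ids), len(self.gene_ids)
        if self.D.shape != (m, m) or self.G.shape != (n, n) or self.A.shape != (m, n):
            raise InputError("inconsistent D/G/A shapes")
        if (self.D < 0).any() or (self.G < 0).any():
            raise InputError("similarity matrices must be nonnegative")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise InputError("A must be binary")
        self._dis_index = {d: i for i, d in enumerate(self.disease_ids)}
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def m(self) -> int:
        return len(self.disease_ids)

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def disease_index(self, disease: str) -> int:
        try:
            return self._dis_index[disease]
        except KeyError:
            raise InputError(f"disease {disease!r} not in the disease network") from None

    def gene_index(self, gene: str) -> int | None:
        return self._gene_index.get(gene)

    @classmethod
    def from_networks(
        cls,
        disease_net: SimilarityNetwork,
        gene_net: SimilarityNetwork,
        associations: list[tuple[str, str]],
    ) -> "HeterogeneousNetwork":
        m, n = len(disease_net.nodes), len(gene_net.nodes)
        A = np.zeros((m, n))
        for d, g in associations:
            i = disease_net.index.get(str(d))
            j = gene_net.index.get(str(g))
            if i is not None and j is not None:
                A[i, j] = 1.0
        return cls(
            D=disease_net.weights,
            G=gene_net.weights,
            A=A,
            disease_ids=list(disease_net.nodes),
            gene_ids=list(gene_net.nodes),
        )


def _row_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    out = np.divide(M, sums, out=np.zeros_like(M, dtype=float), where=sums > 0)
    return out


@dataclass
class TransitionSystem:
    """Row-normalized transition blocks and the overall matrix W."""

    U: np.ndarray
    V: np.ndarray
    R: np.ndarray
    S: np.ndarray
    W: np.ndarray
    tau: float
    m: int
    n: int
    isolated: np.ndarray = field(default=None)  # nodes whose T row was all zero

    def loo_transition(self, i: int, j: int, A: np.ndarray) -> np.ndarray:
        """W with the single association (disease i, gene j) removed.

        Only the two affected rows (disease i, gene m+j) are recomputed.
        """
        if A[i, j] != 1.0:
            raise InputError("leave-one-out requested for a non-associated pair")
        m, n, tau = self.m, self.n, self.tau
        W = self.W.copy()

        a_row = A[i].copy()
        a_row[j] = 0.0
        r = a_row / a_row.sum() if a_row.sum() > 0 else np.zeros(n)
        t_row = np.concatenate(((1.0 - tau) * self.U[i], tau * r))
        tot = t_row.sum()
        if tot > 0:
            W[i] = t_row / tot
        else:
            W[i] = 0.0
            W[i, i] = 1.0

        a_col = A[:, j].copy()
        a_col[i] = 0.0
        s = a_col / a_col.sum() if a_col.sum() > 0 else np.zeros(m)
        t_row = np.concatenate((tau * s, (1.0 - tau) * self.V[j]))
        tot = t_row.sum()
        if tot > 0:
            W[m + j] = t_row / tot
        else:
            W[m + j] = 0.0
            W[m + j, m + j] = 1.0
        return W


def build_transition_system(net: HeterogeneousNetwork, tau: float = 0.5) -> TransitionSystem:
    """Assemble and row-normalize the two-layer transition matrix."""
    U = _row_normalize(net.D)
    V = _row_normalize(net.G)
    R = _row_normalize(net.A)
    S = _row_normalize(net.A.T)
    T = np.block([[(1.0 - tau) * U, tau * R], [tau * S, (1.0 - tau) * V]])
    sums = T.sum(axis=1)
    isolated = sums == 0
    W = _row_normalize(T)
    if isolated.any():
        # isolated nodes keep their mass via a self-loop; restart drains it back
        logger.info("%d isolated node(s) in the heterogeneous network", int(isolated.sum()))
        for i in np.flatnonzero(isolated):
            W[i, i] = 1.0
    return TransitionSystem(U=U, V=V, R=R, S=S, W=W, tau=tau, m=net.m, n=net.n, isolated=isolated)


def initial_distribution(net: HeterogeneousNetwork, query_disease: str) -> np.ndarray:
    """Uniform mass on the query disease's direct neighbours; genes start at 0."""
    i = net.disease_index(query_disease)
    nbr = np.flatnonzero(net.D[i] > 0)
    nbr = nbr[nbr != i]
    if nbr.size == 0:
        raise DegenerateNetworkError(
            f"query disease {query_disease!r} has no neighbour in the disease network; "
            "cannot seed the random walk"
        )
    p0 = np.zeros(net.m + net.n)
    p0[nbr] = 1.0 / nbr.size
    return p0


@dataclass
class RWRState:
    """Outcome of one random walk: start, steady state, convergence info."""

    p0: np.ndarray
    p_inf: np.ndarray
    m: int
    n_iter: int
    converged: bool

    @property
    def u_inf(self) -> np.ndarray:
        return self.p_inf[: self.m]

    @property
    def v_inf(self) -> np.ndarray:
        return self.p_inf[self.m :]


def random_walk(
    ts: TransitionSystem, p0: np.ndarray, params: RWRParams | None = None
) -> RWRState:
    """Iterate the restart walk to the stationary distribution."""
    params = params or RWRParams()
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9 or (p0 < 0).any():
        raise InputError("p0 must be a probability vector")
    WT = ts.W.T
    pi = params.pi
    p = p0.copy()
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        p_next = (1.0 - pi) * (WT @ p) + pi * p0
        delta = p_next - p
        p = p_next
        if float(delta @ delta) < params.eps:
            converged = True
            break
    if not converged:
        logger.warning("random walk did not converge in %d iterations", params.max_iter)
    return RWRState(p0=p0, p_inf=p, m=ts.m, n_iter=it, converged=converged)


class AssociationScorer:
    """Caches walks per query disease and serves association p-values.

    One walk per query disease covers every candidate gene (its steady-state
    probability is read from ``v_inf``); pairs with a known association get a
    dedicated leave-one-out walk with that single link removed.  The empirical
    association null pools steady-state scores over non-associated pairs
    (all pairs by default; a seeded subsample when m*n exceeds
    ``null_pair_cap``).
    """

    def __init__(
        self,
        net: HeterogeneousNetwork,
        params: RWRParams | None = None,
        null_pair_cap: int = 1_000_000,
        null_sample_size: int = 100_000,
        seed: int = 0,
    ) -> None:
        self.net = net
        self.params = params or RWRParams()
        self.ts = build_transition_system(net, self.params.tau)
        self.null_pair_cap = null_pair_cap
        self.null_sample_size = null_sample_size
        self.seed = seed
        self._walk_cache: dict[str, RWRState] = {}
        self._loo_cache: dict[tuple[str, str], float] = {}
        self._null: NullDistribution | None = None

    def walk(self, disease: str) -> RWRState:
        if disease not in self._walk_cache:
            p0 = initial_distribution(self.net, disease)
            self._walk_cache[disease] = random_walk(self.ts, p0, self.params)
        return self._walk_cache[disease]

    def gene_score(self, disease: str, gene: str) -> float | None:
        """Steady-state probability of ``gene`` for ``disease`` (leave-one-out aware).

        Returns None when the gene is absent from the gene network.
        """
        j = self.net.gene_index(gene)
        if j is None:
            logger.info("gene %r absent from %s network; association score missing", gene, "gene")
            return None
        i = self.net.disease_index(disease)
        if self.net.A[i, j] == 1.0:
            key = (disease, gene)
            if key not in self._loo_cache:
                W = self.ts.loo_transition(i, j, self.net.A)
                ts_loo = TransitionSystem(
                    U=self.ts.U, V=self.ts.V, R=self.ts.R, S=self.ts.S,
                    W=W, tau=self.ts.tau, m=self.ts.m, n=self.ts.n,
                )
                p0 = initial_distribution(self.net, disease)
                state = random_walk(ts_loo, p0, self.params)
                self._loo_cache[key] = float(state.v_inf[j])
            return self._loo_cache[key]
        return float(self.walk(disease).v_inf[j])

    @property
    def null(self) -> NullDistribution:
        if self._null is None:
            self._null = self.build_null()
        return self._null

    def build_null(self) -> NullDistribution:
        """Steady-state scores of non-associated disease-gene pairs."""
        m, n = self.net.m, self.net.n
        scores: list[np.ndarray] = []
        sample: np.ndarray | None = None
        if m * n > self.null_pair_cap:
            rng = np.random.default_rng(self.seed)
            flat = rng.choice(m * n, size=min(self.null_sample_size, m * n), replace=False)
            sample = np.zeros(m * n, dtype=bool)
            sample[flat] = True
        for i, disease in enumerate(self.net.disease_ids):
            if not (self.net.D[i] > 0).any():
                continue  # isolated disease cannot seed a walk
            free = self.net.A[i] == 0.0
            if sample is not None:
                free &= sample[i * n : (i + 1) * n]
            if not free.any():
                continue
            scores.append(self.walk(disease).v_inf[free])
        if not scores:
            raise ConfigurationError("no non-associated disease-gene pair to build the null")
        pooled = np.concatenate(scores)
        return NullDistribution(source="association", scores=pooled, direction=Direction.LARGER)

    def association_pvalue(self, disease: str, gene: str) -> float | None:
        """Empirical p-value of the pair's association score, or None if gene unknown."""
        score = self.gene_score(disease, gene)
        if score is None:
            return None
        return self.null.pvalue(score)


def association_null(
    net: HeterogeneousNetwork,
    params: RWRParams | None = None,
    null_sample_size: int = 100_000,
    seed: int = 0,
) -> NullDistribution:
    """Convenience wrapper: build the association null for one network."""
    scorer = AssociationScorer(net, params, null_sample_size=null_sample_size, seed=seed)
    return scorer.build_null()
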