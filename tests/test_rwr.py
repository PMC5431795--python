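import numpy as np
import pytest

from indelrank.exceptions import DegenerateNetworkError, InputError
from indelrank.null_models import Direction
from indelrank.rwr import (
    AssociationScorer,
    HeterogeneousNetwork,
    RWRParams,
    build_transition_system,
    initial_distribution,
    random_walk,
)
from indelrank.synthetic import association_scorers


def tiny_net(A=None, D=None, G=None):
    D = np.array([[0.0]]) if D is None else D
    G = np.array([[0.0]]) if G is None else G
    A = np.array([[1.0]]) if A is None else A
    m, n = A.shape
    return HeterogeneousNetwork(
        D=D, G=G, A=A,
        disease_ids=[f"d{i}" for i in range(m)],
        gene_ids=[f"g{j}" for j in range(n)],
    )


class TestTransitionSystem:
    def test_single_pair_hand_normalized(self):
        ts = build_transition_system(tiny_net(), tau=0.5)
        assert np.allclose(ts.W, [[0.0, 1.0], [1.0, 0.0]])

    def test_tau_zero_is_block_diagonal(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = np.array([[0.0, 0.5], [0.5, 0.0]])
        A = np.ones((2, 2))
        ts = build_transition_system(tiny_net(A, D, G), tau=0.0)
        assert np.allclose(ts.W[:2, 2:], 0.0)
        assert np.allclose(ts.W[2:, :2], 0.0)

    def test_disease_without_gene_renormalizes_over_disease_block(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        G = np.array([[0.0, 1.0], [1.0, 0.0]])
        A = np.array([[0.0, 0.0], [1.0, 0.0]])  # disease 0 has no gene
        ts = build_transition_system(tiny_net(A, D, G), tau=0.5)
        assert np.allclose(ts.W[0, 2:], 0.0)
        assert ts.W[0].sum() == pytest.approx(1.0)

    def test_rows_stochastic(self, small_world, tight_params):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets, params=tight_params)
        for s in scorers.values():
            sums = s.ts.W.sum(axis=1)
            assert np.allclose(sums[sums > 0], 1.0, atol=1e-12)
            assert (s.ts.W >= 0).all()


class TestInitialDistribution:
    def test_uniform_over_neighbours_genes_zero(self):
        D = np.zeros((5, 5))
        D[0, 1:] = D[1:, 0] = 0.3  # query d0 has 4 neighbours
        net = tiny_net(np.zeros((5, 2)), D, np.zeros((2, 2)))
        p0 = initial_distribution(net, "d0")
        assert np.allclose(p0[1:5], 0.25)
        assert p0[0] == 0.0  # query itself excluded
        assert np.allclose(p0[5:], 0.0)  # unknown genetic basis: gene mass zero

    def test_single_neighbour_gets_all_mass(self):
        D = np.zeros((2, 2))
        D[0, 1] = D[1, 0] = 1.0
        net = tiny_net(np.zeros((2, 1)), D, np.zeros((1, 1)))
        p0 = initial_distribution(net, "d0")
        assert p0[1] == 1.0

    def test_isolated_query_rejected(self):
        net = tiny_net(np.zeros((2, 1)), np.zeros((2, 2)), np.zeros((1, 1)))
        with pytest.raises(DegenerateNetworkError):
            initial_distribution(net, "d0")


class TestRandomWalk:
    def test_full_restart_returns_p0(self):
        ts = build_transition_system(tiny_net(), tau=0.5)
        p0 = np.array([1.0, 0.0])
        state = random_walk(ts, p0, RWRParams(pi=1.0))
        assert np.allclose(state.p_inf, p0)

    def test_mass_conserved(self, small_world, tight_params):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets, params=tight_params)
        s = scorers["gexp"]
        state = s.walk(world.disease_ids[0])
        assert state.p_inf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.p_inf >= 0).all()

    def test_matches_direct_linear_solve(self, small_world, tight_params):
        """Iterated walk equals pi (I - (1-pi) W^T)^(-1) p0 on a small network."""
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets, params=tight_params)
        for kind in ("gexp", "strg"):
            s = scorers[kind]
            p0 = initial_distribution(s.net, world.disease_ids[1])
            state = random_walk(s.ts, p0, tight_params)
            pi = tight_params.pi
            direct = np.linalg.solve(
                np.eye(len(p0)) - (1 - pi) * s.ts.W.T, pi * p0
            )
            assert np.abs(state.p_inf - direct).max() < 1e-6

    def test_restart_limit_contracts_to_p0(self, small_world):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets)
        s = scorers["gexp"]
        p0 = initial_distribution(s.net, world.disease_ids[0])
        dists = []
        for pi in (0.5, 0.9, 0.99):
            state = random_walk(s.ts, p0, RWRParams(pi=pi, eps=1e-16, max_iter=2000))
            dists.append(np.linalg.norm(state.p_inf - p0))
        assert dists[0] > dists[1] > dists[2]


class TestAssociationScoring:
    def test_planted_module_genes_score_higher(self, small_world, tight_params):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets, params=tight_params)
        s = scorers["gexp"]
        d = world.disease_ids[0]
        mod = world.disease_module[0]
        v = s.walk(d).v_inf
        in_mod = v[world.gene_module == mod]
        out_mod = v[world.gene_module != mod]
        assert in_mod.mean() > out_mod.mean()

    def test_null_counts_nonassociated_pairs(self, small_world):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets)
        s = scorers["gobp"]
        null = s.null
        n_active = sum(1 for i in range(s.net.m) if (s.net.D[i] > 0).any())
        expected = n_active * s.net.n - int(
            s.net.A[[(s.net.D[i] > 0).any() for i in range(s.net.m)]].sum()
        )
        assert len(null) == expected
        assert null.direction is Direction.LARGER

    def test_known_association_recovers_small_p_despite_loo(self, small_world, tight_params):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets, params=tight_params)
        s = scorers["gexp"]
        pvals = []
        for d, g in world.associations.itertuples(index=False, name=None):
            p = s.association_pvalue(d, g)
            if p is not None:
                pvals.append(p)
        # planted links stay enriched after link removal: the p-value
        # distribution sits well below uniform (median 0.5)
        assert np.median(pvals) < 0.35
        assert np.mean(np.asarray(pvals) < 0.5) > 0.75

    def test_absent_gene_yields_missing(self, small_world):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets)
        assert scorers["gexp"].association_pvalue(world.disease_ids[0], "not_a_gene") is None

    def test_association_pvalues_in_unit_interval(self, small_world):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets)
        s = scorers["tsfc"]
        for g in world.gene_ids[:10]:
            p = s.association_pvalue(world.disease_ids[2], g)
            assert p is not None and 0 < p <= 1

    def test_loo_rejected_for_nonassociated_pair(self, small_world):
        _, world, disease_net, gene_nets = small_world
        scorers = association_scorers(world, disease_net, gene_nets)
        s = scorers["gexp"]
        i, j = 0, 0
        if s.net.A[i, j] == 1.0:
            j = 1 if s.net.A[i, 1] == 0 else 2
        with pytest.raises(InputError):
            s.ts.loo_transition(i, j, s.net.A)
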