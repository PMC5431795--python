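import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indelrank.integration import (
    DependenceModel,
    fisher_integrate,
    fit_dependence_model,
    integrate,
    integrate_matrix,
    minp_integrate,
    rra_integrate,
    stouffer_integrate,
)


def zero_corr_model(sources):
    """A dependence model asserting full independence (cov = 4 I)."""
    k = len(sources)
    eye = pd.DataFrame(np.eye(k) * 4.0, index=sources, columns=sources)
    zero = pd.DataFrame(np.zeros((k, k)), index=sources, columns=sources)
    return DependenceModel(
        sources=list(sources), rho_hat=zero, rho_tilde=zero,
        n_pairs=zero + 1000, cov=eye,
    )


class TestFisher:
    def test_single_source_identity(self):
        model = zero_corr_model(["a"])
        assert fisher_integrate({"a": 0.037}, model) == pytest.approx(0.037, abs=1e-12)

    def test_plain_fisher_closed_form(self):
        # U = -2*3*log(0.05) = 17.97; chi2_6 upper tail
        p = fisher_integrate({"a": 0.05, "b": 0.05, "c": 0.05}, None, variant="plain")
        U = -2 * 3 * np.log(0.05)
        assert p == pytest.approx(stats.chi2.sf(U, 6), abs=1e-12)
        assert p == pytest.approx(0.00632, abs=5e-5)

    def test_all_ones_integrate_to_one(self):
        assert fisher_integrate({"a": 1.0, "b": 1.0}, None, variant="plain") == pytest.approx(1.0)

    def test_zero_correlation_model_equals_textbook(self, rng):
        sources = list("abcdefg")
        model = zero_corr_model(sources)
        for _ in range(20):
            pv = dict(zip(sources, rng.uniform(1e-6, 1, size=7)))
            corrected = fisher_integrate(pv, model, variant="corrected")
            plain = fisher_integrate(pv, None, variant="plain")
            assert corrected == pytest.approx(plain, abs=1e-12)

    def test_missing_sources_reduce_df(self):
        model = zero_corr_model(["a", "b", "c"])
        pv = {"a": 0.01, "b": np.nan, "c": None}
        assert fisher_integrate(pv, model) == pytest.approx(0.01, abs=1e-12)


class TestDependenceModel:
    def test_perfect_correlation_cov_close_to_four(self, rng):
        # identical p-value columns -> rho ~ 1 -> cov ~ a1+a2+a3 - a4 term ~ 4
        p = rng.uniform(size=2000)
        df = pd.DataFrame({"a": p, "b": p})
        model = fit_dependence_model(df)
        assert model.cov.loc["a", "b"] == pytest.approx(4.0, abs=5e-3)

    def test_independent_sources_cov_near_zero(self, rng):
        df = pd.DataFrame(rng.uniform(size=(5000, 3)), columns=list("abc"))
        model = fit_dependence_model(df)
        off = model.cov.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_fitted_variance_matches_monte_carlo(self, rng):
        """Equicorrelated copula (rho=0.5, K=4): fitted Var[U] within 5% of MC."""
        rho, K, n = 0.5, 4, 10_000
        z = np.sqrt(rho) * rng.normal(size=(n, 1)) + np.sqrt(1 - rho) * rng.normal(size=(n, K))
        P = stats.norm.cdf(z)
        df = pd.DataFrame(P, columns=list("abcd"))
        model = fit_dependence_model(df)
        fitted_var = float(model.cov.to_numpy().sum())
        mc_var = float((-2 * np.log(P)).sum(axis=1).var(ddof=1))
        assert fitted_var == pytest.approx(mc_var, rel=0.05)

    def test_sparse_pair_cov_zeroed_with_warning(self):
        df = pd.DataFrame(
            {"a": [0.1, 0.2, 0.3, 0.4], "b": [0.2, np.nan, np.nan, np.nan]}
        )
        with pytest.warns(UserWarning):
            model = fit_dependence_model(df)
        assert model.cov.loc["a", "b"] == 0.0


class TestAlternatives:
    def test_single_source_identity_all_methods(self):
        for fn in (minp_integrate, stouffer_integrate, rra_integrate):
            assert fn({"a": 0.2}) == pytest.approx(0.2, abs=1e-12)

    def test_stouffer_two_sources(self):
        # Z = 2 * 1.6449 / sqrt(2) = 2.3262 -> p ~ 0.0100
        p = stouffer_integrate({"a": 0.05, "b": 0.05})
        assert p == pytest.approx(0.0100, abs=2e-4)

    def test_rra_two_sources(self):
        # beta_1 = 1-(0.9)^2 = 0.19, beta_2 = 0.25 -> p = min(2*0.19, 1)
        assert rra_integrate({"a": 0.1, "b": 0.5}) == pytest.approx(0.38, abs=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 5, 10])
    def test_rra_matches_exhaustive_binomial_tail(self, K, rng):
        pv = dict(zip((f"s{i}" for i in range(K)), rng.uniform(size=K)))
        p_sorted = sorted(pv.values())
        betas = []
        for m, pm in enumerate(p_sorted, start=1):
            tail = sum(
                stats.binom.pmf(i, K, pm) for i in range(m, K + 1)
            )
            betas.append(tail)
        expected = min(K * min(betas), 1.0)
        assert rra_integrate(pv) == pytest.approx(expected, abs=1e-10)

    def test_minp_sidak_and_raw(self):
        pv = {"a": 0.02, "b": 0.5, "c": 0.9}
        assert minp_integrate(pv, correct=False) == 0.02
        assert minp_integrate(pv) == pytest.approx(1 - (1 - 0.02) ** 3)


class TestIntegratorProperties:
    METHODS = ("fisher_corrected", "fisher_plain", "minp", "stouffer", "rra")

    def test_permutation_invariance_and_range(self, rng):
        vals = rng.uniform(1e-4, 1, size=6)
        keys = [f"s{i}" for i in range(6)]
        for method in self.METHODS:
            ps = []
            for perm in itertools.islice(itertools.permutations(range(6)), 5):
                pv = {keys[i]: vals[list(perm)[i]] for i in range(6)}
                ps.append(integrate(pv, method=method))
            assert max(ps) - min(ps) < 1e-12
            assert 0 < ps[0] <= 1

    def test_matrix_path_matches_scalar_path(self, rng):
        P = rng.uniform(1e-4, 1, size=(10, 5))
        sources = [f"s{i}" for i in range(5)]
        model = fit_dependence_model(pd.DataFrame(rng.uniform(size=(200, 5)), columns=sources))
        for method in self.METHODS:
            vec = integrate_matrix(P, method, model=model, sources=sources)
            scal = [
                integrate(dict(zip(sources, row)), method=method, model=model) for row in P
            ]
            assert np.allclose(vec, scal, atol=1e-12)

    def test_uniform_inputs_give_calibrated_outputs(self, rng):
        """Under independent uniforms every combiner is a valid p-value."""
        P = rng.uniform(size=(10_000, 10))
        sources = [f"s{i}" for i in range(10)]
        model = fit_dependence_model(pd.DataFrame(P, columns=sources))
        for method in self.METHODS:
            out = integrate_matrix(P, method, model=model, sources=sources)
            assert (out <= 0.05).mean() <= 0.06
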