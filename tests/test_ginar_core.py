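"""Unit and property tests for the GINAR(1) process core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ginarchart import (
    CountSeries,
    GINARParams,
    binomial_thinning,
    build_tpm,
    default_truncation,
    estimate_params,
    innovation_pmf,
    simulate,
    theoretical_acf,
    transition_prob,
)

from conftest import convolution_transition_prob

params_strategy = st.builds(
    GINARParams,
    p=st.floats(0.05, 0.95),
    rho=st.floats(0.0, 0.9),
)


class TestParams:
    def test_domain_validation(self):
        for p, rho in [(0.0, 0.1), (1.0, 0.1), (0.5, 1.0), (0.5, -0.1), (-1, 0.5)]:
            with pytest.raises(ValueError):
                GINARParams(p=p, rho=rho)
        # rho = 0 is the admitted iid limit
        assert GINARParams(p=0.5, rho=0.0).rho == 0.0

    def test_marginal_mean_decreasing_in_p(self):
        means = [GINARParams(p, 0.2).marginal_mean() for p in np.linspace(0.05, 0.95, 20)]
        assert np.all(np.diff(means) < 0)
        assert GINARParams(0.63, 0.165).marginal_mean() == pytest.approx(0.37 / 0.63)

    def test_kalmykov_domain(self):
        assert GINARParams(0.63, 0.165).kalmykov_domain()
        assert not GINARParams(0.1, 0.165).kalmykov_domain()
        # boundary rho/(rho+1) == p is excluded (strict inequality);
        # 0.25/1.25 is exactly representable, so the comparison is exact
        assert not GINARParams(0.2, 0.25).kalmykov_domain()


class TestInnovationPmf:
    def test_zero_mass_worked_value(self):
        pars = GINARParams(0.63, 0.165)
        assert innovation_pmf(0, pars) == pytest.approx(0.63 * 0.835 + 0.165)
        assert innovation_pmf(0, pars) == pytest.approx(0.69105)

    def test_iid_limit_is_plain_geometric(self):
        pars = GINARParams(0.42, 0.0)
        j = np.arange(30)
        np.testing.assert_allclose(innovation_pmf(j, pars), (1 - 0.42) ** j * 0.42)

    def test_negative_support_rejected(self):
        with pytest.raises(ValueError):
            innovation_pmf(-1, GINARParams(0.5, 0.3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(params_strategy)
    def test_normalises(self, pars):
        J = default_truncation(pars) + 1
        mass = innovation_pmf(np.arange(J + 1), pars)
        assert np.all(mass >= 0)
        assert mass.sum() == pytest.approx(1.0, abs=1e-11)


class TestTransitionProb:
    def test_row_zero_is_innovation(self):
        pars = GINARParams(0.63, 0.165)
        for j in range(10):
            assert transition_prob(0, j, pars) == pytest.approx(
                innovation_pmf(j, pars), abs=1e-15
            )

    def test_worked_value_i1_j0(self):
        # thinning must kill the single survivor, innovation must be 0
        pars = GINARParams(0.63, 0.165)
        assert transition_prob(1, 0, pars) == pytest.approx(0.835 * 0.69105, abs=1e-12)

    def test_matches_convolution_oracle(self, rng):
        for _ in range(20):
            pars = GINARParams(p=rng.uniform(0.1, 0.9), rho=rng.uniform(0.0, 0.9))
            i = int(rng.integers(0, 51))
            for j in rng.integers(0, 51, size=8):
                assert transition_prob(i, int(j), pars) == pytest.approx(
                    convolution_transition_prob(i, int(j), pars), abs=1e-12
                )

    def test_rows_normalise(self):
        pars = GINARParams(0.3, 0.6)
        J = 400
        for i in range(11):
            total = sum(transition_prob(i, j, pars) for j in range(J))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_states_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(-1, 0, GINARParams(0.5, 0.3))
        with pytest.raises(ValueError):
            transition_prob(0, -2, GINARParams(0.5, 0.3))


class TestBuildTpm:
    def test_row_zero_and_shape(self, illus_params):
        tpm = build_tpm(illus_params, n=5)
        assert tpm.entries.shape == (6, 6)
        np.testing.assert_allclose(
            tpm.entries[0], innovation_pmf(np.arange(6), illus_params), atol=1e-15
        )

    def test_tail_mass_accounting(self, illus_params):
        tpm = build_tpm(illus_params, n=40)
        assert np.all(tpm.tail_mass >= 0)
        np.testing.assert_allclose(tpm.entries.sum(axis=1) + tpm.tail_mass, 1.0)
        # default truncation rule drives the marginal tail below 1e-12
        n_default = default_truncation(illus_params)
        assert (1 - illus_params.p) ** (n_default + 1) < 1e-12
        assert (1 - illus_params.p) ** n_default >= 1e-12

    def test_geometric_marginal_is_stationary(self, illus_params):
        tpm = build_tpm(illus_params, n=100)
        pi = illus_params.marginal_pmf(np.arange(101))
        resid = pi @ tpm.entries - pi
        assert np.max(np.abs(resid)) < tpm.tail_mass.max() + pi[-1] + 1e-13

    def test_iid_limit_rows_identical(self):
        pars = GINARParams(0.63, 0.0)
        tpm = build_tpm(pars, n=12)
        geo = pars.marginal_pmf(np.arange(13))
        for row in tpm.entries:
            np.testing.assert_allclose(row, geo, atol=1e-15)

    def test_large_truncation_overflow_safe(self):
        tpm = build_tpm(GINARParams(0.2, 0.5), n=200)
        assert np.all(np.isfinite(tpm.entries))
        assert np.all(tpm.entries >= 0) and np.all(tpm.entries <= 1)


class TestAcfAndThinning:
    def test_theoretical_acf(self):
        assert theoretical_acf(0, GINARParams(0.5, 0.3)) == 1.0
        assert theoretical_acf(1, GINARParams(0.63, 0.165)) == pytest.approx(0.165)
        assert theoretical_acf(3, GINARParams(0.5, 0.5)) == pytest.approx(0.125)
        with pytest.raises(ValueError):
            theoretical_acf(-1, GINARParams(0.5, 0.3))

    def test_thinning_edge_cases(self, rng):
        assert binomial_thinning(0, 0.7, rng) == 0
        assert binomial_thinning(10, 1.0, rng) == 10
        assert binomial_thinning(10, 0.0, rng) == 0
        with pytest.raises(ValueError):
            binomial_thinning(3, 1.5, rng)
        with pytest.raises(ValueError):
            binomial_thinning(-1, 0.5, rng)

    def test_thinning_is_binomial(self, rng):
        n, x, rho = 100_000, 20, 0.3
        draws = np.array([binomial_thinning(x, rho, rng) for _ in range(n)])
        se = np.sqrt(x * rho * (1 - rho) / n)
        assert abs(draws.mean() - x * rho) < 3 * se
        assert draws.min() >= 0 and draws.max() <= x


class TestSimulate:
    def test_reproducible_and_typed(self, illus_params):
        s1 = simulate(illus_params, 500, seed=7)
        s2 = simulate(illus_params, 500, seed=7)
        np.testing.assert_array_equal(s1.values, s2.values)
        assert s1.values.dtype == np.int64 and np.all(s1.values >= 0)
        with pytest.raises(ValueError):
            simulate(illus_params, 0)

    def test_stationary_moments_and_acf(self, illus_params):
        T = 100_000
        s = simulate(illus_params, T, seed=3).values.astype(float)
        mean, var = illus_params.marginal_mean(), illus_params.marginal_var()
        # ACF inflates the variance of the sample mean by (1+rho)/(1-rho)
        se_mean = np.sqrt(var / T * (1 + 0.165) / (1 - 0.165))
        assert abs(s.mean() - mean) < 3 * se_mean
        c = s - s.mean()
        for k in (1, 2, 3):
            acf_k = np.dot(c[:-k], c[k:]) / (T * s.var())
            assert abs(acf_k - 0.165**k) < 3 / np.sqrt(T) + 0.01

    def test_iid_limit_uncorrelated(self):
        s = simulate(GINARParams(0.63, 0.0), 50_000, seed=5).values.astype(float)
        c = s - s.mean()
        acf1 = np.dot(c[:-1], c[1:]) / (s.size * s.var())
        assert abs(acf1) < 3 / np.sqrt(s.size)

    def test_fixed_init_used(self, illus_params):
        # from a huge start, thinning survivors dominate the first step
        s = simulate(illus_params, 1, init=10_000, seed=1)
        assert s.values[0] > 1000


class TestEstimateParams:
    def test_mean_inversion_worked_value(self):
        values = np.concatenate([np.ones(5872, dtype=int), np.zeros(4128, dtype=int)])
        est = estimate_params(CountSeries(values=values))
        assert round(est.p, 2) == 0.63

    def test_round_trip_recovery(self, illus_params):
        s = simulate(illus_params, 100_000, seed=11)
        est = estimate_params(s)
        assert est.p == pytest.approx(0.63, abs=0.01)
        assert est.rho == pytest.approx(0.165, abs=0.02)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_params(CountSeries(values=np.zeros(50, dtype=int)))
        with pytest.raises(ValueError):
            estimate_params(CountSeries(values=np.full(50, 3)))
        with pytest.raises(ValueError):
            estimate_params(CountSeries(values=np.array([1, 2, 3])))
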