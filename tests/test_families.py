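"""Distributional identities and sampling correctness for the seven families."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import integrate, stats

from survunc.families import (
    DivergingMeanError,
    FamilyParams,
    ParameterDomainError,
    TimeGrid,
    analytic_mean,
    cumulative_hazard,
    hazard,
    log_density,
    restricted_mean,
    sample,
    survival,
)

TIMES = np.array([0.05, 0.3, 0.7, 1.0, 1.8, 3.2, 6.0, 10.0])

# a representative spread of valid parameter sets per family
PARAM_SETS = {
    "exponential": [{"lam": 0.2}, {"lam": 1.11}, {"lam": 4.0}],
    "weibull": [{"lam": 1.0, "gamma": 0.6}, {"lam": 0.97, "gamma": 2.0},
                {"lam": 2.5, "gamma": 1.0}],
    "gompertz": [{"lam": 0.9, "theta": 0.5}, {"lam": 1.2, "theta": -0.4},
                 {"lam": 0.5, "theta": 0.0}],
    "gamma": [{"shape": 0.5, "rate": 0.56}, {"shape": 2.0, "rate": 2.22},
              {"shape": 1.0, "rate": 1.5}],
    "loglogistic": [{"alpha": 1.75, "beta": 2.0}, {"alpha": 0.8, "beta": 0.9},
                    {"alpha": 3.0, "beta": 4.0}],
    "lognormal": [{"mu": -0.51, "sigma": 0.9}, {"mu": 0.4, "sigma": 0.3},
                  {"mu": -1.0, "sigma": 1.6}],
    "gengamma": [{"lam": -0.5, "beta": 0.2, "sigma": 0.8},
                 {"lam": 1.4, "beta": -0.3, "sigma": 0.6},
                 {"lam": 0.3, "beta": 0.0, "sigma": 1.1}],
}

ALL_CASES = [(fam, p) for fam, sets in PARAM_SETS.items() for p in sets]


@pytest.mark.parametrize("family,params", ALL_CASES)
def test_cumulative_hazard_is_minus_log_survival(family, params):
    fp = FamilyParams(family, params)
    H = cumulative_hazard(fp, TIMES)
    S = survival(fp, TIMES)
    assert np.all(np.abs(H + np.log(S)) < 1e-8)
    assert np.all(np.diff(H) >= 0)
    assert cumulative_hazard(fp, 0.0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("family,params", ALL_CASES)
def test_survival_boundary_and_monotonicity(family, params):
    fp = FamilyParams(family, params)
    S = survival(fp, TIMES)
    assert survival(fp, 0.0) == pytest.approx(1.0)
    assert np.all((S >= 0) & (S <= 1))
    assert np.all(np.diff(S) <= 1e-15)


@pytest.mark.parametrize("family,params", ALL_CASES)
def test_density_equals_hazard_times_survival(family, params):
    fp = FamilyParams(family, params)
    f = np.exp(log_density(fp, TIMES))
    assert np.all(np.abs(f - hazard(fp, TIMES) * survival(fp, TIMES)) < 1e-10)


def test_exponential_closed_values():
    fp = FamilyParams("exponential", {"lam": np.log(2)})
    assert survival(fp, 1.0) == pytest.approx(0.5)
    fp = FamilyParams("exponential", {"lam": 1.16})
    assert np.all(hazard(fp, TIMES) == 1.16)
    assert cumulative_hazard(fp, 2.0) == pytest.approx(2.32)
    assert log_density(FamilyParams("exponential", {"lam": 1.0}), 2.0) == pytest.approx(-2.0)


def test_lognormal_density_at_one():
    fp = FamilyParams("lognormal", {"mu": 0.0, "sigma": 1.0})
    assert log_density(fp, 1.0) == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)))


def test_gengamma_survival_matches_hazard_quadrature():
    """S(t) must equal exp(-integral of h) for the gen. gamma."""
    fp = FamilyParams("gengamma", {"lam": -0.5, "beta": 0.2, "sigma": 0.8})
    H, _ = integrate.quad(lambda u: float(hazard(fp, u)), 0.0, 1.3, limit=200)
    assert survival(fp, 1.3) == pytest.approx(np.exp(-H), rel=1e-8)


def test_loglogistic_hazard_matches_finite_difference():
    fp = FamilyParams("loglogistic", {"alpha": 1.5, "beta": 2.0})
    t, h = 0.9, 1e-6
    fd = -(np.log(survival(fp, t + h)) - np.log(survival(fp, t - h))) / (2 * h)
    assert hazard(fp, t) == pytest.approx(fd, rel=1e-6)


class TestNesting:
    """Each reduction of a flexible family must reproduce its special case."""

    def test_weibull_gamma_one_is_exponential(self):
        wb = FamilyParams("weibull", {"lam": 2.0, "gamma": 1.0})
        assert np.allclose(hazard(wb, TIMES), 2.0)
        assert hazard(wb, 0.7) == pytest.approx(2.0)

    def test_gamma_shape_one_is_exponential(self):
        gm = FamilyParams("gamma", {"shape": 1.0, "rate": 1.5})
        ex = FamilyParams("exponential", {"lam": 1.5})
        assert np.allclose(survival(gm, TIMES), survival(ex, TIMES), atol=1e-12)

    def test_gompertz_theta_zero_is_exponential(self):
        gz = FamilyParams("gompertz", {"lam": 0.5, "theta": 0.0})
        assert cumulative_hazard(gz, 3.0) == pytest.approx(1.5)
        tiny = FamilyParams("gompertz", {"lam": 0.5, "theta": 1e-10})
        assert cumulative_hazard(tiny, 3.0) == pytest.approx(1.5, rel=1e-6)

    def test_gengamma_lam_one_is_weibull(self):
        sigma, beta = 0.7, 0.3
        gg = FamilyParams("gengamma", {"lam": 1.0, "beta": beta, "sigma": sigma})
        wb = FamilyParams(
            "weibull", {"lam": float(np.exp(-beta / sigma)), "gamma": 1.0 / sigma})
        assert np.allclose(hazard(gg, TIMES), hazard(wb, TIMES), rtol=1e-10)

    def test_gengamma_small_lam_approaches_lognormal(self):
        # the residual difference is O(lam * |w|^3), so compare at times with
        # moderate standardised log-time w rather than in the far tails
        gg = FamilyParams("gengamma", {"lam": 1e-4, "beta": 0.3, "sigma": 0.7})
        ln = FamilyParams("lognormal", {"mu": 0.3, "sigma": 0.7})
        t = TIMES[(TIMES >= 0.3) & (TIMES <= 10.0)]
        assert np.allclose(hazard(gg, t), hazard(ln, t), rtol=1e-3)


class TestSampling:
    def test_reproducible_with_same_seed(self):
        fp = FamilyParams("gengamma", {"lam": 0.3, "beta": 0.0, "sigma": 1.1})
        a = sample(fp, 5, np.random.default_rng(7))
        b = sample(fp, 5, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_exponential_mean_matches_design(self):
        fp = FamilyParams("exponential", {"lam": 1.0 / 0.9})
        x = sample(fp, 10**6, np.random.default_rng(11))
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 0.9) < 3 * se

    @pytest.mark.parametrize("family,params", [
        ("weibull", {"lam": 1.0, "gamma": 2.0}),
        ("gompertz", {"lam": 1.2, "theta": 0.5}),
        ("loglogistic", {"alpha": 1.75, "beta": 2.0}),
        ("gengamma", {"lam": -0.5, "beta": 0.2, "sigma": 0.8}),
    ])
    def test_empirical_cdf_matches_analytic(self, family, params):
        fp = FamilyParams(family, params)
        x = sample(fp, 10**5, np.random.default_rng(3))
        ks = stats.kstest(x, lambda v: 1.0 - np.asarray(survival(fp, v)))
        # 1% critical value of the KS statistic, n = 1e5
        assert ks.statistic < 1.63 / np.sqrt(x.size)

    def test_improper_gompertz_yields_infinite_latents(self):
        fp = FamilyParams("gompertz", {"lam": 0.3, "theta": -1.0})
        x = sample(fp, 2000, np.random.default_rng(5))
        assert np.isinf(x).any()          # the never-dying fraction
        assert np.all(x[np.isfinite(x)] > 0)


class TestRestrictedMean:
    @pytest.mark.parametrize("family,params", ALL_CASES)
    def test_matches_quadrature_oracle(self, family, params):
        fp = FamilyParams(family, params)
        for tau in (0.5, 10.0):
            oracle, _ = integrate.quad(
                lambda u: float(survival(fp, u)), 0, tau, limit=200, epsabs=1e-10)
            assert restricted_mean(fp, tau) == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("family,params", ALL_CASES)
    def test_monotone_in_horizon_and_bounded(self, family, params):
        fp = FamilyParams(family, params)
        horizons = [0.25, 1.0, 4.0, 10.0]
        values = [restricted_mean(fp, h) for h in horizons]
        assert all(np.diff(values) >= -1e-12)
        assert all(0 < v <= h for v, h in zip(values, horizons))

    def test_vanishes_as_horizon_shrinks(self):
        fp = FamilyParams("weibull", {"lam": 1.0, "gamma": 2.0})
        assert restricted_mean(fp, 1e-8) < 1e-7

    def test_exponential_infinite_horizon(self):
        fp = FamilyParams("exponential", {"lam": 1.0 / 0.9})
        assert restricted_mean(fp, np.inf) == pytest.approx(0.9)

    def test_improper_gompertz_raises(self):
        fp = FamilyParams("gompertz", {"lam": 1.2, "theta": -0.4})
        with pytest.raises(DivergingMeanError):
            restricted_mean(fp, np.inf)
        assert restricted_mean(fp, 10.0) > 0  # finite horizon is fine

    def test_analytic_means(self):
        assert analytic_mean(FamilyParams("gamma", {"shape": 2.0, "rate": 2.0})) == 1.0
        wb = FamilyParams("weibull", {"lam": 1.0, "gamma": 2.0})
        from scipy.special import gamma as gfun
        assert analytic_mean(wb) == pytest.approx(gfun(1.5))


class TestValidation:
    @pytest.mark.parametrize("family,params", [
        ("exponential", {"lam": -1.0}),
        ("weibull", {"lam": 1.0, "gamma": 0.0}),
        ("lognormal", {"mu": 0.0, "sigma": -0.1}),
        ("gengamma", {"lam": 0.5, "beta": 0.0, "sigma": 0.0}),
    ])
    def test_domain_violations_raise(self, family, params):
        with pytest.raises(ParameterDomainError):
            FamilyParams(family, params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterDomainError):
            FamilyParams("genf", {"lam": 1.0})

    def test_singular_hazard_at_zero_raises(self):
        fp = FamilyParams("weibull", {"lam": 1.0, "gamma": 0.6})
        with pytest.raises(ValueError):
            hazard(fp, 0.0)

    def test_time_grid_invariants(self):
        grid = TimeGrid(np.array([0.1, 0.5, 2.0]), observed_end=1.0)
        assert grid.extrapolated.tolist() == [False, False, True]
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.5, 0.1]), observed_end=0.3)
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.1, 0.5]), observed_end=2.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    lam=st.floats(0.05, 5.0),
    gamma=st.floats(0.3, 4.0),
    t=st.floats(0.01, 20.0),
)
def test_weibull_identities_property(lam, gamma, t):
    fp = FamilyParams("weibull", {"lam": lam, "gamma": gamma})
    assume(cumulative_hazard(fp, t) < 500)  # keep S(t) away from underflow
    assert cumulative_hazard(fp, t) == pytest.approx(-np.log(survival(fp, t)), abs=1e-8)
    f = np.exp(log_density(fp, t))
    assert f == pytest.approx(hazard(fp, t) * survival(fp, t), abs=1e-10)
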