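"""Exact, delta and multivariate-normal uncertainty propagation."""

import numpy as np
import pytest
from scipy import integrate

import survunc as su
from survunc.families import FamilyParams, TimeGrid, restricted_mean, survival
from survunc.fitting import FittedModel, fit_exponential_closed_form, fit_mle
from survunc.uncertainty import (
    band_transform,
    delta_variance,
    exact_exponential_uncertainty,
    mean_survival_with_ci,
    mvn_uncertainty,
    parameter_draws,
)


def exponential_model(lam: float, n_events: int) -> FittedModel:
    """Hand-built exponential fit with the closed-form variance."""
    return FittedModel(
        family="exponential",
        params=FamilyParams("exponential", {"lam": lam}),
        theta=np.array([np.log(lam)]),
        vcov=np.array([[1.0 / n_events]]),
        loglik=0.0, n_events=n_events, n=n_events, converged=True,
    )


GRID = TimeGrid(np.linspace(0.1, 100.0, 40), observed_end=1.0)


class TestExactExponential:
    def test_hazard_variance_constant_in_time(self):
        fm = exponential_model(0.3, 3)
        curve, mean = exact_exponential_uncertainty(fm, GRID)
        assert np.all(curve.se**2 == pytest.approx(0.03))  # lam^2/Ne at all t
        width = curve.upper - curve.lower
        assert np.ptp(width) == pytest.approx(0.0, abs=1e-12)

    def test_mean_survival_variance(self):
        fm = exponential_model(0.3, 3)
        _, mean = exact_exponential_uncertainty(fm, GRID)
        assert mean.point == pytest.approx(1.0 / 0.3)
        assert mean.se**2 == pytest.approx(1.0 / (0.3**2 * 3))  # ~= 3.704
        assert mean.lower < mean.point < mean.upper

    def test_wrong_family_rejected(self, flat_data):
        fm = fit_mle(flat_data, "weibull")
        with pytest.raises(ValueError, match="exponential"):
            exact_exponential_uncertainty(fm, GRID)


class TestDelta:
    def test_identity_functional_returns_vcov_entry(self, flat_data):
        fm = fit_mle(flat_data, "weibull")
        var = delta_variance(fm, lambda fp: float(np.log(fp["lam"])))
        assert var == pytest.approx(fm.vcov[0, 0], rel=1e-6)

    def test_exponential_hazard_reproduces_closed_form(self, flat_data):
        fm = fit_exponential_closed_form(flat_data)
        lam, ne = fm.params["lam"], fm.n_events
        for t in (0.5, 2.0, 50.0):
            var = delta_variance(fm, lambda fp: float(su.hazard(fp, t)))
            assert var == pytest.approx(lam**2 / ne, abs=1e-8)


class TestMVN:
    def test_degenerate_vcov_gives_zero_band(self, flat_data):
        fm = fit_exponential_closed_form(flat_data)
        degenerate = FittedModel(**{**fm.__dict__, "vcov": np.zeros((1, 1))})
        curve = mvn_uncertainty(degenerate, "hazard", GRID, B=200,
                                rng=np.random.default_rng(0))
        assert np.all(curve.se == 0)
        assert np.all(curve.upper - curve.lower == 0)

    def test_reproducible_with_same_seed(self, flat_data):
        fm = fit_mle(flat_data, "weibull")
        a = mvn_uncertainty(fm, "hazard", GRID, B=300, rng=np.random.default_rng(9))
        b = mvn_uncertainty(fm, "hazard", GRID, B=300, rng=np.random.default_rng(9))
        assert np.array_equal(a.se, b.se) and np.array_equal(a.lower, b.lower)

    def test_exponential_se_matches_analytic(self, flat_data):
        fm = fit_exponential_closed_form(flat_data)
        curve = mvn_uncertainty(fm, "hazard", GRID, B=10**5,
                                rng=np.random.default_rng(4))
        target = fm.params["lam"] / np.sqrt(fm.n_events)
        assert np.all(np.abs(curve.se / target - 1) < 0.02)

    def test_bands_respect_ranges(self, increasing_data):
        fm = fit_mle(increasing_data, "gompertz")
        rng = np.random.default_rng(2)
        hz = mvn_uncertainty(fm, "hazard", GRID, B=500, rng=rng)
        sv = mvn_uncertainty(fm, "survival", GRID, B=500, rng=rng)
        assert np.all(hz.lower >= 0)
        assert np.all((sv.lower >= 0) & (sv.upper <= 1))
        assert np.all(hz.lower <= hz.point + 1e-12)
        assert np.all(hz.upper >= hz.point - 1e-12)

    def test_non_psd_vcov_rejected(self, flat_data):
        fm = fit_exponential_closed_form(flat_data)
        bad = FittedModel(**{**fm.__dict__, "vcov": np.array([[-1.0]])})
        with pytest.raises(np.linalg.LinAlgError, match="PSD|positive"):
            parameter_draws(bad, 100, np.random.default_rng(0))


class TestMeanSurvival:
    def test_exact_exponential_infinite_horizon(self, flat_data):
        fm = fit_exponential_closed_form(flat_data)
        est = mean_survival_with_ci(fm, np.inf, method="exact")
        assert est.point == pytest.approx(1.0 / fm.params["lam"])
        assert est.se == pytest.approx(1.0 / (fm.params["lam"] * np.sqrt(fm.n_events)))

    def test_mvn_se_converges_in_draws(self, increasing_data):
        fm = fit_mle(increasing_data, "weibull")
        small = mean_survival_with_ci(fm, 10.0, method="mvn", B=1000,
                                      rng=np.random.default_rng(21))
        large = mean_survival_with_ci(fm, 10.0, method="mvn", B=10**4,
                                      rng=np.random.default_rng(22))
        assert abs(small.se / large.se - 1) < 0.10

    def test_diverging_mean_propagates(self, flat_data):
        fm = fit_mle(flat_data, "gompertz")
        if fm.params["theta"] < 0:
            with pytest.raises(su.DivergingMeanError):
                mean_survival_with_ci(fm, np.inf, method="delta")

    def test_shared_draws_are_coherent(self, increasing_data):
        """Mean-survival draws must integrate the survival draws: spot-check
        that the same parameter sample drives both functionals."""
        fm = fit_mle(increasing_data, "gamma")
        draws = parameter_draws(fm, 200, np.random.default_rng(6))
        est = mean_survival_with_ci(fm, 10.0, method="mvn", draws=draws)
        from survunc.fitting import from_estimation_scale
        rng = np.random.default_rng(1)
        for b in rng.integers(0, 200, 10):
            fp = from_estimation_scale("gamma", draws[b])
            quad, _ = integrate.quad(lambda u: float(survival(fp, u)), 0, 10.0,
                                     limit=200)
            assert restricted_mean(fp, 10.0) == pytest.approx(quad, abs=1e-6)
        assert est.lower <= est.point <= est.upper


class TestBandTransform:
    def test_logit_round_trip(self):
        from scipy.special import expit, logit
        assert logit(0.5) == 0.0
        assert expit(logit(0.731)) == pytest.approx(0.731)

    def test_percentile_bands_invariant_under_monotone_transform(self, flat_data):
        fm = fit_mle(flat_data, "weibull")
        curve = mvn_uncertainty(fm, "hazard", GRID, B=400,
                                rng=np.random.default_rng(5))
        logged = band_transform(curve, "log")
        assert np.array_equal(logged.lower, curve.lower)
        assert np.array_equal(logged.upper, curve.upper)
        assert logged.transform == "log"

    def test_normal_approx_log_band_matches_percentiles_at_large_b(self, flat_data):
        """For the exponential the MVN hazard draws are exactly log-normal, so
        the log-scale normal band and the percentile band coincide."""
        fm = fit_exponential_closed_form(flat_data)
        grid = TimeGrid(np.array([0.5, 2.0]), 1.0)
        exact_curve, _ = exact_exponential_uncertainty(fm, grid)
        mvn_curve = mvn_uncertainty(fm, "hazard", grid, B=10**5,
                                    rng=np.random.default_rng(8))
        assert mvn_curve.lower == pytest.approx(exact_curve.lower, rel=0.02)
        assert mvn_curve.upper == pytest.approx(exact_curve.upper, rel=0.02)

    def test_out_of_domain_values_rejected(self, flat_data):
        """Normal-approximation bands cannot be rebuilt on a scale whose
        domain the point estimate violates."""
        import dataclasses
        from survunc.uncertainty import delta_curve
        fm = fit_mle(flat_data, "weibull")
        curve = delta_curve(fm, "hazard", GRID, transform="identity")
        bad = dataclasses.replace(curve, point=curve.point - curve.point.max() - 1.0)
        with pytest.raises(ValueError, match="log"):
            band_transform(bad, "log")

    def test_tidy_export_columns(self, flat_data):
        fm = fit_mle(flat_data, "exponential")
        curve = mvn_uncertainty(fm, "hazard", GRID, B=150,
                                rng=np.random.default_rng(1))
        df = curve.to_frame()
        assert list(df.columns) == ["time", "quantity", "method", "point", "se",
                                    "lower", "upper", "extrapolated"]
        assert df["extrapolated"].sum() == int(np.sum(GRID.times > 1.0))
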