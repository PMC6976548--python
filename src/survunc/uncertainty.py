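"""Uncertainty propagation from fitted models to hazard, survival and mean
survival.

Three routes are provided, mirroring how uncertainty about functionals of
survival-model parameters is quantified in practice:

* **exact** — closed-form variances, available only for the exponential
  family, where Var(h_hat(t)) = lambda_hat**2 / N_e for every t (the hazard
  band does not fan out) and Var(mu_hat) = 1 / (lambda_hat**2 N_e);
* **delta** — first-order propagation Var(g) = grad(g)' Var(theta) grad(g),
  with the gradient taken numerically on the estimation scale;
* **mvn** — Monte-Carlo propagation: draw theta_b ~ N(theta_hat,
  Var(theta_hat)) on the estimation scale, push each draw through the
  functional, and summarise with the plug-in variance
  (1/B) sum_b [g(theta_b) - g(theta_hat)]**2 and percentile intervals.

Sampling on the estimation scale guarantees every draw satisfies the
family's parameter domain.  Percentile bands commute with monotone
transforms; normal-approximation bands (exact/delta) are built on a
transformed scale — log for hazards and means, logit for survival — and
back-transformed, which keeps hazard bands non-negative and survival bands
inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .families import (
    DivergingMeanError,
    FamilyParams,
    TimeGrid,
    hazard,
    restricted_mean,
    survival,
)
from .fitting import FittedModel, from_estimation_scale

__all__ = [
    "CurveEstimate",
    "MeanSurvivalEstimate",
    "BASE_SEED",
    "parameter_draws",
    "exact_exponential_uncertainty",
    "delta_variance",
    "mvn_uncertainty",
    "mean_survival_with_ci",
    "band_transform",
]

#: default base seed recorded in pipeline outputs
BASE_SEED = 20191125

_Z95 = float(stats.norm.ppf(0.975))

_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y),
    "log": (np.log, np.exp),
    "logit": (special.logit, special.expit),
}


@dataclass(frozen=True)
class CurveEstimate:
    """Pointwise estimate of a hazard or survival curve with 95% bands."""

    grid: TimeGrid
    quantity: str                 # "hazard" | "survival"
    method: str                   # "exact" | "delta" | "mvn"
    point: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    transform: str = "identity"   # scale the band was built on

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per grid time."""
        return pd.DataFrame(
            {
                "time": self.grid.times,
                "quantity": self.quantity,
                "method": self.method,
                "point": self.point,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
                "extrapolated": self.grid.extrapolated,
            }
        )


@dataclass(frozen=True)
class MeanSurvivalEstimate:
    """(Restricted) mean survival with SE and 95% CI at a stated horizon."""

    point: float
    se: float
    lower: float
    upper: float
    horizon: float
    method: str

    def summary(self) -> dict:
        return {
            "mean_survival": self.point,
            "se": self.se,
            "ci95": [self.lower, self.upper],
            "horizon_years": self.horizon,
            "method": self.method,
        }


def _quantity_fn(quantity: str):
    if quantity == "hazard":
        return hazard
    if quantity == "survival":
        return survival
    raise ValueError(f"quantity must be 'hazard' or 'survival', got {quantity!r}")


def parameter_draws(fm: FittedModel, B: int, rng: np.random.Generator) -> np.ndarray:
    """``B`` multivariate-normal draws of the estimation-scale parameters.

    One call per model, shared across all functionals, keeps hazard,
    survival and mean-survival draws coherent (draw b uses the same
    theta_b everywhere).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    vcov = np.asarray(fm.vcov, dtype=float)
    eigvals = np.linalg.eigvalsh(0.5 * (vcov + vcov.T))
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals).max()):
        raise np.linalg.LinAlgError(
            "Var(theta_hat) is not positive semi-definite; repair it (e.g. "
            "nearest-PSD projection) before sampling"
        )
    return rng.multivariate_normal(fm.theta, vcov, size=B, check_valid="ignore")


def exact_exponential_uncertainty(
    fm: FittedModel, grid: TimeGrid, horizon: float = np.inf
) -> tuple[CurveEstimate, MeanSurvivalEstimate]:
    """Closed-form exponential uncertainty for the hazard curve and the mean.

    The hazard variance lambda_hat**2 / N_e is constant in t, so the 95%
    band has the same width at every grid point, observed or extrapolated.
    Bands use the log-scale normal approximation (Var(ln lambda_hat) =
    1/N_e), keeping them positive.
    """
    if fm.family != "exponential":
        raise ValueError("exact formulas are only available for the exponential family")
    lam = fm.params["lam"]
    ne = fm.n_events
    se_h = lam / np.sqrt(ne)
    width = np.exp(_Z95 / np.sqrt(ne))  # multiplicative, from Var(ln lam)=1/Ne
    t = grid.times
    curve = CurveEstimate(
        grid=grid, quantity="hazard", method="exact",
        point=np.full_like(t, lam), se=np.full_like(t, se_h),
        lower=np.full_like(t, lam / width), upper=np.full_like(t, lam * width),
        transform="log",
    )
    mu = restricted_mean(fm.params, horizon)
    if np.isinf(horizon):
        se_mu = 1.0 / (lam * np.sqrt(ne))  # Var = 1/(lam^2 Ne)
    else:
        se_mu = float(np.sqrt(delta_variance(
            fm, lambda fp: restricted_mean(fp, horizon))))
    mean = MeanSurvivalEstimate(
        point=mu, se=se_mu,
        lower=mu * np.exp(-_Z95 * se_mu / mu), upper=mu * np.exp(_Z95 * se_mu / mu),
        horizon=horizon, method="exact",
    )
    return curve, mean


def delta_variance(fm: FittedModel, g, rel_step: float = 1e-6) -> float:
    """First-order (delta-method) variance of a scalar functional ``g``.

    ``g`` maps a :class:`FamilyParams` to a float; its gradient with respect
    to the estimation-scale parameters is taken by central differences.
    """
    theta = fm.theta
    h = rel_step * np.maximum(1.0, np.abs(theta))
    grad = np.empty_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = h[i]
        try:
            hi = g(from_estimation_scale(fm.family, theta + e))
            lo = g(from_estimation_scale(fm.family, theta - e))
        except Exception as err:
            raise ValueError(
                f"gradient evaluation failed for component {i} of {fm.family}"
            ) from err
        grad[i] = (hi - lo) / (2.0 * h[i])
    if not np.all(np.isfinite(grad)):
        raise ValueError(f"non-finite gradient for {fm.family} delta variance")
    return float(grad @ fm.vcov @ grad)


def delta_curve(
    fm: FittedModel, quantity: str, grid: TimeGrid, transform: str = "log"
) -> CurveEstimate:
    """Delta-method curve with bands built on ``transform`` scale."""
    fn = _quantity_fn(quantity)
    t = grid.times
    point = np.asarray(fn(fm.params, t), dtype=float)
    var = np.array([
        delta_variance(fm, lambda fp, tt=tt: float(fn(fp, tt))) for tt in t
    ])
    se = np.sqrt(np.maximum(var, 0.0))
    fwd, inv = _TRANSFORMS[transform]
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "identity":
            se_tr = se
        elif transform == "log":
            se_tr = se / point
        else:  # logit
            se_tr = se / (point * (1.0 - point))
        centre = fwd(point)
    lower = inv(centre - _Z95 * se_tr)
    upper = inv(centre + _Z95 * se_tr)
    return CurveEstimate(grid=grid, quantity=quantity, method="delta",
                         point=point, se=se, lower=lower, upper=upper,
                         transform=transform)


def mvn_uncertainty(
    fm: FittedModel,
    quantity: str,
    grid: TimeGrid,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
) -> CurveEstimate:
    """Multivariate-normal Monte-Carlo curve uncertainty.

    Reports the plug-in variance (1/B) sum_b [g(theta_b) - g(theta_hat)]**2
    as the squared SE and the 2.5th/97.5th percentiles of the draws as the
    95% band.  Pass precomputed ``draws`` to share one parameter sample
    across several functionals of the same model.
    """
    if draws is None:
        if B < 100:
            raise ValueError("B must be >= 100")
        if rng is None:
            rng = np.random.default_rng(BASE_SEED)
        draws = parameter_draws(fm, B, rng)
    fn = _quantity_fn(quantity)
    t = grid.times
    point = np.asarray(fn(fm.params, t), dtype=float)
    samples = np.empty((draws.shape[0], t.size))
    for b, theta_b in enumerate(draws):
        samples[b] = fn(from_estimation_scale(fm.family, theta_b), t)
    var = np.mean((samples - point) ** 2, axis=0)
    lower, upper = np.percentile(samples, [2.5, 97.5], axis=0)
    return CurveEstimate(grid=grid, quantity=quantity, method="mvn",
                         point=point, se=np.sqrt(var),
                         lower=lower, upper=upper, transform="identity")


def mean_survival_with_ci(
    fm: FittedModel,
    horizon: float,
    method: str = "mvn",
    B: int = 1000,
    rng: np.random.Generator | None = None,
    draws: np.ndarray | None = None,
) -> MeanSurvivalEstimate:
    """(Restricted) mean survival with SE and 95% CI by the requested method.

    ``exact`` is the closed-form exponential route (infinite horizon);
    ``delta`` propagates the RMST gradient; ``mvn`` integrates the survival
    draw of every parameter sample (percentile CI).
    """
    point = restricted_mean(fm.params, horizon)
    if method == "exact":
        _, mean = exact_exponential_uncertainty(
            fm, TimeGrid(np.array([0.0, 1.0]), 1.0), horizon
        )
        return mean
    if method == "delta":
        se = float(np.sqrt(delta_variance(fm, lambda fp: restricted_mean(fp, horizon))))
        return MeanSurvivalEstimate(
            point=point, se=se,
            lower=point * np.exp(-_Z95 * se / point),
            upper=point * np.exp(_Z95 * se / point),
            horizon=horizon, method="delta",
        )
    if method != "mvn":
        raise ValueError(f"method must be exact, delta or mvn, got {method!r}")
    if draws is None:
        if rng is None:
            rng = np.random.default_rng(BASE_SEED)
        draws = parameter_draws(fm, B, rng)
    samples = np.empty(draws.shape[0])
    for b, theta_b in enumerate(draws):
        fp = from_estimation_scale(fm.family, theta_b)
        try:
            samples[b] = restricted_mean(fp, horizon)
        except DivergingMeanError:
            raise
    var = float(np.mean((samples - point) ** 2))
    lower, upper = np.percentile(samples, [2.5, 97.5])
    return MeanSurvivalEstimate(point=point, se=float(np.sqrt(var)),
                                lower=float(lower), upper=float(upper),
                                horizon=horizon, method="mvn")


def band_transform(curve: CurveEstimate, transform: str) -> CurveEstimate:
    """Rebuild a curve's 95% band on another scale.

    Percentile (MVN) bands are invariant under monotone transforms and are
    returned unchanged apart from the tag; normal-approximation bands are
    recomputed on the transformed scale and back-transformed.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"transform must be one of {tuple(_TRANSFORMS)}")
    if curve.method == "mvn":
        # percentile bands are not recomputed, so no domain restriction applies
        return replace(curve, transform=transform)
    point = curve.point
    if transform == "log" and np.any(point <= 0):
        bad = curve.grid.times[point <= 0]
        raise ValueError(f"log transform needs positive values; offending times {bad}")
    if transform == "logit" and np.any((point <= 0) | (point >= 1)):
        bad = curve.grid.times[(point <= 0) | (point >= 1)]
        raise ValueError(f"logit transform needs values in (0,1); offending times {bad}")
    fwd, inv = _TRANSFORMS[transform]
    with np.errstate(divide="ignore"):
        if transform == "identity":
            se_tr = curve.se
        elif transform == "log":
            se_tr = curve.se / point
        else:
            se_tr = curve.se / (point * (1.0 - point))
        centre = fwd(point)
    return replace(curve, lower=inv(centre - _Z95 * se_tr),
                   upper=inv(centre + _Z95 * se_tr), transform=transform)
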