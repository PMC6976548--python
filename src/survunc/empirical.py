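"""Model-free survival and hazard estimates for exploratory diagnostics.

Before committing to a parametric family, standard practice is to look at
the Kaplan-Meier survival curve and at empirical hazard estimates: a
piecewise (occurrence/exposure) version that exposes the raw variability,
and a kernel-smoothed version that reveals the underlying shape.  Pointwise
bands for the hazards come from a nonparametric case-resampling bootstrap,
since no simple analytic variance exists for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import SurvivalData

__all__ = [
    "StepSurvival",
    "EmpiricalHazard",
    "kaplan_meier",
    "piecewise_hazard",
    "smoothed_hazard",
    "bootstrap_hazard_band",
]


@dataclass(frozen=True)
class StepSurvival:
    """Product-limit survival estimate with Greenwood variances."""

    knots: np.ndarray        # distinct event times
    survival: np.ndarray     # S(t) just after each knot
    variance: np.ndarray     # Greenwood variance at each knot
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """Step-function value of S at arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.knots,
                "survival": self.survival,
                "greenwood_var": self.variance,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass(frozen=True)
class EmpiricalHazard:
    """Empirical hazard values on an evaluation grid."""

    times: np.ndarray
    hazard: np.ndarray
    style: str                       # "piecewise" | "smoothed"
    bandwidth: float | None = None   # smoothed style
    n_intervals: int | None = None   # piecewise style
    lower: np.ndarray | None = None  # bootstrap band
    upper: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "hazard": self.hazard,
                           "style": self.style})
        if self.lower is not None:
            df["lower"] = self.lower
            df["upper"] = self.upper
        return df


def kaplan_meier(data: SurvivalData) -> StepSurvival:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set without a step; the Greenwood
    variance is S(t)**2 * sum_{t_j <= t} d_j / (r_j (r_j - d_j)).
    """
    order = np.argsort(data.time, kind="stable")
    t_sorted = data.time[order]
    d_sorted = data.event[order]
    event_times = np.unique(t_sorted[d_sorted == 1])
    n = len(data)
    surv = np.empty(event_times.size)
    var_sum = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d_at = np.empty(event_times.size, dtype=int)
    s, acc = 1.0, 0.0
    for j, tj in enumerate(event_times):
        r = int(np.sum(t_sorted >= tj))
        d = int(np.sum((t_sorted == tj) & (d_sorted == 1)))
        s *= 1.0 - d / r
        if r > d:
            acc += d / (r * (r - d))
        else:
            acc = np.inf  # S hits zero; variance conventionally undefined
        surv[j] = s
        var_sum[j] = acc
        at_risk[j] = r
        d_at[j] = d
    with np.errstate(invalid="ignore"):
        variance = np.where(surv > 0, surv**2 * var_sum, 0.0)
    return StepSurvival(knots=event_times, survival=surv, variance=variance,
                        at_risk=at_risk, events=d_at)


def piecewise_hazard(data: SurvivalData, n_intervals: int = 25) -> EmpiricalHazard:
    """Occurrence/exposure hazard on equal-width intervals over
    (0, max follow-up].

    Each interval's hazard is (events in interval) / (person-time at risk in
    interval); intervals with no person-time are reported as NaN, not zero.
    With a single interval this reduces to the exponential MLE N_e/sum(t_i).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    t_max = float(data.time.max())
    edges = np.linspace(0.0, t_max, n_intervals + 1)
    haz = np.full(n_intervals, np.nan)
    for k in range(n_intervals):
        lo, hi = edges[k], edges[k + 1]
        # person-time spent inside (lo, hi] by each subject
        exposure = np.clip(np.minimum(data.time, hi) - lo, 0.0, hi - lo).sum()
        events = int(np.sum((data.time > lo) & (data.time <= hi) & (data.event == 1)))
        if exposure > 0:
            haz[k] = events / exposure
    mid = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalHazard(times=mid, hazard=haz, style="piecewise",
                           n_intervals=n_intervals)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)


def _epanechnikov_cdf(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, -1.0, 1.0)
    return 0.25 * (2.0 + 3.0 * u - u**3)


def smoothed_hazard(
    data: SurvivalData,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 101,
) -> EmpiricalHazard:
    """Kernel-smoothed hazard: smoothed event counts over smoothed
    person-time at risk.

    With Epanechnikov kernel K_b, the estimate at t is

        h_hat(t) = sum_{i: event} K_b(t - t_i) / sum_j integral_0^{t_j} K_b(t - u) du.

    Numerator and denominator are truncated by the same observation window,
    so the ratio is approximately unbiased near both boundaries (a
    ratio-based boundary correction).  Default bandwidth is one eighth of
    the follow-up range.
    """
    t_max = float(data.time.max())
    if bandwidth is None:
        bandwidth = t_max / 8.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if bandwidth > 0.5 * t_max:
        warnings.warn("bandwidth exceeds half the follow-up range; clamping")
        bandwidth = 0.5 * t_max
    if grid is None:
        grid = np.linspace(t_max / (n_grid + 1), t_max * n_grid / (n_grid + 1), n_grid)
    grid = np.asarray(grid, dtype=float)

    event_t = data.time[data.event == 1]
    if event_t.size == 0:
        return EmpiricalHazard(times=grid, hazard=np.zeros_like(grid),
                               style="smoothed", bandwidth=bandwidth)
    # numerator: smoothed counting-process increments
    num = _epanechnikov((grid[:, None] - event_t[None, :]) / bandwidth).sum(axis=1)
    num /= bandwidth
    # denominator: smoothed person-time, integral over each subject's follow-up
    upper = _epanechnikov_cdf(grid[:, None] / bandwidth)
    lower = _epanechnikov_cdf((grid[:, None] - data.time[None, :]) / bandwidth)
    denom = (upper - lower).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        haz = np.where(denom > 0, num / denom, np.nan)
    return EmpiricalHazard(times=grid, hazard=haz, style="smoothed",
                           bandwidth=bandwidth)


def bootstrap_hazard_band(
    data: SurvivalData,
    estimator,
    reps: int = 500,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> EmpiricalHazard:
    """Pointwise 95% bootstrap band for an empirical hazard estimator.

    Case-resampling: subjects' (time, event) pairs are drawn with
    replacement; the estimator is re-evaluated on the point estimate's own
    grid.  Replicates where the estimator fails are dropped (an error is
    raised if more than 10% fail).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if rng is None:
        rng = np.random.default_rng(0)
    base = estimator(data, **kwargs)
    grid = base.times
    if base.style == "smoothed":
        kwargs = {**kwargs, "bandwidth": base.bandwidth, "grid": grid}
    n = len(data)
    samples, failures = [], 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        boot = SurvivalData(time=data.time[idx], event=data.event[idx])
        try:
            rep = estimator(boot, **kwargs)
            if base.style == "piecewise":
                # interpolate onto the base grid (max follow-up may differ)
                values = np.interp(grid, rep.times, rep.hazard,
                                   left=np.nan, right=np.nan)
            else:
                values = rep.hazard
            samples.append(values)
        except Exception:
            failures += 1
    if failures > 0.1 * reps:
        raise RuntimeError(f"{failures}/{reps} bootstrap replicates failed")
    stack = np.vstack(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns where exposure vanishes
        lower = np.nanpercentile(stack, 2.5, axis=0)
        upper = np.nanpercentile(stack, 97.5, axis=0)
    return EmpiricalHazard(times=grid, hazard=base.hazard, style=base.style,
                           bandwidth=base.bandwidth, n_intervals=base.n_intervals,
                           lower=lower, upper=upper)
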