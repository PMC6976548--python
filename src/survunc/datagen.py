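"""Synthetic right-censored survival datasets for the four case studies.

Each case-study dataset mimics a single arm of a trial with n = 400
subjects, a design mean survival of 0.9 years and administrative censoring
at 1 year (no other censoring).  Four hazard shapes are covered:

* ``flat``        — 400 draws from one exponential;
* ``increasing``  — 200 Weibull + 200 gamma draws, both shape > 1;
* ``decreasing``  — 200 Weibull + 200 gamma draws, both shape < 1;
* ``unimodal``    — 200 log-logistic + 200 log-normal draws.

Mixtures keep a dataset's behaviour from being driven by the one family
that generated it.  Every component is calibrated (by root-finding on its
scale parameter) so its analytic mean survival equals the design mean.
The shape parameters themselves are free design choices — only the mean,
sample size, censoring rule and qualitative shapes are fixed — and live in
:data:`SCENARIO_SHAPES` so they are easy to audit or override.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .families import FamilyParams, PARAM_NAMES, analytic_mean, sample

__all__ = [
    "SurvivalData",
    "ScenarioSpec",
    "SCENARIO_KINDS",
    "SCENARIO_SHAPES",
    "DESIGN_MEAN",
    "CalibrationError",
    "calibrate_component",
    "scenario_components",
    "make_dataset",
    "load_dataset",
    "save_dataset",
]

SCENARIO_KINDS = ("flat", "increasing", "decreasing", "unimodal")

#: design mean survival (years) shared by every component of every scenario
DESIGN_MEAN = 0.9

#: non-authoritative shape choices per scenario: (family, fixed shape params,
#: free scale parameter solved for the design mean)
SCENARIO_SHAPES: dict[str, list[tuple[str, dict[str, float], str]]] = {
    "flat": [("exponential", {}, "lam")],
    "increasing": [
        ("weibull", {"gamma": 2.0}, "lam"),
        ("gamma", {"shape": 2.0}, "rate"),
    ],
    "decreasing": [
        ("weibull", {"gamma": 0.6}, "lam"),
        ("gamma", {"shape": 0.5}, "rate"),
    ],
    "unimodal": [
        ("loglogistic", {"beta": 2.0}, "alpha"),
        ("lognormal", {"sigma": 0.9}, "mu"),
    ],
}


class CalibrationError(ValueError):
    """A mixture component could not be calibrated to the design mean."""


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: times ``t`` (years) and event flags ``event``
    (1 = observed event, 0 = administratively censored)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.event)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("dataset is empty")
        if np.any(t <= 0):
            idx = int(np.argmax(t <= 0))
            raise ValueError(f"non-positive follow-up time at row {idx}")
        if not np.isin(d, (0, 1)).all():
            idx = int(np.argmax(~np.isin(d, (0, 1))))
            raise ValueError(f"event indicator not in {{0,1}} at row {idx}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", d.astype(int))

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def total_time(self) -> float:
        """Total person-time at risk, sum of t_i."""
        return float(self.time.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one case-study dataset."""

    kind: str
    n: int = 400
    censor_time: float = 1.0
    target_mean: float = DESIGN_MEAN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; choose from {SCENARIO_KINDS}"
            )
        n_comp = len(SCENARIO_SHAPES[self.kind])
        if self.n % n_comp:
            raise ValueError(f"n={self.n} not divisible into {n_comp} equal components")
        if self.censor_time <= 0 or self.target_mean <= 0:
            raise ValueError("censor_time and target_mean must be > 0")


def calibrate_component(
    family: str,
    shape_controls: dict[str, float],
    target_mean: float,
    scale_param: str | None = None,
) -> FamilyParams:
    """Solve a family's free scale/rate parameter so the analytic mean
    survival equals ``target_mean``.

    ``shape_controls`` fixes all but one parameter; the remaining one (or
    ``scale_param``) is found by Brent root-finding on the analytic mean.
    """
    if target_mean <= 0:
        raise CalibrationError("target_mean must be > 0")
    names = PARAM_NAMES[family]
    if scale_param is None:
        free = [n for n in names if n not in shape_controls]
        if len(free) != 1:
            raise CalibrationError(
                f"shape_controls must fix all but one of {names}, got {shape_controls}"
            )
        scale_param = free[0]

    # closed-form inversions where elementary
    if family == "exponential":
        return FamilyParams("exponential", {"lam": 1.0 / target_mean})
    if family == "lognormal" and scale_param == "mu":
        sigma = shape_controls["sigma"]
        return FamilyParams(
            "lognormal", {"mu": float(np.log(target_mean) - 0.5 * sigma**2), "sigma": sigma}
        )

    unconstrained = family in ("gompertz", "gengamma", "lognormal") and scale_param in (
        "theta", "beta", "mu",
    )

    def mean_at(x: float) -> float:
        value = x if unconstrained else float(np.exp(x))
        fp = FamilyParams(family, {**shape_controls, scale_param: value})
        return analytic_mean(fp) - target_mean

    lo, hi = (-20.0, 20.0)
    grid = np.linspace(lo, hi, 81)
    vals = []
    for x in grid:
        try:
            vals.append(mean_at(x))
        except Exception:
            vals.append(np.nan)
    vals = np.asarray(vals)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    sign_change = [i for i in sign_change if np.isfinite(vals[i]) and np.isfinite(vals[i + 1])]
    if not sign_change:
        raise CalibrationError(
            f"no {scale_param} in domain gives mean {target_mean} for {family}"
        )
    i = sign_change[0]
    root = optimize.brentq(mean_at, grid[i], grid[i + 1], xtol=1e-14)
    value = root if unconstrained else float(np.exp(root))
    fp = FamilyParams(family, {**shape_controls, scale_param: value})
    if abs(analytic_mean(fp) - target_mean) > 1e-6:
        raise CalibrationError(f"calibration of {family} did not reach 1e-6 accuracy")
    return fp


def scenario_components(spec: ScenarioSpec) -> list[tuple[FamilyParams, int]]:
    """Calibrated mixture components and their sample counts for a scenario."""
    recipes = SCENARIO_SHAPES[spec.kind]
    per = spec.n // len(recipes)
    return [
        (calibrate_component(family, shapes, spec.target_mean, scale), per)
        for family, shapes, scale in recipes
    ]


def make_dataset(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> SurvivalData:
    """Generate one case-study dataset: draw latent event times from the
    calibrated mixture and apply administrative censoring at
    ``spec.censor_time``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    latent = np.concatenate(
        [sample(fp, count, rng) for fp, count in scenario_components(spec)]
    )
    censored = latent > spec.censor_time
    time = np.where(censored, spec.censor_time, latent)
    return SurvivalData(time=time, event=(~censored).astype(int))


def latent_times(spec: ScenarioSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uncensored draws from the scenario's mixture (equal component split),
    used for calibration checks."""
    comps = scenario_components(spec)
    per = n // len(comps)
    parts = [sample(fp, per, rng) for fp, _ in comps]
    rem = n - per * len(comps)
    if rem:
        parts.append(sample(comps[0][0], rem, rng))
    return np.concatenate(parts)


def save_dataset(data: SurvivalData, path: str | Path) -> None:
    """Write a two-column CSV (time, event)."""
    data.to_frame().to_csv(path, index=False)


def load_dataset(
    path: str | Path | io.IOBase,
    time_col: str = "time",
    event_col: str = "event",
) -> SurvivalData:
    """Read a two-column CSV of follow-up times and 0/1 event indicators."""
    df = pd.read_csv(path)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {list(df.columns)}")
    if df.empty:
        raise ValueError("empty dataset file")
    return SurvivalData(time=df[time_col].to_numpy(float), event=df[event_col].to_numpy())
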