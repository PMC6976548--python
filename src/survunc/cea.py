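"""Hypothetical cost-effectiveness analysis driven by fitted survival models.

A two-state ("well", "dead") Markov cohort model with weekly cycles over a
10-year horizon.  The control arm's per-cycle death probabilities come from
a fitted survival model's cumulative hazard; the intervention arm applies a
hazard ratio (default 0.75) directly to that hazard.  Utilities are 1
(well) and 0 (dead); the control treatment costs 100 GBP every 2 weeks and
the intervention an additional 100 GBP every 2 weeks, accrued as per-week
rates while alive.  No discounting is applied.

Parameter uncertainty enters through the survival model only: the
probabilistic sensitivity analysis redraws the model's parameters from
their multivariate-normal sampling distribution (costs, utilities and the
hazard ratio stay fixed), rebuilds both arms, and summarises incremental
costs and QALYs, the cost-effectiveness acceptability curve and the
per-person expected value of perfect information

    EVPI(wtp) = E_b[max_s NB_s,b] - max_s E_b[NB_s,b],   NB = wtp*QALY - cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import cumulative_hazard
from .fitting import FittedModel, from_estimation_scale
from .uncertainty import parameter_draws

__all__ = [
    "MarkovSpec",
    "ArmResult",
    "PSAResult",
    "DEFAULT_WTP_GRID",
    "cycle_transition_probabilities",
    "run_markov",
    "deterministic_cea",
    "run_psa",
    "ceac",
    "evpi",
]

#: willingness-to-pay grid (GBP per QALY); includes the 20,000 threshold
DEFAULT_WTP_GRID = tuple(range(0, 50001, 2500))

WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class MarkovSpec:
    """Constants of the two-state cohort model."""

    horizon_years: float = 10.0
    cycles_per_year: int = WEEKS_PER_YEAR
    control_cost_per_2wk: float = 100.0
    intervention_extra_cost_per_2wk: float = 100.0
    hazard_ratio: float = 0.75
    utility_well: float = 1.0
    utility_dead: float = 0.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        n = self.horizon_years * self.cycles_per_year
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be a whole number of cycles")
        if self.hazard_ratio <= 0 and self.hazard_ratio != 0.0:
            raise ValueError("hazard ratio must be >= 0")
        if min(self.control_cost_per_2wk, self.intervention_extra_cost_per_2wk) < 0:
            raise ValueError("costs must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))

    @property
    def cycle_length_years(self) -> float:
        return 1.0 / self.cycles_per_year

    def weekly_cost(self, arm: str) -> float:
        """Per-cycle (weekly) cost while alive; '100 GBP per 2 weeks' is a
        rate of 50 GBP per weekly cycle."""
        base = self.control_cost_per_2wk / 2.0
        if arm == "control":
            return base
        if arm == "intervention":
            return base + self.intervention_extra_cost_per_2wk / 2.0
        raise ValueError(f"arm must be 'control' or 'intervention', got {arm!r}")


@dataclass(frozen=True)
class ArmResult:
    cost: float
    qalys: float


@dataclass(frozen=True)
class PSAResult:
    """Paired per-draw outcomes for the two strategies."""

    control_cost: np.ndarray
    control_qalys: np.ndarray
    intervention_cost: np.ndarray
    intervention_qalys: np.ndarray
    wtp_grid: np.ndarray

    @property
    def delta_cost(self) -> np.ndarray:
        return self.intervention_cost - self.control_cost

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.intervention_qalys - self.control_qalys

    @property
    def icer(self) -> float:
        """Mean incremental cost per mean incremental QALY."""
        return float(self.delta_cost.mean() / self.delta_qalys.mean())

    def net_benefit(self, wtp: float) -> np.ndarray:
        """Per-draw net monetary benefit, columns (control, intervention)."""
        return np.column_stack([
            wtp * self.control_qalys - self.control_cost,
            wtp * self.intervention_qalys - self.intervention_cost,
        ])

    def icer_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of the per-draw cost-effectiveness ratios.

        Convention: per-draw ratios DeltaC_b / DeltaQ_b, 2.5th/97.5th
        percentiles; well-behaved when all draws share the incremental-QALY
        sign (the case here, since the hazard ratio helps in every draw).
        """
        ratios = self.delta_cost / self.delta_qalys
        a = 100 * (1.0 - level) / 2.0
        lo, hi = np.percentile(ratios, [a, 100 - a])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "control_cost": self.control_cost,
                "control_qalys": self.control_qalys,
                "intervention_cost": self.intervention_cost,
                "intervention_qalys": self.intervention_qalys,
            }
        )

    def summary(self) -> dict:
        lo, hi = self.icer_ci()
        wtps = self.wtp_grid
        return {
            "n_samples": int(self.control_cost.size),
            "mean_control_cost": float(self.control_cost.mean()),
            "mean_control_qalys": float(self.control_qalys.mean()),
            "mean_intervention_cost": float(self.intervention_cost.mean()),
            "mean_intervention_qalys": float(self.intervention_qalys.mean()),
            "incremental_cost": float(self.delta_cost.mean()),
            "incremental_qalys": float(self.delta_qalys.mean()),
            "icer": self.icer,
            "icer_ci95": [lo, hi],
            "wtp_grid": wtps.tolist(),
            "ceac_intervention": [ceac(self, w) for w in wtps],
            "evpi": [evpi(self, w) for w in wtps],
        }


def cycle_transition_probabilities(
    fm_or_params, spec: MarkovSpec, hazard_ratio: float = 1.0
) -> np.ndarray:
    """Per-cycle death probabilities from a fitted model's cumulative hazard.

    For cycle k spanning [t_k, t_{k+1}):
    p_k = 1 - exp(-hr * (H(t_{k+1}) - H(t_k))).
    """
    params = fm_or_params.params if isinstance(fm_or_params, FittedModel) else fm_or_params
    edges = np.arange(spec.n_cycles + 1) * spec.cycle_length_years
    H = np.asarray(cumulative_hazard(params, edges), dtype=float)
    if np.any(np.isnan(H)) or np.any(H < 0):
        k = int(np.argmax(np.isnan(H) | (H < 0)))
        raise ValueError(f"invalid cumulative hazard at cycle {k}")
    if hazard_ratio == 0.0:
        return np.zeros(spec.n_cycles)
    # H = +inf means survival underflowed: the cohort is extinct to machine
    # precision, so every later cycle has certain death.
    dH = np.diff(H)
    dH[np.isnan(dH)] = np.inf  # inf - inf past the extinction point
    return -np.expm1(-hazard_ratio * dH)


def run_markov(spec: MarkovSpec, death_probs: np.ndarray, arm: str = "control") -> ArmResult:
    """Run the cohort trace and accrue costs and QALYs.

    The cohort starts fully alive.  Membership for accrual is "alive at
    cycle start" (with an optional half-cycle correction averaging the
    start and end of each cycle); each alive cycle contributes one cycle
    length of utility-weighted time and one cycle of treatment cost.
    """
    p = np.asarray(death_probs, dtype=float)
    if p.size != spec.n_cycles:
        raise ValueError(f"expected {spec.n_cycles} death probabilities, got {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("death probabilities must lie in [0, 1]")
    alive_start = np.concatenate([[1.0], np.cumprod(1.0 - p)])  # length n_cycles+1
    if spec.half_cycle_correction:
        membership = 0.5 * (alive_start[:-1] + alive_start[1:])
    else:
        membership = alive_start[:-1]
    life_years = float(membership.sum() * spec.cycle_length_years)
    qalys = life_years * spec.utility_well
    cost = float(membership.sum() * spec.weekly_cost(arm))
    return ArmResult(cost=cost, qalys=qalys)


def deterministic_cea(fm: FittedModel, spec: MarkovSpec) -> dict:
    """Point-estimate cost-effectiveness comparison of the two arms."""
    control = run_markov(spec, cycle_transition_probabilities(fm, spec, 1.0), "control")
    interv = run_markov(
        spec, cycle_transition_probabilities(fm, spec, spec.hazard_ratio), "intervention"
    )
    d_cost = interv.cost - control.cost
    d_q = interv.qalys - control.qalys
    return {
        "control": control,
        "intervention": interv,
        "incremental_cost": d_cost,
        "incremental_qalys": d_q,
        "icer": d_cost / d_q if d_q != 0 else np.inf,
    }


def run_psa(
    fm: FittedModel,
    spec: MarkovSpec,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
    wtp_grid=DEFAULT_WTP_GRID,
) -> PSAResult:
    """Probabilistic sensitivity analysis over survival-model parameters.

    Each draw resamples the model's parameters from N(theta_hat,
    Var(theta_hat)) on the estimation scale and rebuilds both arms' traces;
    costs, utilities and the hazard ratio are fixed constants of the
    decision problem.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    draws = parameter_draws(fm, n_samples, rng)
    cc = np.empty(n_samples); cq = np.empty(n_samples)
    ic = np.empty(n_samples); iq = np.empty(n_samples)
    for b, theta_b in enumerate(draws):
        params_b = from_estimation_scale(fm.family, theta_b)
        control = run_markov(
            spec, cycle_transition_probabilities(params_b, spec, 1.0), "control")
        interv = run_markov(
            spec, cycle_transition_probabilities(params_b, spec, spec.hazard_ratio),
            "intervention")
        cc[b], cq[b] = control.cost, control.qalys
        ic[b], iq[b] = interv.cost, interv.qalys
    return PSAResult(control_cost=cc, control_qalys=cq,
                     intervention_cost=ic, intervention_qalys=iq,
                     wtp_grid=np.asarray(wtp_grid, dtype=float))


def ceac(psa: PSAResult, wtp: float) -> float:
    """Probability the intervention has the higher net benefit at ``wtp``."""
    nb = psa.net_benefit(wtp)
    return float(np.mean(nb[:, 1] > nb[:, 0]))


def evpi(psa: PSAResult, wtp: float) -> float:
    """Per-person expected value of perfect information at ``wtp`` (GBP)."""
    if wtp < 0:
        raise ValueError("willingness to pay must be >= 0")
    if psa.control_cost.size == 0:
        raise ValueError("empty PSA")
    nb = psa.net_benefit(wtp)
    value = float(nb.max(axis=1).mean() - nb.mean(axis=0).max())
    # clip summation round-off (positive or negative) relative to the NB scale
    tol = 1e-9 * max(1.0, float(np.abs(nb).max()))
    return value if value > tol else 0.0
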