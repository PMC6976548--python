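"""Parametric survival families for hazard extrapolation.

Seven families commonly used to extrapolate single-arm time-to-event data:
exponential, Weibull, Gompertz, gamma, log-logistic, log-normal and the
generalised gamma.  Each is expressed through its survival function S(t),
hazard h(t) and cumulative hazard H(t) = -ln S(t), on the package's natural
parameter scale:

============  =========================  =============================
family        parameters                 survival function
============  =========================  =============================
exponential   lam > 0                    exp(-lam*t)
weibull       lam > 0, gamma > 0         exp(-lam*t**gamma)
gompertz      lam > 0, theta real        exp(-lam/theta*(e**(theta*t)-1))
gamma         shape > 0, rate > 0        Q(shape, rate*t)   (upper reg. gamma)
loglogistic   alpha > 0, beta > 0        1/(1+(alpha*t)**beta)
lognormal     mu real, sigma > 0         1 - Phi((ln t - mu)/sigma)
gengamma      lam real, beta real,       Q(a, u) if lam>0, P(a, u) if lam<0,
              sigma > 0                  a = lam**-2, u = a*exp(lam*w),
                                         w = (ln t - beta)/sigma
============  =========================  =============================

The generalised gamma uses the flexible (Prentice) convention: ``beta`` is a
location parameter on the log-time scale (it enters as ``exp(-beta)*t``) and
``lam`` is the shape index, with ``lam -> 0`` recovering the log-normal and
``lam = 1`` a Weibull.  Conversions to common software conventions:

* Weibull here ``S = exp(-lam*t**g)`` corresponds to scale
  ``b = lam**(-1/g)`` and shape ``g`` in the numpy/scipy/lifelines
  convention ``S = exp(-(t/b)**g)``.
* log-logistic ``alpha`` is the reciprocal of the usual scale parameter
  (``S = 1/(1+(t/scale)**beta)`` with ``scale = 1/alpha``).
* generalised gamma ``(lam, beta, sigma)`` maps to flexsurv's
  ``(Q, mu, sigma) = (lam, beta, sigma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "FAMILIES",
    "FamilyParams",
    "TimeGrid",
    "ParameterDomainError",
    "DivergingMeanError",
    "survival",
    "hazard",
    "cumulative_hazard",
    "log_density",
    "sample",
    "restricted_mean",
    "analytic_mean",
]

FAMILIES = (
    "exponential",
    "weibull",
    "gompertz",
    "gamma",
    "loglogistic",
    "lognormal",
    "gengamma",
)

#: parameter names, in canonical order, per family
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("lam",),
    "weibull": ("lam", "gamma"),
    "gompertz": ("lam", "theta"),
    "gamma": ("shape", "rate"),
    "loglogistic": ("alpha", "beta"),
    "lognormal": ("mu", "sigma"),
    "gengamma": ("lam", "beta", "sigma"),
}

#: parameters that must be strictly positive; the rest are unconstrained
POSITIVE_PARAMS: dict[str, tuple[str, ...]] = {
    "exponential": ("lam",),
    "weibull": ("lam", "gamma"),
    "gompertz": ("lam",),
    "gamma": ("shape", "rate"),
    "loglogistic": ("alpha", "beta"),
    "lognormal": ("sigma",),
    "gengamma": ("sigma",),
}

# |lam| below this is treated as the log-normal limit of the gen. gamma
_GG_LOGNORMAL_EPS = 1e-7


class ParameterDomainError(ValueError):
    """Parameters violate the family's domain (e.g. a non-positive rate)."""


class DivergingMeanError(ValueError):
    """Unrestricted mean requested for an improper survival distribution."""


@dataclass(frozen=True)
class FamilyParams:
    """A survival family with parameter values on the natural scale."""

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterDomainError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        names = PARAM_NAMES[self.family]
        if set(self.params) != set(names):
            raise ParameterDomainError(
                f"{self.family} expects parameters {names}, got {tuple(self.params)}"
            )
        for name in names:
            value = float(self.params[name])
            if not np.isfinite(value):
                raise ParameterDomainError(f"{self.family} {name}={value} not finite")
            if name in POSITIVE_PARAMS[self.family] and value <= 0:
                raise ParameterDomainError(
                    f"{self.family} requires {name} > 0, got {value}"
                )
        object.__setattr__(self, "params", {n: float(self.params[n]) for n in names})

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.params[n] for n in PARAM_NAMES[self.family]])


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing non-negative evaluation times with an
    observed/extrapolated boundary."""

    times: np.ndarray
    observed_end: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-d array")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if not (0.0 <= self.observed_end <= t[-1]):
            raise ValueError("observed_end must not exceed the grid range")
        object.__setattr__(self, "times", t)

    @property
    def extrapolated(self) -> np.ndarray:
        """Boolean mask: True where the grid lies beyond the observed period."""
        return self.times > self.observed_end


def _as_times(t, positive: bool = False) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    low = 0.0
    if np.any(t < low) or (positive and np.any(t == 0.0)):
        bound = "> 0" if positive else ">= 0"
        raise ValueError(f"times must be {bound}")
    return t


def _gg_branch(fp: FamilyParams):
    lam, beta, sigma = fp["lam"], fp["beta"], fp["sigma"]
    return lam, beta, sigma, abs(lam) < _GG_LOGNORMAL_EPS


def survival(fp: FamilyParams, t) -> np.ndarray:
    """Survival probability S(t); vectorised over ``t >= 0``."""
    t = _as_times(t)
    p = fp.params
    if fp.family == "exponential":
        return np.exp(-p["lam"] * t)
    if fp.family == "weibull":
        return np.exp(-p["lam"] * t ** p["gamma"])
    if fp.family == "gompertz":
        lam, theta = p["lam"], p["theta"]
        if theta == 0.0:
            return np.exp(-lam * t)
        return np.exp(-lam / theta * np.expm1(theta * t))
    if fp.family == "gamma":
        return special.gammaincc(p["shape"], p["rate"] * t)
    if fp.family == "loglogistic":
        return 1.0 / (1.0 + (p["alpha"] * t) ** p["beta"])
    if fp.family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(t) - p["mu"]) / p["sigma"]
        return special.ndtr(-z)
    # generalised gamma
    lam, beta, sigma, ln_limit = _gg_branch(fp)
    with np.errstate(divide="ignore"):
        w = (np.log(t) - beta) / sigma
    if ln_limit:
        return special.ndtr(-w)
    a = lam ** -2
    with np.errstate(over="ignore"):
        u = a * np.exp(lam * w)
    if lam > 0:
        return special.gammaincc(a, u)
    return special.gammainc(a, u)


def log_density(fp: FamilyParams, t) -> np.ndarray:
    """Log of the event-time density f(t) = h(t) S(t), for ``t > 0``."""
    t = _as_times(t, positive=True)
    p = fp.params
    if fp.family == "exponential":
        return np.log(p["lam"]) - p["lam"] * t
    if fp.family == "weibull":
        lam, g = p["lam"], p["gamma"]
        return np.log(lam * g) + (g - 1.0) * np.log(t) - lam * t**g
    if fp.family == "gompertz":
        lam, theta = p["lam"], p["theta"]
        if theta == 0.0:
            return np.log(lam) - lam * t
        return np.log(lam) + theta * t - lam / theta * np.expm1(theta * t)
    if fp.family == "gamma":
        shape, rate = p["shape"], p["rate"]
        return (
            shape * np.log(rate)
            + (shape - 1.0) * np.log(t)
            - rate * t
            - special.gammaln(shape)
        )
    if fp.family == "loglogistic":
        alpha, beta = p["alpha"], p["beta"]
        log_at_b = beta * np.log(alpha * t)
        return (
            np.log(alpha * beta)
            + (beta - 1.0) * np.log(alpha * t)
            - 2.0 * np.logaddexp(0.0, log_at_b)
        )
    if fp.family == "lognormal":
        mu, sigma = p["mu"], p["sigma"]
        z = (np.log(t) - mu) / sigma
        return -np.log(sigma * t) - 0.5 * np.log(2.0 * np.pi) - 0.5 * z**2
    lam, beta, sigma, ln_limit = _gg_branch(fp)
    w = (np.log(t) - beta) / sigma
    if ln_limit:
        return -np.log(sigma * t) - 0.5 * np.log(2.0 * np.pi) - 0.5 * w**2
    a = lam ** -2
    u = a * np.exp(lam * w)
    return (
        np.log(abs(lam)) - np.log(sigma * t) - special.gammaln(a)
        + a * np.log(u) - u
    )


def hazard(fp: FamilyParams, t) -> np.ndarray:
    """Hazard rate h(t) (events per year).

    Vectorised.  At ``t = 0`` families with a singular formula return the
    analytic limit where it is finite (log-normal, gen. gamma and
    log-logistic with beta>1 tend to 0; Weibull gamma<1, gamma shape<1 and
    log-logistic beta<1 diverge, which raises a domain error).
    """
    t = _as_times(t)
    p = fp.params
    if fp.family == "exponential":
        return np.full_like(t, p["lam"], dtype=float)
    if fp.family == "gompertz":
        return p["lam"] * np.exp(p["theta"] * t)
    if fp.family == "weibull":
        lam, g = p["lam"], p["gamma"]
        if g < 1.0 and np.any(t == 0.0):
            raise ValueError("Weibull hazard diverges at t=0 for gamma < 1")
        with np.errstate(divide="ignore"):
            return lam * g * t ** (g - 1.0)
    if fp.family == "loglogistic":
        alpha, beta = p["alpha"], p["beta"]
        if beta < 1.0 and np.any(t == 0.0):
            raise ValueError("log-logistic hazard diverges at t=0 for beta < 1")
        with np.errstate(divide="ignore"):
            h = alpha * beta * (alpha * t) ** (beta - 1.0) / (1.0 + (alpha * t) ** beta)
        return np.where(t == 0.0, 0.0 if beta > 1.0 else alpha * beta, h)
    if fp.family == "gamma":
        shape = p["shape"]
        if shape < 1.0 and np.any(t == 0.0):
            raise ValueError("gamma hazard diverges at t=0 for shape < 1")
    # remaining families: h = f/S via logs, with the t=0 limit patched in
    zero = t == 0.0
    t_safe = np.where(zero, 1.0, t)
    h = np.exp(log_density(fp, t_safe) - np.log(survival(fp, t_safe)))
    if np.any(zero):
        if fp.family == "gamma":
            limit = p["rate"] if p["shape"] == 1.0 else 0.0
        else:  # lognormal, gengamma: density -> 0 faster than any power
            limit = 0.0
        h = np.where(zero, limit, h)
    return h


def cumulative_hazard(fp: FamilyParams, t) -> np.ndarray:
    """Cumulative hazard H(t) = -ln S(t); vectorised, H(0) = 0."""
    t = _as_times(t)
    p = fp.params
    if fp.family == "exponential":
        return p["lam"] * t
    if fp.family == "weibull":
        return p["lam"] * t ** p["gamma"]
    if fp.family == "gompertz":
        lam, theta = p["lam"], p["theta"]
        if theta == 0.0:
            return lam * t
        return lam / theta * np.expm1(theta * t)
    if fp.family == "loglogistic":
        return np.log1p((p["alpha"] * t) ** p["beta"])
    with np.errstate(divide="ignore"):
        return -np.log(survival(fp, t))


def sample(fp: FamilyParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` event times.  Uses inversion or exact transformations
    (gen. gamma times arise from a gamma variate), so draws are reproducible
    given the generator state."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = fp.params
    if fp.family == "exponential":
        return rng.exponential(1.0 / p["lam"], n)
    if fp.family == "weibull":
        # S = exp(-lam t^g)  =>  t = (E/lam)^(1/g), E ~ Exp(1)
        return (rng.exponential(1.0, n) / p["lam"]) ** (1.0 / p["gamma"])
    if fp.family == "gompertz":
        lam, theta = p["lam"], p["theta"]
        e = rng.exponential(1.0, n)  # E = H(T)
        if theta == 0.0:
            return e / lam
        arg = 1.0 + theta * e / lam
        with np.errstate(invalid="ignore"):
            t = np.log1p(theta * e / lam) / theta
        # theta < 0: H(inf) = -lam/theta is finite => a never-dying fraction;
        # represent those latent times as +inf (administrative censoring will
        # truncate them in any finite study window).
        return np.where(arg > 0.0, t, np.inf)
    if fp.family == "gamma":
        return rng.gamma(p["shape"], 1.0 / p["rate"], n)
    if fp.family == "loglogistic":
        u = rng.uniform(size=n)
        return (u / (1.0 - u)) ** (1.0 / p["beta"]) / p["alpha"]
    if fp.family == "lognormal":
        return np.exp(p["mu"] + p["sigma"] * rng.standard_normal(n))
    lam, beta, sigma, ln_limit = _gg_branch(fp)
    if ln_limit:
        return np.exp(beta + sigma * rng.standard_normal(n))
    g = rng.gamma(lam ** -2, 1.0, n)  # u = a e^{lam w} ~ Gamma(a, 1)
    return np.exp(beta + sigma / lam * np.log(lam**2 * g))


def analytic_mean(fp: FamilyParams) -> float:
    """Closed-form unrestricted mean where one exists; quadrature otherwise.

    Raises :class:`DivergingMeanError` when the mean is infinite (improper
    Gompertz with theta < 0, log-logistic with beta <= 1, gen. gamma with
    ``1/lam**2 + sigma/lam <= 0``).
    """
    p = fp.params
    if fp.family == "exponential":
        return 1.0 / p["lam"]
    if fp.family == "weibull":
        lam, g = p["lam"], p["gamma"]
        return lam ** (-1.0 / g) * special.gamma(1.0 + 1.0 / g)
    if fp.family == "gamma":
        return p["shape"] / p["rate"]
    if fp.family == "lognormal":
        return float(np.exp(p["mu"] + 0.5 * p["sigma"] ** 2))
    if fp.family == "loglogistic":
        alpha, beta = p["alpha"], p["beta"]
        if beta <= 1.0:
            raise DivergingMeanError("log-logistic mean diverges for beta <= 1")
        b = np.pi / beta
        return b / np.sin(b) / alpha
    if fp.family == "gengamma":
        lam, beta, sigma, ln_limit = _gg_branch(fp)
        if ln_limit:
            return float(np.exp(beta + 0.5 * sigma**2))
        a = lam ** -2
        if a + sigma / lam <= 0.0:
            raise DivergingMeanError("generalised-gamma mean diverges")
        # E[T] = e^beta lam^(2 sigma/lam) Gamma(a + sigma/lam)/Gamma(a)
        return float(
            np.exp(
                beta
                + (2.0 * sigma / lam) * np.log(abs(lam))
                + special.gammaln(a + sigma / lam)
                - special.gammaln(a)
            )
        )
    # Gompertz: no elementary closed form
    return restricted_mean(fp, np.inf)


def _partial_expectation(fp: FamilyParams, tau: float) -> float | None:
    """E[T * 1(T <= tau)] in closed form, or None if unavailable.

    Together with RMST(tau) = tau*S(tau) + E[T 1(T<=tau)] this gives the
    restricted mean without quadrature for most families.
    """
    p = fp.params
    if fp.family == "weibull":
        lam, g = p["lam"], p["gamma"]
        return float(
            lam ** (-1.0 / g) * special.gamma(1.0 + 1.0 / g)
            * special.gammainc(1.0 + 1.0 / g, lam * tau**g)
        )
    if fp.family == "gamma":
        a, r = p["shape"], p["rate"]
        return float(a / r * special.gammainc(a + 1.0, r * tau))
    if fp.family == "lognormal":
        mu, sigma = p["mu"], p["sigma"]
        w = (np.log(tau) - mu) / sigma
        return float(np.exp(mu + 0.5 * sigma**2) * special.ndtr(w - sigma))
    if fp.family == "loglogistic":
        alpha, beta = p["alpha"], p["beta"]
        if beta <= 1.0:
            return None  # partial mean finite but the beta-function form is not
        c = 1.0 / beta
        x = (alpha * tau) ** beta
        prob = x / (1.0 + x)
        return float(
            special.betainc(1.0 + c, 1.0 - c, prob)
            * special.beta(1.0 + c, 1.0 - c) / alpha
        )
    if fp.family == "gengamma":
        lam, beta, sigma, ln_limit = _gg_branch(fp)
        if ln_limit:
            return _partial_expectation(
                FamilyParams("lognormal", {"mu": beta, "sigma": sigma}), tau)
        a = lam ** -2
        c = sigma / lam
        if a + c <= 0.0:
            return None
        u = a * np.exp(lam * (np.log(tau) - beta) / sigma)
        reg = special.gammainc if lam > 0 else special.gammaincc
        mean = np.exp(
            beta + 2.0 * c * np.log(abs(lam))
            + special.gammaln(a + c) - special.gammaln(a)
        )
        return float(mean * reg(a + c, u))
    return None  # exponential handled separately; Gompertz has no closed form


def restricted_mean(fp: FamilyParams, horizon: float) -> float:
    """Restricted mean survival time: integral of S over [0, horizon].

    Closed forms (incomplete gamma/beta/normal integrals) are used where
    they exist; the Gompertz and a few parameter corners fall back to
    adaptive quadrature (absolute tolerance 1e-8, infinite horizons handled
    by scipy's semi-infinite transformation).  ``horizon=inf`` is allowed
    only when the survival function is proper; an improper fit (Gompertz
    theta < 0) raises :class:`DivergingMeanError` directing the caller to a
    finite horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    p = fp.params
    if fp.family == "exponential":
        lam = p["lam"]
        return 1.0 / lam if np.isinf(horizon) else float(-np.expm1(-lam * horizon) / lam)
    if np.isinf(horizon):
        if fp.family == "gompertz" and p["theta"] < 0:
            raise DivergingMeanError(
                "Gompertz with theta < 0 is improper (S(inf) > 0); "
                "use a finite horizon"
            )
        if fp.family in ("loglogistic", "gengamma"):
            return analytic_mean(fp)  # raises if divergent
    else:
        part = _partial_expectation(fp, horizon)
        if part is not None:
            return float(horizon * survival(fp, horizon) + part)
    value, _ = integrate.quad(
        lambda u: float(survival(fp, u)), 0.0, horizon,
        epsabs=1e-8, epsrel=1e-8, limit=200,
    )
    return float(value)
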