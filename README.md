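# survunc

How uncertain is a survival extrapolation? When a cost-effectiveness
analysis needs lifetime mean survival from a trial arm with one year of
follow-up, the analyst fits a parametric survival model and extrapolates.
`survunc` quantifies how strongly the *choice of family* drives the
uncertainty of everything downstream: the extrapolated hazard h(t) and
survival S(t), restricted mean survival ∫₀^τ S(t)dt, and the ICER, CEAC
and expected value of perfect information (EVPI) of a decision model built
on the fit. The headline phenomenon: families that fit the observed window
near-identically can imply interval estimates that are constant, exploding
or collapsing in the extrapolated period.

The package provides, as importable library code under `src/survunc/`:

* **families** — exponential, Weibull, Gompertz, gamma, log-logistic,
  log-normal and generalised-gamma distributions (S, h, H = −ln S, log
  density, exact seeded sampling, restricted mean);
* **fitting** — right-censored maximum likelihood
  ℓ(θ) = Σ[δᵢ ln f(tᵢ) + (1−δᵢ) ln S(tᵢ)] on an unconstrained estimation
  scale, with Var(θ̂) from the inverse negative Hessian and the exact
  exponential closed form λ̂ = N_e/Σtᵢ, Var(λ̂) = λ̂²/N_e;
* **uncertainty** — exact, delta-method
  (Var g ≈ ∇gᵀ Var(θ̂) ∇g) and multivariate-normal Monte-Carlo
  (θ_b ~ N(θ̂, Var θ̂), Var g ≈ (1/B)Σ[g(θ_b) − g(θ̂)]², percentile bands)
  propagation to hazard/survival curves and mean survival;
* **empirical** — Kaplan–Meier with Greenwood variance, piecewise
  (occurrence/exposure) and kernel-smoothed hazards, bootstrap bands;
* **datagen** — four synthetic case-study datasets (n = 400, design mean
  survival 0.9 years, administrative censoring at 1 year) with flat,
  increasing, decreasing and unimodal hazards built from calibrated
  mixtures;
* **cea** — a two-state Markov cohort model (weekly cycles, 10-year
  horizon, hazard ratio 0.75, £100/2-week costs) with PSA, ICER, CEAC and
  per-person EVPI;
* **pipeline** — configuration, seeds-in-outputs reproducibility, and the
  stage functions driven by the numbered scripts in `analysis/`.

See `docs/methods.md` for the model details and numerical conventions.

## Worked example

Fit two families to the same increasing-hazard dataset and compare the
uncertainty of their 10-year mean-survival extrapolations:

```python
import numpy as np
import survunc as su
from survunc.datagen import ScenarioSpec, make_dataset

data = make_dataset(ScenarioSpec("increasing", seed=20191125))
for family in ("gompertz", "loglogistic"):
    fm = su.fit_mle(data, family)
    est = su.mean_survival_with_ci(fm, horizon=10.0, method="mvn",
                                   B=1000, rng=np.random.default_rng(1))
    print(f"{family:>12}: mean={est.point:.2f} y  SE={est.se:.3f}  "
          f"95% CI=({est.lower:.2f}, {est.upper:.2f})")
```

```
    gompertz: mean=0.80 y  SE=0.023  95% CI=(0.75, 0.85)
 loglogistic: mean=1.06 y  SE=0.055  95% CI=(0.96, 1.18)
```

Both models fit the observed year acceptably, yet the log-logistic's
mean-survival SE is more than twice the Gompertz's — the uncertainty a
decision model inherits depends on the family, not just the data. Running
the full analysis chain:

```sh
python analysis/01_simulate_datasets.py    # four case-study CSVs
python analysis/02_empirical_hazards.py    # KM + empirical hazard diagnostics
python analysis/03_fit_extrapolate.py      # 7 fits x 4 datasets, 95% bands to 10 y
python analysis/04_mean_survival.py        # mean-survival table across families
python analysis/05_cost_effectiveness.py   # Markov CEA + PSA + EVPI per family
```

writes tables and figures under `results/`. On the checked-in seeds the
mean-survival SE varies up to 7.6-fold across families on the decreasing
dataset, and at £20,000/QALY several families yield £0 per-person EVPI
while disagreeing with each other about the funding decision — the
signature that parameter uncertainty within one model understates the
structural uncertainty between models.

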