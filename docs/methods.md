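# Methods

## Problem and scope

`survunc` studies how the choice of parametric survival family drives the
*uncertainty* of extrapolated quantities — the hazard function h(t), the
survival function S(t), (restricted) lifetime mean survival, and downstream
cost-effectiveness results — when a single trial arm with limited follow-up
is extrapolated over a decision horizon. Point estimates from different
families can be near-identical inside the observed window while their
interval estimates diverge dramatically beyond it; the package makes that
divergence measurable and reproducible.

Out of scope by design: the generalised F family (fragile estimation),
spline/fractional-polynomial and piecewise hazards, covariate effects,
interval censoring, Bayesian estimation and model averaging.

## Survival families

Seven families are implemented with the parameterisations documented in
`survunc.families` (module docstring), on a *natural* scale chosen so each
hazard formula is elementary: exponential (rate λ), Weibull
(S = exp(−λt^γ)), Gompertz (h = λe^{θt}), gamma (shape/rate), log-logistic
(S = 1/(1+(αt)^β)), log-normal (μ, σ of log-time) and the generalised gamma
in the flexible (Prentice) convention (shape index λ ∈ ℝ, log-time location
β, scale σ). The generalised gamma nests a Weibull at λ = 1, the gamma at
λ = σ, and tends to the log-normal as λ → 0; values |λ| < 1e−7 are
evaluated on the log-normal branch to avoid the λ^{-2} → ∞ shape parameter
overwhelming the incomplete-gamma routines. A conversion table to the
conventions of common fitting software is in the same docstring, so fits
can be cross-checked against external tools.

Numerical choices:

* H(t) is computed from its analytic form where one is elementary
  (`expm1`/`log1p` for Gompertz and log-logistic) and as −ln S(t)
  otherwise; the identity |H + ln S| < 1e−8 is enforced by tests wherever
  S(t) is representable in double precision.
* Hazards singular at t = 0 (Weibull γ < 1, gamma shape < 1, log-logistic
  β < 1) raise a domain error at exactly t = 0; finite limits (log-normal,
  generalised gamma, log-logistic β ≥ 1) are returned analytically.
  Plotting and likelihood evaluation only ever use t > 0.
* Sampling is by inversion or exact transformation (the generalised gamma
  maps a unit-scale gamma variate through t = exp(β + (σ/λ)ln(λ²G))), so a
  seeded generator reproduces draws exactly. An improper Gompertz (θ < 0)
  returns +∞ for the never-dying fraction; administrative censoring
  truncates these in any finite design.
* Restricted mean survival ∫₀^τ S dt uses closed forms via incomplete
  gamma/beta/normal integrals for all families except the Gompertz (and a
  few parameter corners), which fall back to adaptive quadrature with
  absolute tolerance 1e−8; τ = ∞ uses scipy's semi-infinite transformation
  and raises a diverging-mean error for improper distributions.

## Maximum-likelihood fitting

The right-censored log-likelihood Σ[δᵢ ln f(tᵢ) + (1−δᵢ) ln S(tᵢ)] is
maximised on an unconstrained **estimation scale**: log for strictly
positive parameters, identity for Gompertz θ, log-normal μ and the
generalised gamma's λ and β. This scale matters downstream: the reported
Var(θ̂) is the inverse negative Hessian *on that scale*, and both the delta
method and multivariate-normal sampling operate there, which keeps every
sampled parameter vector inside its domain and makes the normal
approximation more plausible for positive parameters. (The choice slightly
changes the shape of MVN bands relative to natural-scale sampling; it is
deliberate and reported.)

Optimisation is BFGS from moment/quantile starting values (the
occurrence/exposure rate N_e/Σtᵢ anchors every family; the generalised
gamma starts at its fitted-Weibull embedding) plus two jittered restarts.
Because BFGS's internal two-point finite-difference gradient is too noisy
to certify a 1e−8 gradient norm on a likelihood of order 10², convergence
is declared from an accurate central-difference gradient at the returned
optimum, with tolerance 1e−4·(1 + |ℓ|). Non-converged fits are returned
flagged, never dropped silently. The Hessian uses central differences with
relative step 1e−5. The exponential family additionally has the exact
closed form λ̂ = N_e/Σtᵢ, Var(λ̂) = λ̂²/N_e (log scale: 1/N_e), against
which the optimiser is tested.

Simulation evidence (part of the test suite): across all seven families,
200 replicates at n = 2000 with administrative censoring at 1 year give
Wald 95% coverage between 92% and 98% for every parameter.

## Uncertainty propagation

Three routes from Var(θ̂) to functionals g(θ):

* **exact** — exponential only: Var(ĥ(t)) = λ̂²/N_e for all t (the hazard
  band has constant width and does not fan out), Var(μ̂) = 1/(λ̂²N_e).
* **delta** — Var(g) ≈ ∇g(θ̂)ᵀ Var(θ̂) ∇g(θ̂) with a central-difference
  gradient (relative step 1e−6) on the estimation scale.
* **mvn** — B draws θ_b ~ N(θ̂, Var(θ̂)); the plug-in variance
  (1/B)Σ[g(θ_b) − g(θ̂)]² is reported as SE², and the 2.5th/97.5th
  percentiles of {g(θ_b)} form the 95% band. Default B = 1000 (matching
  the PSA sample count); one draw matrix can be shared across hazard,
  survival and mean-survival functionals of a model so all summaries are
  coherent draw-by-draw.

For the exponential the three routes agree (tests enforce ≤ 2% on the
hazard SE); for the Weibull at n = 2000 the delta and large-B MVN SEs of
the extrapolated hazard and the 10-year restricted mean agree within 1%.
Agreement degrades for smaller samples/wilder functionals because the delta
method is first-order — that gap is real, not a bug.

Band construction: percentile bands commute with monotone maps, so they are
simply re-tagged under a transform; normal-approximation bands are built on
a transformed scale (log for hazards and means, logit for survival) and
back-transformed, keeping hazard bands ≥ 0 and survival bands in [0, 1].
Mean-survival CIs from the exact/delta routes use the log-scale normal
interval for the same reason.

"Lifetime" mean survival defaults to the 10-year decision horizon; τ = ∞
is allowed where the fitted survival function is proper.

## Synthetic case-study datasets

Four datasets emulate the common hazard shapes met in practice. Shared
design: n = 400, design mean survival 0.9 years, administrative censoring
at exactly 1 year, no other censoring. Shapes:

| kind       | components (200 + 200)            | shape choices        |
|------------|-----------------------------------|----------------------|
| flat       | one exponential (400)             | —                    |
| increasing | Weibull + gamma                   | γ = 2, shape = 2     |
| decreasing | Weibull + gamma                   | γ = 0.6, shape = 0.5 |
| unimodal   | log-logistic + log-normal         | β = 2, σ = 0.9       |

Mixtures prevent any dataset's behaviour from being an artefact of the one
family that generated it. Only the mean, sample size, censoring rule and
qualitative shapes are fixed by the study design; the shape parameters
above are this package's own choices (`datagen.SCENARIO_SHAPES`, one
auditable block), picked so the kernel-smoothed empirical hazards show the
intended shapes clearly at n = 400, and they are **non-authoritative**:
the deposited original datasets are the only authoritative realisation,
so numerical results on regenerated data differ from published ones in a
realisation-dependent way while reproducing every qualitative finding.
Each component's free scale parameter is calibrated by Brent root-finding
on the analytic mean to hit 0.9 years within 1e−6.

What the generator does *not* emulate: covariates, informative or staggered
censoring, multiple hazard turning points, and discrete-time recording.
Passing tests therefore demonstrate correctness of the machinery under
clean administrative censoring, not robustness to messy real trial data.

## Empirical diagnostics

Kaplan–Meier with Greenwood variances is implemented directly (and
cross-checked against lifelines in the tests). The piecewise hazard uses 25
equal-width intervals by default — events over person-time per interval,
with empty intervals reported as missing; the data-driven breakpoints of
the external smoothing package this mirrors are intentionally not
reproduced. The smoothed hazard is an Epanechnikov-kernel ratio estimator
(smoothed event counts over smoothed person-time), default bandwidth =
follow-up range / 8; truncating numerator and denominator by the same
observation window gives a first-order boundary correction. Hazard bands
come from a 500-replicate case-resampling bootstrap (no analytic variance
exists). Because bandwidth and breakpoint rules are this package's own
defaults, empirical-hazard values are qualitative diagnostics, not
replication targets.

## Cost-effectiveness model

Two states (well → dead), weekly cycles over 10 years (520 cycles).
Per-cycle death probability for cycle [t_k, t_{k+1}):
p_k = 1 − exp(−hr·[H(t_{k+1}) − H(t_k)]) from the fitted cumulative
hazard; hr = 1 for control, 0.75 for the intervention (applied directly to
the hazard). Utilities 1/0; "£100 every 2 weeks" is accrued as a weekly
rate (£50 control, £100 intervention) while alive. Accrual membership is
*alive at cycle start*, with a half-cycle-correction switch (off by
default); no discounting. A cumulative hazard that overflows to +∞ within
the horizon is treated as extinction (p = 1 thereafter), which is the
correct limit when survival underflows double precision.

PSA redraws only the survival-model parameters via the MVN mechanism
(costs, utility and the hazard ratio are fixed constants of the decision
problem), 1000 samples by default. Summaries: ICER = mean ΔC / mean ΔQ;
an ICER interval from the 2.5/97.5 percentiles of per-draw ΔC_b/ΔQ_b
(well-defined here because the intervention improves survival in every
draw — this percentile convention is flagged wherever intervals are
compared against externally reported ones); CEAC and per-person
EVPI(wtp) = E_b[max_s NB_{s,b}] − max_s E_b[NB_{s,b}] on a WTP grid that
includes £20,000/QALY. Each family is analysed as its own structural
scenario; no model averaging.

## Reproducibility

All randomness flows through `numpy.random.Generator` objects seeded from a
single integer; the pipeline's base seed (20191125) and a configuration
hash are embedded in every output file, and re-running a configuration
reproduces outputs byte-for-byte. Problem sizes used by the checked-in
analyses — 200,000 latent draws for calibration checks, B = 10⁵–2×10⁵ MVN
draws for method-agreement checks, 200 replicates × n = 2000 for coverage,
1000 PSA samples — were chosen to make Monte-Carlo error small relative to
the tolerances they are compared against.

## Known limitations

* Single-arm, single-endpoint only; the hazard ratio is a fixed scenario
  constant, not an estimated quantity with uncertainty.
* The delta method is first-order; its disagreement with MVN grows with
  parameter uncertainty and functional curvature.
* Wald intervals and MVN sampling both lean on asymptotic normality on the
  estimation scale; small event counts will break the stated coverage.
* The smoothed-hazard bandwidth rule is deliberately simple; it
  undersmooths near sharp modes and oversmooths gentle trends compared to
  an optimised bandwidth.
* Published case-study numbers depend on the original deposited data
  realisation; regenerated datasets reproduce qualitative behaviour only
  (see README on obtaining the deposited files).
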