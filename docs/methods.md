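# Methods

## Tumor-dynamics model

Observed tumor burden is the sum of longest diameters (SLD, mm) of target
lesions. For subject *i* at time *t* (weeks, 0 = treatment start):

```
TS_i(t) = TS0_i · exp(KG_i·t)                            t < 0
TS_i(t) = TS0_i · [exp(−KS_i·t) + exp(KG_i·t) − 1]       t ≥ 0
y_ij = TS_i(t_ij) + ε_ij,   ε_ij ~ N(0, σ²)
```

The on-treatment curve is the sum of a treatment-sensitive component
shrinking at first-order rate `KS` and a resistant component growing at rate
`KG`; when `KS > KG` it declines to a nadir at `ln(KS/KG)/(KS+KG)` weeks and
regrows afterwards. Both branches agree at `t = 0` (`TS(0) = TS0`), so
pre-treatment screening scans can be fitted with the same parameters; their
inclusion is a settings flag (default on).

Individual parameters are log-normal around arm-level typical values:
`log p_i = log θ + η_i`, `η_i ~ N(0, ω²)`, with separate `(KG, KS)` typicals
and variances per arm and a common `TS0` distribution, diagonal Ω (no
random-effect correlations — only variances are identifiable at these sample
sizes, and the generator draws them independently). An observed SLD of 0
(complete response) is valid data because the residual error is additive.

### Estimation

The marginal likelihood integrates the three random effects per subject.
The default approximation is Laplace: for each subject the posterior mode of
`η` is found by a damped Newton solver (analytic gradients; full analytic
Hessian where positive definite, Gauss–Newton otherwise; per-subject
backtracking line search; Newton-decrement stopping rule), and the mode's
curvature supplies the Gaussian correction. All subjects are solved
simultaneously in vectorized form. An adaptive Gauss–Hermite option
(`FitSettings(method="agq")`, default 5 nodes per dimension, centered and
scaled at the per-subject modes) upgrades the integral when the posterior is
visibly non-Gaussian; with one node it reduces to Laplace.

The outer problem maximizes the approximate marginal likelihood over the
11-dimensional vector (5 typicals, 5 variances, residual variance), all on
the log scale for positivity, with L-BFGS-B under wide bounds. The gradient
is central differences (step 1e-4) with every perturbed evaluation
warm-started from the base point's posterior modes, which keeps each subject
in the same posterior basin and makes the finite differences smooth; the
objective itself re-solves the modes from both the warm start and zero and
keeps the better of the two per subject, so a stale cache can never poison
the fit. Starting values come from per-subject log-linear heuristics
(baseline size; shrink rate from baseline→nadir; growth rate from
nadir→last observation), pooled per arm; up to three jittered restarts run
on non-convergence. Convergence uses scipy's `ftol`/`gtol` (1e-10 / 1e-7,
max 500 iterations). Relative standard errors come from the observed
information (finite-difference Hessian of the negative log-likelihood at the
optimum); because parameters are estimated on the log scale, the log-scale
SE is directly the relative SE of the natural estimate.

Empirical-Bayes estimates (EBEs) are the posterior modes at the final
estimates; η-shrinkage is `100·(1 − SD(η̂)/ω)` per random effect (sample SD,
ddof 1). `fix_omega2_zero=True` collapses the model to plain nonlinear least
squares on the typical values (trust-region `least_squares`, σ² profiled
with the MLE denominator n) — the limiting case used to validate against a
generic curve fitter.

Reporting convention: inter-individual variability is quoted as
CV% = 100·√ω². (With ω² on the log scale this is the conventional
first-order CV quoted by NLME software.)

## Survival model

OS (days) is log-normal: `log T ~ N(μ, scale²)` with

```
μ = β₀ + β_KG·log KG + β_alb·albumin[g/L] + β_ecog·1[ECOG≥1]
  + β_race·1[Asian] + β_met·min(sites,5) + β_nlr·NLR + β_liver·1[liver met]
  + β_sld·baseline SLD[mm] + β_line·1[line 2+] + β_sex·1[female]
```

so `S(t) = 1 − Φ((ln t − μ)/scale)`. `log KG` is the natural logarithm of
the individual KG in week⁻¹ — in the fitted pipeline the EBE from the tumor
model, in the generator the true individual value. Covariates enter in
natural units (no standardization; the published coefficient tables use
natural units). The number of metastatic sites is capped at 5 before
entering the model. Reference levels: ECOG 0, non-Asian, no liver
metastasis, line 1, male.

Fitting is censored maximum likelihood (event terms use the log-normal
density, censored terms the survivor function, with `log_ndtr` for
stability), analytic gradient, BFGS. Standard errors are the inverse
observed information; Wald z = β/SE with two-sided normal p-values, which is
the format of published AFT coefficient tables, and the scale is reported as
log(scale). Covariates that are constant in the estimation sample (e.g.
line of therapy in a strictly first-line trial) are unidentifiable and are
dropped with a record on the fitted model; genuinely collinear designs raise
an error naming the offending columns. An optional backward-elimination
procedure (`select_covariates`, default α = 0.01) drops the least
significant covariate and refits until all remaining effects are
significant; `log KG` is the model's anchor and is never dropped. The exact
covariate-selection procedure used to build published models of this kind is
rarely reported; backward elimination at α = 0.01 is this package's
documented stand-in.

A fitted model and an externally published coefficient table are the same
object (`OSModel`); `from_coefficients` lets a printed table drive
simulation without refitting.

## Virtual-trial simulator

Each replicate: (1) draw one AFT parameter vector — point estimates
(`none`), independent normal draws per coefficient using its SE
(`diagonal-normal`, the default, since published tables carry SEs but no
covariance), or a full multivariate draw when a covariance matrix is
available; (2) compute each subject's μ from their fixed covariates and
log KG; (3) draw `T ~ LogNormal(μ, scale)` and a study duration
`C ~ Uniform(low, high)` (default 1278–1825 days, i.e. a 3.5–5-year window
emulating accrual plus cut-off), observe `(min(T,C), 1[T≤C])`; (4) per arm,
the Kaplan–Meier curve (lifelines) evaluated on a common monthly grid to 60
months, landmark rates (default 2 years) read off the KM curve; (5) the
treatment-vs-control hazard ratio from a Cox fit with Efron tie handling
(lifelines). Replicates where the Cox partial likelihood is degenerate (all
events in one arm) are recorded as missing and excluded from the HR
percentiles with a reported count, never silently. Aggregation is the
pointwise median and 2.5/97.5 percentiles across replicates; the HR
prediction interval is the percentile interval of the per-replicate Cox
estimates. The whole pipeline is bit-reproducible for a fixed seed.

## Synthetic-trial generator

Emulates a two-arm, first-line, ALK-positive advanced-NSCLC design: 143
evaluable subjects per arm plus 17 baseline-only subjects (≈6%, excluded by
the evaluability filter), tumor assessments at baseline and every 8 weeks up
to 260 weeks, stopping at detected progression or death. Generating truths
default to the published population estimates for this setting (tumor
dynamics: KG 0.00196/0.00438 week⁻¹ treatment/control, KS 0.0342/0.0373,
TS0 57 mm, log-scale variances 1.90/0.943/1.10/0.833/0.436, σ² 42.5 mm²;
survival: the 10-covariate AFT coefficient table with intercept 2.87,
β_logKG −0.642, log(scale) −0.225). Every value is configuration.

Covariate marginals (all overridable, chosen as physiologically plausible
for this population): albumin N(40, 4²) g/L truncated above 20; P(ECOG≥1)
0.6; P(Asian) 0.45; metastatic sites 1 + Poisson(1.5); NLR
LogNormal(ln 3.5, 0.5²); P(liver met) 0.2; line 2+ probability 0
(first-line design); P(female) 0.55. Baseline SLD is the subject's generated
true TS0. OS is generated from the *true* individual log KG; the fitted
pipeline uses EBEs, so recovery tolerances absorb the shrinkage-induced
attenuation. Residual noise on SLD is additive normal **clipped at 0** — an
SLD of 0 is a recordable measurement (complete response); resample-style
truncation was evaluated and rejected because it systematically lifts small
values and distorts the growth signal. The progression proxy stops
assessments at the first visit where the true SLD exceeds the running nadir
by 20% plus 5 mm (the visit itself is still observed); this mimics
"assessments until progression or death" and is an artifact choice, with the
real-world difference that progression calls there are made on noisy
measured SLD.

What the generator does not emulate: the joint (correlated) covariate
distribution of a real population, CNS-metastasis stratification, crossover,
non-uniform accrual, or measurement-driven progression calls. Passing
recovery tests therefore demonstrates internal consistency of the estimators
under the stated design, not performance on real trial data.

## Problem sizes and numerical choices

- Tumor-model recovery experiments: 3 virtual trials of ~303 subjects
  (~286 evaluable), Laplace fit, ~15 s each on one CPU.
- Survival-model recovery: 2000 subjects, ~40% censoring via
  Uniform(400, 4500)-day study durations (bounds calibrated once to give
  that fraction under the default samplers, then frozen); line-2+ prevalence
  0.25 in this experiment so all ten coefficients are estimable.
- Simulation experiments: 286 fixed subjects, 1000 replicates (~40 s).
- Guards: exponents clipped at ±60, random effects clipped at ±25 on the log
  scale, non-finite likelihoods mapped to a penalty dominating any real
  value. Quadrature oracle in the tests: tensor Gauss–Hermite (25 nodes per
  dimension) centered and scaled at modes found by an independent
  Nelder-Mead/BFGS search.

## Known limitations

- Maximum-likelihood estimates of the KG variance under the default design
  are systematically low (≈ −15 to −25% versus the realized sample variance
  of the drawn effects; verified to persist under exact adaptive-quadrature
  likelihood and to vanish in a high-information regime, so it is a
  small-information finite-sample property, not an approximation artifact).
  Zero-clipping of the observed SLD adds a few further points. The variance
  recovery tolerance (±30%) absorbs this; users comparing fitted ω² across
  designs should expect the same attenuation.
- Observation stopping at progression/death depends on the latent individual
  parameters, which the likelihood ignores (standard practice for this model
  class); this mildly attenuates variance components as well.
- The log-normal AFT has non-proportional hazards; the simulated Cox HR is a
  population-averaged summary whose value depends on follow-up length and
  censoring pattern.
- The Laplace approximation error grows with inter-individual variance and
  sparsity; the `agq` option trades ~4× runtime for a materially better
  integral when ω² is large.
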