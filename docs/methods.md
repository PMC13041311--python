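# Methods

## Scientific setting

Cefepime is renally cleared, and in acute kidney injury (AKI) its plasma
half-life is prolonged roughly ten-fold; the accumulating drug crosses the
blood–brain barrier, antagonises GABA_A signalling and can precipitate
seizures.  The package models a rat study of this phenomenon: folic-acid AKI
rats receive high-dose i.v. cefepime, plasma is sampled repeatedly, the
cerebral cortex and hippocampus are sampled once per animal at serial
sacrifice, seizures are scored on a modified Racine scale (0–7), and the
exposure–toxicity relationship is quantified as a TC₅₀ — the exposure at
which the fitted logistic model gives 50% seizure probability.

## Structural model

A linear three-compartment mammillary system (amounts in mg, volumes in L,
times in h):

```
dA_central/dt     = −(kel + k12 + k13)·A_central + k21·A_cortex + k31·A_hippocampus + R(t)
dA_cortex/dt      = k12·A_central − k21·A_cortex
dA_hippocampus/dt = k13·A_central − k31·A_hippocampus
C_x = A_x / V_x
```

`R(t)` is the piecewise-constant infusion rate.  Because the system is
linear with piecewise-constant input, each inter-breakpoint segment is
solved **exactly** with a matrix exponential of the augmented (state + input)
system; an eigendecomposition fast path (the mammillary structure guarantees
a real spectrum) serves the estimation hot loop, with the matrix-exponential
propagator as fallback for degenerate spectra.  Mass balance — amounts in the
three compartments plus cumulative elimination equal cumulative input — is
tracked explicitly and holds to ≲1e−15 relative.

Default parameters (`final_model_population()`): kel 0.14 h⁻¹, V_central
0.12 L, V_cortex 0.0039 L, V_hippocampus 0.00039 L, k12 0.00013 h⁻¹,
k21 0.17 h⁻¹, k13 1.5e−5 h⁻¹, k31 0.15 h⁻¹.  kel and V_central scale
allometrically with body weight (exponents 0.75 and 1, reference 0.282 kg).
With these values a single 1,593 mg/kg infusion into a 282-g rat yields a
plasma AUC₀₋₂₄ near 2.6·10⁴ mg·h/L and brain Cmax near 36 (cortex) and
44 (hippocampus) mg/L — the exposure scale at which seizures appear.

Units: brain tissue concentrations in µg/g are treated as numerically equal
to mg/L (tissue density 1 g/mL).  Dose conversions use the FDA
body-surface-area factor 6.2 between human and rat mg/kg doses; rounding to
whole mg/kg is applied only for display.  Infusion durations default to
5 min for the main-study doses and 2 min for the preliminary bolus arm (the
protocol reports only a pump-rate range, so the exact durations are a design
choice here).

## Population model

Individual parameters are lognormal around covariate-scaled medians:
`log p_i = log p_pop + β·log(W_i/W_ref) + η_i`, `η ~ N(0, Ω)`.  Ω is
diagonal except one off-diagonal — the correlation between the kel and
V_hippocampus random effects (0.92 in the final model), the single
correlation whose inclusion improved the model-selection criterion.  k12 and
k13 are held fixed by default: with one terminal brain sample per animal the
slow influx constants are not individually estimable.

The study reports no between-subject SDs or residual-error magnitudes, so
the generator uses package defaults chosen once as realistic for this kind
of preclinical PK data: ω(kel) = 0.40 (AKI severity varies between animals),
ω(V_central) = 0.10, ω = 0.25 for the brain volumes and efflux constants,
and a combined residual error a = 0.5 mg/L (the assay's lower limit) with
b = 0.15 (15% CV; assay imprecision is <5%, and the remainder absorbs model
misspecification) in every matrix.  Residual error is combined
additive + proportional, `SD = √(a² + (b·f)²)`, selectable per matrix
(`additive`, `proportional`, `combined`, `fixed`).

Concentrations below the limit of quantification (LOQ, default 0.5 mg/L —
the assay's lower calibration bound) are interval-censored on (0, LOQ]: the
M3 treatment with a positivity constraint.  The pre-dose samples the design
collects at time 0 naturally exercise this path.

## SAEM estimation

No Python package provides nonlinear mixed-effects estimation, so the SAEM
machinery is implemented here.

* **Latent variables** are the individual log-parameter vectors.  Each
  iteration runs, per subject and chain, one independent
  Metropolis–Hastings proposal from the prior, one joint prior-shaped
  random walk and one componentwise random-walk sweep; step sizes adapt
  toward 35% acceptance during the exploratory phase only.  The
  componentwise kernel matters: plasma-rich data make some η components
  (kel, V_central) far better determined than the brain components, and a
  joint kernel alone mixes the weak components too slowly to recover the
  random-effect correlation.
* **Stochastic approximation**: step size 1 for the exploratory phase
  (default 300 iterations), 1/(k−K₁) for the smoothing phase (default 200);
  default 5 chains (the experiments below use 2–4, noted per experiment).
  μ and Ω update in closed form from smoothed sufficient statistics; BLQ
  residuals are imputed from the truncated Gaussian for the error-parameter
  statistics, and the combined-error M-step is a small Nelder–Mead in
  (log a, log b).
* **Stabilisation**: during exploration, Ω variances may shrink at most 5%
  per iteration (the usual annealing guard against premature collapse), and
  the residual-error parameters move at most ±5% per iteration in *either*
  direction — without the upward bound, the gross misfit of the initial
  guess inflates the proportional error in the first iterations and the
  run settles in a flat-likelihood local solution.
* **Likelihood, criteria**: −2LL at the final estimates by importance
  sampling (t proposal, df 4, 300 draws/subject, centred at the
  empirical-Bayes mode with Laplace covariance).  AIC = −2LL + 2k,
  BIC = −2LL + k·ln(n) with n = number of subjects (the convention is
  recorded in the fit output).  Optional RSE% for the population medians
  from per-subject scores of the importance-sampled log-likelihood
  (central differences with common random numbers, information ≈ sum of
  score outer products); this is a score-based asymptotic estimate and is
  labelled as such.
* **Empirical Bayes**: MAP of η by multi-start damped Newton (starts at the
  chain state, η = 0, and three prior draws) on batched finite-difference
  stencils; posterior profiles on a 0.1-h grid feed the exposure metrics.

Fits are bit-reproducible for a given seed and configuration.

## Exposure metrics and toxicodynamics

AUC₀₋₂₄ by linear trapezoid and Cmax/tmax by grid maximum, both on fixed
0.1-h (6-min) grids so the metrics do not depend on the solver grid.  The
logistic TC₅₀ (`fit_logistic_tc50`) is a maximum-likelihood logit of the
dichotomized Racine stage (>1) on a single exposure metric — one model per
metric, as in the source analysis — with TC₅₀ = −β₀/β₁ and a delta-method
SE; complete separation is flagged and reported as bounds (the gap between
the outcome classes), never as a silent estimate.  Group comparisons use
the two-sided Mann–Whitney test (exact enumeration for groups ≤8 without
ties; continuity- and tie-corrected normal approximation otherwise — the
two agree within 0.01 at the sizes where the switch occurs).  Time to
seizure is summarised by Kaplan–Meier product-limit curves for animals
above vs below a plasma-AUC cut-off (default: the fitted plasma AUC TC₅₀),
with non-seizing animals censored at sacrifice and stage-7 animals (death)
counted as events at their event time.

The outlier screen removes quantified plasma records whose leave-one-out
z-score within (matrix × nominal post-dose time) strata exceeds 3 SD;
leave-one-out keeps a gross outlier from masking itself by inflating its
own stratum SD.  The exclusion report lists every removal with its stratum
and z-score.

## Synthetic cohorts

`generate_cohort` emulates the study design: 18 rats (configurable),
weights ~N(0.282, 0.017²) kg truncated at 3 SD; day-1-sacrifice rats
receive 1,593 mg/kg once, day-3/5 rats 1,250 mg/kg daily; plasma sampled at
0, 15, 30, 120 min after each dose up to sacrifice; one terminal cortex and
hippocampus sample per rat at its serial-sacrifice slot (30/120 min day 1,
120 min day 3 and 5, round-robin).  AKI is a constant multiplier (default
0.1) on each rat's kel: the generator's base population carries the
healthy-kidney kel of 1.4 h⁻¹, so the default multiplier reproduces the
study-state 0.14 h⁻¹ and, by construction, a 10× half-life prolongation.
An optional linear-recovery hook (`kel_recovery_per_day`, default 0) raises
the multiplier day by day, emulating the spontaneous return of renal
function over about a week; when enabled, profiles are solved exactly
within each day and chained across days, so only the daily (rather than
continuous) multiplier update is approximate.

Seizure outcomes come from a logistic model on the true (noise-free)
exposure — default driver: hippocampal Cmax, TC₅₀ 48.2 mg/L, slope
3/TC₅₀ — with the Racine stage drawn uniformly from {2..6} for seizing rats
(stage 7 frequency 0 by default; the study reports no stage distribution)
and the event time uniform on 1–4 h after the first dose; non-seizing rats
score 0 or 1 and are censored at sacrifice.  Ground truth (individual
parameters, noise-free exposures, outcome probabilities) is returned with
the cohort and serialised as a JSON sidecar.

What the generator does *not* emulate: assay drift or dilution workflow,
time-varying renal function, between-occasion variability, covariates other
than weight, and any real misspecification between the data-generating and
fitted structural model.  Passing recovery tests therefore demonstrate that
the estimation machinery is correct and well-calibrated under the study
design — not that the three-compartment model is the right model for real
rats.

## Experiment sizes and numerical choices

Recovery experiments in the test suite and acceptance script use cohorts of
100 rats (population medians; SAEM 300+200 iterations, 3 chains) and 200
rats (random-effect correlation; 4 chains), with starting values displaced
from the truth (kel 0.3, V_central 0.2, brain constants 0.3, volumes off by
~2×) so the fit performs genuine optimisation.  TC₅₀ recovery uses 500
animals with exposures uniform on [0, 2·TC₅₀] and slope 3/TC₅₀.  The
bundled pipeline configuration runs the 18-rat design with a shortened
schedule (150+100, 2 chains) suitable for interactive use.

Degenerate inputs: zero-amount regimens yield identically zero profiles;
observations at exactly a dose time take the pre-dose value; a subject with
no observations shrinks to the covariate-scaled population parameters; a
matrix with constant observations reports R² as missing rather than
failing; complete separation in the logistic fit returns bounds, not an
estimate.

## Known limitations

* Brain transfer constants k12/k13 are fixed, and k21/k31/V_cortex
  estimates rest on one terminal sample per animal; their recovery is
  noticeably noisier than kel/V_central and degrades for cohorts much
  smaller than the defaults.
* RSE% is score-based asymptotic, not bootstrap; it is off by default and
  computed only on request.
* The M3 interval is (0, LOQ]; simulated BLQ flags include the (tiny)
  probability mass below zero that the positivity-constrained likelihood
  attributes to the interval.
* The importance-sampled −2LL is a Monte-Carlo estimate; model-ladder
  comparisons closer than a few points should increase `n_importance`.
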