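# cefetox

Population pharmacokinetic/toxicodynamic modelling of cefepime brain
exposure and seizures in rats with acute kidney injury (AKI).

Cefepime is cleared by the kidneys; in renal failure it accumulates,
crosses the blood–brain barrier and can cause seizures.  This package
implements, end to end, the quantitative analysis of a preclinical rat
study of that phenomenon, for pharmacometricians and quantitative
pharmacologists who want to simulate, fit and analyse such designs:

* **Structural model** — a linear three-compartment system
  (plasma → cerebral cortex, plasma → hippocampus) solved exactly by
  piecewise matrix exponentials:

  ```
  dA_c/dt = −(kel + k12 + k13)·A_c + k21·A_cx + k31·A_hip + R(t)
  dA_cx/dt  = k12·A_c − k21·A_cx
  dA_hip/dt = k13·A_c − k31·A_hip          C_x = A_x / V_x
  ```

  with allometric weight scaling (kel ∝ W^0.75, V_central ∝ W) and the
  human↔rat body-surface-area dose conversion (×6.2).
* **Population layer** — lognormal between-subject variability with a
  single retained random-effect correlation, corr(η_kel, η_V_hippocampus);
  combined residual error; interval-censored (M3, positivity-constrained)
  likelihood for below-LOQ records.
* **Estimation** — SAEM (stochastic approximation EM) written for this
  model family: batched MCMC over individual parameters, closed-form
  M-steps, importance-sampled −2LL, AIC/BIC, empirical-Bayes (MAP)
  individual profiles, goodness-of-fit diagnostics (obs-vs-pred R², PWRES),
  and a 3-SD outlier screen.
* **Toxicodynamics** — AUC₀₋₂₄/Cmax₀₋₂₄ exposure metrics on 6-min grids,
  logistic TC₅₀ (the exposure giving 50% seizure probability,
  TC₅₀ = −β₀/β₁), Mann–Whitney group comparisons, and Kaplan–Meier
  time-to-seizure curves split at an exposure cut-off.
* **Synthetic cohorts** — a generator reproducing the study design
  (18 rats, 1,593 mg/kg once or 1,250 mg/kg/day i.v., plasma at
  0/15/30/120 min post-dose, terminal brain samples at serial sacrifice,
  AKI as a 10× prolongation of half-life, Racine-scale outcomes from a
  logistic exposure–toxicity model) with full ground truth attached.

See `docs/methods.md` for the model, algorithms, defaults and limitations.

## Worked example

`examples/04_fit_population.py` simulates a 40-rat cohort from the
final-model values, screens outliers, and fits the population model by SAEM
starting from deliberately wrong initial values (about one minute):

```
6 plasma record(s) excluded by the 3-SD screen

parameter            truth    estimate
kel                   0.14       0.144
V_central             0.12      0.1223
V_cortex            0.0039    0.003926
V_hippocampus      0.00039   0.0003957
k21                   0.17      0.1572
k31                   0.15      0.1421
corr(kel,Vhip)        0.92        0.98

-2LL = 5469.4   AIC = 5507.4   BIC = 5539.5 (n = subjects, k = 19)
```

The elimination rate constant (kel, h⁻¹), central volume (L) and brain
transfer/volume parameters are recovered within a few percent, and the
kel–V_hippocampus random-effect correlation — animals that clear drug
faster tend to have larger hippocampal distribution volumes, hence lower
local concentrations — is found again from the data.

The other examples cover the dose-scaling arithmetic
(86 → 531 → 1,593 → 2,124 mg/kg/day), single-animal concentration profiles
(brain Cmax ≈ 36–44 mg/L after the maximum tolerated dose), cohort
generation, and the TC₅₀ / rank-sum / Kaplan–Meier toxicodynamic stage.

## Command line

A thin CLI wraps the pipeline for shell use:

```bash
cefetox run-all --seed 5 --output-dir run5      # simulate → fit → TC50 → KM
cefetox simulate --config my_config.yaml        # individual stages
```

Runs are byte-reproducible for a given configuration and seed; stage
outputs (dataset CSV, fit JSON, exposure/TC50/KM tables, diagnostics) land
in the output directory with a manifest in `run_report.json`.

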