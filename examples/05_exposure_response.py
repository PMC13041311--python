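"""Toxicodynamic analysis: TC50, group comparison and time-to-seizure.

Runs the complete pipeline on the bundled 18-rat configuration, then reads
the stage outputs: the logistic TC50 per exposure metric, the Mann-Whitney
comparison of exposures between seizure groups, and the Kaplan-Meier
time-to-seizure curves split at the plasma AUC TC50.  Takes ~15 s.
"""

import json
from pathlib import Path

import pandas as pd

from cefetox.cli import default_config
from cefetox.pipeline import run_pipeline

out = Path("scratch_run")
report = run_pipeline(default_config(seed=5, output_dir=str(out)))
print(f"pipeline wrote {len(report.manifest)} files to {out}/ "
      f"(config hash {report.config_hash})\n")

tc = json.loads((out / "tc50.json").read_text())
print("TC50 estimates (exposure at 50% seizure probability):")
for key in ("auc_plasma", "auc_hippocampus", "cmax_cortex", "cmax_hippocampus"):
    d = tc[key]
    unit = "mg·h/L" if key.startswith("auc") else "mg/L"
    print(f"  {key:18s} {d['tc50']:10.1f} {unit}  (n={d['n']}, "
          f"converged={d['converged']})")

print("\nMann-Whitney exposure comparison, stage <=1 vs > 1:")
print(pd.read_csv(out / "ranksum.csv").to_string(index=False))

km = pd.read_csv(out / "km_curves.csv")
print("\nKaplan-Meier (plasma AUC above vs below the TC50 cut-off):")
print(km.groupby("group")["survival"].min().rename("final seizure-free fraction")
      .to_string())
print("\nHigh-exposure animals seize early (1-4 h post-dose); low-exposure")
print("animals are censored seizure-free at sacrifice.  With only 18 animals")
print("the per-metric TC50s are noisy (a weak or negative slope can even put")
print("the 50% crossing outside the observed range); the recovery experiments")
print("in the test suite quantify this at n = 500.")
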