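"""Plot-file rendering for a completed pipeline run directory.

Panels mirror the analysis outputs: exposures by outcome group (strip plots),
logistic exposure-toxicity curves with their TC50s, and the Kaplan-Meier
time-to-seizure curves.  Everything is rendered from the stage CSV/JSON
tables, never recomputed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_MATS = ("plasma", "cortex", "hippocampus")


def plot_exposures(out: Path) -> None:
    df = pd.read_csv(out / "exposure_table.csv")
    fig, axes = plt.subplots(2, 3, figsize=(10, 6), sharex=True)
    for row, metric in enumerate(("AUC", "CMAX")):
        for col, m in enumerate(_MATS):
            ax = axes[row, col]
            for grp, x in (("stage<=1", 0), ("stage>1", 1)):
                vals = df.loc[df["SEIZURE"] == x, f"{metric}_{m}"]
                jitter = np.linspace(-0.15, 0.15, max(len(vals), 1))
                ax.plot(np.full(len(vals), x) + jitter[:len(vals)], vals, "o",
                        alpha=0.6, label=grp if (row, col) == (0, 0) else None)
            ax.set_yscale("log")
            ax.set_title(f"{metric}$_{{0-24}}$ {m}", fontsize=9)
            ax.set_xticks([0, 1], ["stage ≤1", "stage >1"])
    fig.tight_layout()
    fig.savefig(out / "fig_exposures.png", dpi=110)
    plt.close(fig)


def plot_tc50(out: Path) -> None:
    df = pd.read_csv(out / "exposure_table.csv")
    tc = json.loads((out / "tc50.json").read_text())
    keys = [k for k in sorted(tc) if np.isfinite(tc[k].get("tc50") or np.nan)]
    if not keys:
        return
    fig, axes = plt.subplots(1, len(keys), figsize=(3 * len(keys), 3))
    axes = np.atleast_1d(axes)
    for ax, key in zip(axes, keys):
        metric, m = key.split("_", 1)
        x = df[f"{metric.upper()}_{m}"].to_numpy()
        y = df["SEIZURE"].to_numpy()
        d = tc[key]
        grid = np.linspace(0, max(x.max(), d["tc50"]) * 1.1, 200)
        p = 1 / (1 + np.exp(-(d["intercept"] + d["slope"] * grid)))
        ax.plot(grid, p, "-")
        ax.plot(x, y, "k|", alpha=0.7)
        ax.axvline(d["tc50"], ls="--", color="gray")
        ax.set_title(f"{key}\nTC50 = {d['tc50']:.1f}", fontsize=8)
        ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(out / "fig_tc50.png", dpi=110)
    plt.close(fig)


def plot_km(out: Path) -> None:
    path = out / "km_curves.csv"
    if not path.exists():
        return
    df = pd.read_csv(path)
    fig, ax = plt.subplots(figsize=(4, 3))
    for grp, sub in df.groupby("group"):
        ax.step(sub["time"], sub["survival"], where="post", label=grp)
    ax.set_xlabel("time after first dose (h)")
    ax.set_ylabel("seizure-free fraction")
    ax.legend(title="plasma AUC vs cut-off")
    fig.tight_layout()
    fig.savefig(out / "fig_km.png", dpi=110)
    plt.close(fig)


def render_all(out: Path) -> None:
    plot_exposures(out)
    plot_tc50(out)
    plot_km(out)
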