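"""Figures from the cohort tables written by 01_run_cohort.py.

Produces, under results/figures/:
  distance_profiles.png  - median SUV_mean error (bars) with interquartile
                           range (errorbars) vs distance to bone / air
  regional_errors.png    - per-region box plots of SUV_mean errors
  threshold_fractions.png- fraction of voxels within +/-5/10/20 % error

Usage: python analysis/02_make_figures.py
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
FIG = ROOT / "figures"

COLORS = {"deep": "tab:blue", "atlas": "tab:orange"}


def distance_profiles():
    agg = pd.read_csv(ROOT / "cohort" / "profiles_aggregate.csv")
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=False)
    for ax, comp in zip(axes, ("bone", "air")):
        for i, method in enumerate(("deep", "atlas")):
            d = agg[(agg["method"] == method) & (agg["compartment"] == comp)]
            d = d[d["bin"] <= 8]
            x = d["bin"] + 0.38 * i - 0.19
            ax.bar(x, d["median"], width=0.36, color=COLORS[method], label=f"PET_{method}")
            yerr = [d["median"] - d["lq"], d["uq"] - d["median"]]
            ax.errorbar(x, d["median"], yerr=yerr, fmt="none", ecolor="k", capsize=2)
        ax.axhline(0, color="gray", lw=0.8)
        ax.set_xticks(range(9))
        ax.set_xticklabels(["in"] + [f"{3*(k-1)}-{3*k}" for k in range(1, 9)], fontsize=8)
        ax.set_xlabel(f"distance to {comp} (mm)")
        ax.set_ylabel("SUV$_{mean}$ error (%)")
        ax.set_title(f"error vs distance to {comp}")
        ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "distance_profiles.png", dpi=150)


def regional_errors():
    tab = pd.read_csv(ROOT / "cohort" / "regional_errors.csv")
    regions = sorted(tab["region"].unique())
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, method in enumerate(("deep", "atlas")):
        data = [
            tab[(tab["method"] == method) & (tab["region"] == r)]["error_pct"].dropna()
            for r in regions
        ]
        pos = [j + 0.38 * i - 0.19 for j in range(len(regions))]
        bp = ax.boxplot(data, positions=pos, widths=0.3, patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(COLORS[method])
    ax.axhline(0, color="gray", lw=0.8)
    ax.set_xticks(range(len(regions)))
    ax.set_xticklabels(regions, rotation=30, ha="right")
    ax.set_ylabel("SUV$_{mean}$ error (%)")
    ax.set_title("regional errors (blue: deep-like, orange: atlas-like)")
    fig.tight_layout()
    fig.savefig(FIG / "regional_errors.png", dpi=150)


def threshold_fractions():
    rep = json.loads((ROOT / "cohort" / "cohort_report.json").read_text())
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, method in enumerate(("deep", "atlas")):
        frac = rep["cohort"][method]["frac_within"]
        ts = sorted(frac, key=float)
        ax.bar(
            [j + 0.38 * i - 0.19 for j in range(len(ts))],
            [100 * frac[t] for t in ts],
            width=0.36,
            color=COLORS[method],
            label=f"PET_{method}",
        )
    ax.set_xticks(range(3))
    ax.set_xticklabels([f"< {t}%" for t in sorted(rep["cohort"]["deep"]["frac_within"], key=float)])
    ax.set_ylabel("fraction of voxels (%)")
    ax.set_title("voxels within absolute error thresholds")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "threshold_fractions.png", dpi=150)


if __name__ == "__main__":
    FIG.mkdir(parents=True, exist_ok=True)
    distance_profiles()
    regional_errors()
    threshold_fractions()
    print(f"figures written to {FIG}")
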