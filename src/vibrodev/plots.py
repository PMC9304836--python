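"""Optional figures for a finished pipeline run.

Renders the age-trajectory scatter with the selected model curve per
measure, and the two correlation heatmaps.  Imported lazily by the CLI so
matplotlib is only touched when figures are requested.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import GeneratingCurve, MEASURES, evaluate_curve

__all__ = ["render_run_figures"]


def render_run_figures(outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    paths: list[Path] = []
    table = pd.read_csv(outdir / "included_outcomes.csv")
    models = json.loads((outdir / "model_report.json").read_text())

    fig, axes = plt.subplots(2, 3, figsize=(13, 7), constrained_layout=True)
    grid = np.linspace(3.0, 23.0, 300)
    for ax, measure in zip(axes.ravel(), MEASURES):
        sub = table[["age", measure]].dropna()
        ax.scatter(sub["age"], sub[measure], s=12, alpha=0.6)
        entry = models.get(measure, {})
        if "chosen" in entry:
            best = entry["candidates"][entry["chosen"]]
            curve = GeneratingCurve(best["family"], best["coefficients"])
            ax.plot(grid, evaluate_curve(curve, grid), color="crimson")
            ax.set_title(f"{measure} ({best['family']})")
        else:
            ax.set_title(measure)
        ax.set_xlabel("age (years)")
    path = outdir / "trajectories.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(11, 5), constrained_layout=True)
    for ax, stem, title in (
        (axes[0], "correlations_adult_r", "adults (18-23)"),
        (axes[1], "correlations_under18_r", "under 18"),
    ):
        r = pd.read_csv(outdir / f"{stem}.csv", index_col=0)
        im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(r.columns)), r.columns, rotation=45)
        ax.set_yticks(range(len(r.index)), r.index)
        ax.set_title(title)
    fig.colorbar(im, ax=axes, shrink=0.8, label="Pearson r")
    path = outdir / "correlation_heatmaps.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)
    return paths
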