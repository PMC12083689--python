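"""Diagnostic figures (matplotlib, Agg backend; files only, no display)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .distill import CutoffSet
from .stats import SurvivalCurve

__all__ = ["plot_distillation", "plot_km_groups"]


def plot_distillation(cutoffset: CutoffSet, path) -> None:
    """Split density vs data density, their difference, and chosen cutoffs."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    if cutoffset.split_density is not None:
        grid = cutoffset.split_density.grid
        ax.plot(grid, cutoffset.split_density.density, label="split-threshold density")
        ax.plot(grid, cutoffset.data_density.density, label="training-value density")
        ax.plot(grid, cutoffset.difference, label="difference", linestyle="--")
    for c in cutoffset.cutoffs:
        ax.axvline(c, color="firebrick", alpha=0.7)
    ax.set_xlabel(cutoffset.variable)
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    ax.set_title(f"Distilled cutoffs for {cutoffset.variable}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km_groups(curves: dict[int, SurvivalCurve], path, title: str = "Risk groups") -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for group, curve in sorted(curves.items()):
        ax.step(curve.time, curve.survival, where="post", label=f"Group {group}")
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
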