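"""Diagnostic scatter plots for reaction-norm evolution output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_slope_comparison(
    ancestral_slopes: pd.Series,
    evolved_slopes: pd.Series,
    highlight: pd.Index | None = None,
    path=None,
    ax=None,
):
    """Ancestral vs evolved reaction-norm slopes (log2FC 23 vs 15 C).

    Points on the identity line kept their plasticity; deviations above
    |x| = |y| magnified it.  ``highlight`` marks a gene subset (e.g.
    significant slope changes).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    common = ancestral_slopes.index.intersection(evolved_slopes.index)
    x, y = ancestral_slopes.loc[common], evolved_slopes.loc[common]
    ax.scatter(x, y, s=4, alpha=0.3, color="grey", label="all genes")
    if highlight is not None and len(highlight):
        hi = common.intersection(highlight)
        ax.scatter(x.loc[hi], y.loc[hi], s=8, color="crimson", label="highlighted")
    lim = float(max(np.abs(ax.get_xlim()).max(), np.abs(ax.get_ylim()).max()))
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="black")
    ax.set_xlabel("ancestral slope (log2FC 23 vs 15 °C)")
    ax.set_ylabel("evolved slope (log2FC 23 vs 15 °C)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_shift_scatter(class_table: pd.DataFrame, cls: str = "INCREASED",
                       path=None, ax=None):
    """Evolved expression shift at 15 C vs at 23 C for one class.

    Anti-concordant genes (opposite-sign shifts, the signature of
    reinforced plasticity) fall in the top-left and bottom-right quadrants.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = class_table[class_table["class"] == cls]
    ax.scatter(sub["delta15"], sub["delta23"], s=8, color="tab:blue")
    ax.axhline(0, lw=0.8, color="black")
    ax.axvline(0, lw=0.8, color="black")
    ax.set_xlabel("evolved − ancestral at 15 °C (log2FC)")
    ax.set_ylabel("evolved − ancestral at 23 °C (log2FC)")
    ax.set_title(f"{cls} plasticity genes (n={len(sub)})", fontsize=10)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
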