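"""Plain plotting helpers for the standard study figures.

Requires matplotlib (the ``plot`` extra); everything else in the package
works without it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def accuracy_scatter(acc_x, acc_y, label_x: str, label_y: str,
                     threshold: float = 0.13, ax=None):
    """Voxel-wise accuracy scatter of two models with the significance
    threshold marked (voxels below it in both models drawn in black)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    acc_x = np.asarray(acc_x)
    acc_y = np.asarray(acc_y)
    below = (acc_x <= threshold) & (acc_y <= threshold)
    ax.scatter(acc_x[below], acc_y[below], s=6, c="black", alpha=0.4)
    ax.scatter(acc_x[~below], acc_y[~below], s=6,
               c=np.where(acc_y[~below] > acc_x[~below], "tab:orange", "tab:blue"),
               alpha=0.6)
    lim = max(0.5, float(np.max(np.abs([acc_x, acc_y]))) * 1.05)
    ax.plot([-lim, lim], [-lim, lim], lw=0.8, color="gray")
    for v in (threshold,):
        ax.axvline(v, ls="--", lw=0.8, color="green")
        ax.axhline(v, ls="--", lw=0.8, color="green")
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    return ax


def layer_contribution_bars(table: pd.DataFrame, ax=None):
    """Stacked per-ROI bars of best-layer fractions (rows = ROIs)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    bottom = np.zeros(len(table))
    cmap = plt.get_cmap("viridis")
    for j, col in enumerate(table.columns):
        vals = table[col].to_numpy()
        ax.bar(table.index, vals, bottom=bottom,
               color=cmap(j / max(1, len(table.columns) - 1)), label=col)
        bottom += vals
    ax.set_ylabel("fraction of voxels")
    ax.legend(fontsize=6, ncol=2)
    return ax


def sweep_curves(sweep: pd.DataFrame, ax=None):
    """Mean accuracy vs selection fraction, one line per ROI."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for roi, grp in sweep.groupby("roi"):
        grp = grp.sort_values("fraction")
        ax.plot(grp["fraction"], grp["mean_accuracy"], marker="o", label=roi)
    ax.set_xscale("log")
    ax.set_xlabel("selected fraction of dimensions")
    ax.set_ylabel("mean prediction accuracy (r)")
    ax.legend(fontsize=7)
    return ax
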