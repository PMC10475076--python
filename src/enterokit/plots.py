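"""Basic diagnostic plots: NMDS ordination and the CH k-selection curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_ordination(coordinates: pd.DataFrame, labels=None, stress: float | None = None,
                    ax=None, path=None):
    """Scatter the first two ordination axes, coloured by cluster label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x, y = coordinates.iloc[:, 0], coordinates.iloc[:, 1]
    if labels is None:
        ax.scatter(x, y, s=12, alpha=0.7)
    else:
        labels = np.asarray(labels)
        for g in np.unique(labels):
            mask = labels == g
            ax.scatter(x[mask], y[mask], s=12, alpha=0.7, label=str(g))
        ax.legend(title="cluster", frameon=False)
    ax.set_xlabel(coordinates.columns[0])
    ax.set_ylabel(coordinates.columns[1])
    title = "NMDS"
    if stress is not None:
        title += f" (stress-1 = {stress:.3f})"
    ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_ch_curve(curve, ax=None, path=None):
    """CH index against candidate k, with the selected k marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.k_values, curve.ch, "o-")
    ax.axvline(curve.argmax_k, color="grey", ls="--", lw=1)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("Calinski–Harabasz index")
    ax.set_title(f"selected k = {curve.argmax_k}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


__all__ = ["plot_ordination", "plot_ch_curve"]
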