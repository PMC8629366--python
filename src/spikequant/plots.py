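"""Diagnostic plots: dendrogram, ordination scatter and fit overlay."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _agg():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_dendrogram(tree, path) -> None:
    """Dendrogram of a species ClusterTree."""
    from scipy.cluster.hierarchy import dendrogram

    plt = _agg()
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(tree.labels) + 2))
    dendrogram(tree.linkage_matrix, labels=tree.labels, orientation="left", ax=ax)
    ax.set_xlabel(f"distance ({tree.metric})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ordination(ordination, labels: pd.Series | None, path) -> None:
    """Scatter of the 2-D embedding, optionally colored by a label column."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(7, 6))
    xy = ordination.coordinates
    if labels is not None:
        for value in pd.unique(labels):
            pick = np.asarray(labels == value)
            ax.scatter(xy[pick, 0], xy[pick, 1], s=10, label=str(value), alpha=0.7)
        ax.legend(fontsize=8)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], s=10, alpha=0.7)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fit_overlay(measurement, path) -> None:
    """Half-width profiles with the fitted quadrangle chains overlaid."""
    from ._geometry import upper_chain

    plt = _agg()
    frame, model = measurement.frame, measurement.model
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(frame.x_mm, frame.upper_mm, color="saddlebrown", lw=1, label="contour (upper)")
    ax.plot(frame.x_mm, -frame.lower_mm, color="peru", lw=1, label="contour (lower)")
    ax.plot(frame.x_mm, upper_chain(frame.x_mm, model.xu1, model.yu1, model.xu2, model.yu2, model.L),
            color="green", lw=1.5, label="model (upper)")
    ax.plot(frame.x_mm, -upper_chain(frame.x_mm, model.xb1, model.yb1, model.xb2, model.yb2, model.L),
            color="darkgreen", lw=1.5, label="model (lower)")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("x along centerline (mm)")
    ax.set_ylabel("half-width (mm)")
    ax.set_title(f"residual {model.residual_mm:.2f} mm ({model.status})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
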