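"""Small rendering helpers for the standard diagnostic figures."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_interval_heatmap(matrix, column_index, bin_edges, title="", ax=None):
    """Training heatmap: interval probability distributions over trials."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(
        matrix,
        aspect="auto",
        origin="lower",
        extent=[column_index[0], column_index[-1], bin_edges[0], bin_edges[-1]],
        cmap="magma",
    )
    ax.set_xlabel("trial")
    ax.set_ylabel("interval (ms)")
    ax.set_title(title)
    return ax


def plot_decision_graph(dp, ax=None):
    """Density-peak decision graph (rho vs delta, centers highlighted)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(dp.rho, dp.delta, s=10, c="gray")
    ax.scatter(dp.rho[dp.centers], dp.delta[dp.centers], s=40, c="crimson")
    ax.set_xlabel(r"$\rho$ (local density)")
    ax.set_ylabel(r"$\delta$ (distance to denser point)")
    return ax


def plot_embedding(assignment, ax=None):
    """t-SNE embedding colored by final mode label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    coords = assignment.embedding
    if coords is None:
        raise ValueError("assignment carries no embedding coordinates")
    for lab in np.unique(assignment.labels):
        pts = coords[assignment.labels == lab]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=f"mode {lab}")
    ax.legend(frameon=False, fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
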