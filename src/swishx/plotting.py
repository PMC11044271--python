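"""Plot helpers: replica-merged exposure violins and cluster maps."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .clustermaps import ClusterMap, HOLO_LABEL, NOISE_LABEL

__all__ = ["violin_exposure", "plot_cluster_map"]


def violin_exposure(samples_by_run: dict, ax: Optional[plt.Axes] = None):
    """One violin per simulation, replicas merged (exposure % pooled)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * len(samples_by_run) + 2, 4))
    names = list(samples_by_run)
    ax.violinplot([np.asarray(samples_by_run[n]) for n in names], showmedians=True)
    ax.set_xticks(np.arange(1, len(names) + 1), names, rotation=20)
    ax.set_ylabel("pocket exposure (% of holo volume)")
    return ax


def plot_cluster_map(
    cmap: ClusterMap,
    contours: Optional[Sequence[dict]] = None,
    color_by: Optional[np.ndarray] = None,
    ax: Optional[plt.Axes] = None,
):
    """2-D embedding: clusters colored, noise grey, holo contours overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xy = cmap.coords
    noise = cmap.labels == NOISE_LABEL
    holo = cmap.labels == HOLO_LABEL
    member = cmap.labels >= 0
    ax.scatter(xy[noise, 0], xy[noise, 1], s=4, c="0.8", label="unclustered")
    if np.any(member):
        c = color_by[member] if color_by is not None else cmap.labels[member]
        sc = ax.scatter(xy[member, 0], xy[member, 1], s=6, c=c, cmap="viridis")
        plt.colorbar(
            sc, ax=ax,
            label="exposure (%)" if color_by is not None else "cluster id",
        )
    ax.scatter(xy[holo, 0], xy[holo, 1], s=4, c="crimson", alpha=0.3, label="holo-like")
    for cont in contours or ():
        for line in cont["polylines"]:
            ax.plot(line[:, 0], line[:, 1], "k-", lw=0.8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(loc="best", fontsize=8)
    return ax
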