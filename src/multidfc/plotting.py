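"""Figures for similarity matrices and method dendrograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from .compare import MethodGrouping, SimilarityResult


def plot_similarity_matrix(sim: SimilarityResult, path=None, ax=None):
    """Heatmap of a method x method similarity matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(sim.matrix, cmap="RdBu_r", vmin=-1 if sim.metric != "euclidean" else None)
    ax.set_xticks(range(sim.method_ids.size), sim.method_ids, rotation=45)
    ax.set_yticks(range(sim.method_ids.size), sim.method_ids)
    ax.set_title(f"{sim.level} similarity ({sim.metric})")
    plt.colorbar(im, ax=ax)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_dendrogram(grouping: MethodGrouping, path=None, ax=None):
    """Ward dendrogram with the 0.7 x max-height cutoff line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dendrogram(grouping.linkage_matrix, labels=list(grouping.method_ids), ax=ax)
    ax.axhline(grouping.cutoff, linestyle="--", color="k", linewidth=1)
    ax.set_ylabel("Ward distance")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
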