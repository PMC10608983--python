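"""Figure helpers (matplotlib, legible defaults only)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .buckets import BucketTable
from .pipeline import PCAScores
from .relations import RelationClustering, RelationMatrix

__all__ = [
    "plot_relation_heatmap",
    "plot_pca_scores",
    "plot_venn_counts",
    "plot_cluster_boxplots",
]


def plot_relation_heatmap(
    matrix: RelationMatrix,
    clustering: RelationClustering | None = None,
    path: str | Path | None = None,
):
    """Heatmap of the (symmetrised) relation matrix, dendrogram-ordered
    when a clustering is given."""
    order = clustering.leaf_order() if clustering is not None else matrix.labels
    values = matrix.values.loc[order, order]
    fig, ax = plt.subplots(figsize=(0.25 * len(order) + 2, 0.25 * len(order) + 2))
    im = ax.imshow(values.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="mean adjusted agreement")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pca_scores(pca: PCAScores, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, grp in pca.scores.groupby("class"):
        ax.scatter(grp["PC1"], grp["PC2"], label=str(cls), s=18)
    evr = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)" if len(evr) > 1 else "PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_venn_counts(
    n_common: int, n_only_a: int, n_only_b: int,
    labels: tuple[str, str] = ("SMD", "Boruta"),
    path: str | Path | None = None,
):
    """Two-set Venn diagram of selection overlap counts."""
    fig, ax = plt.subplots(figsize=(4, 3))
    for cx, color in ((-0.55, "tab:blue"), (0.55, "tab:orange")):
        ax.add_patch(plt.Circle((cx, 0), 1.0, alpha=0.35, color=color))
    ax.text(-1.1, 0, str(n_only_a), ha="center", fontsize=12)
    ax.text(0, 0, str(n_common), ha="center", fontsize=12)
    ax.text(1.1, 0, str(n_only_b), ha="center", fontsize=12)
    ax.text(-0.8, 1.15, labels[0], ha="center")
    ax.text(0.8, 1.15, labels[1], ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-1.4, 1.5)
    ax.set_aspect("equal")
    ax.axis("off")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_cluster_boxplots(
    table: BucketTable,
    members: Mapping[int, Sequence[str]],
    max_per_cluster: int = 2,
    path: str | Path | None = None,
):
    """Per-class intensity boxplots of representative cluster variables."""
    panels = [(cl, lab) for cl, labs in sorted(members.items()) for lab in labs[:max_per_cluster]]
    classes = table.classes
    ncol = max(1, len(panels))
    fig, axes = plt.subplots(1, ncol, figsize=(2.2 * ncol, 3), squeeze=False)
    for ax, (cl, lab) in zip(axes[0], panels):
        col = table.column(lab)
        data = [
            [v for v, c in zip(col, table.class_labels) if c == cls] for cls in classes
        ]
        ax.boxplot(data, tick_labels=[c[:6] for c in classes])
        ax.set_title(f"cluster {cl}: {lab}", fontsize=8)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
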