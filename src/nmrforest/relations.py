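"""Variable relation analysis via mean adjusted agreement.

The relation parameter between variables i and j is the average
adjusted agreement with which j can substitute for i across the forest:
over all nodes where i is the primary splitter, j's adjusted agreement
is taken (0 when j is not among the node's stored surrogates), node
values are averaged within each tree, and tree values are averaged over
the trees in which i splits at all.  Unlike plain intensity
correlation, this measures shared *classification* information: two
buckets relate strongly only if the forest can swap one for the other
without changing its decisions.

Downstream utilities: Ward/Euclidean clustering of the relation matrix,
reduction of same-signal bucket groups to their most important member,
and the disambiguation of buckets in which several metabolites
superimpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .buckets import BucketTable, parse_bucket_label
from .forest import SurrogateForestResults

__all__ = [
    "RelationMatrix",
    "mean_adjusted_agreement",
    "correlation_matrix",
    "RelationClustering",
    "cluster_relations",
    "reduce_same_signal",
    "adjacency_signal_groups",
    "disambiguate_bucket",
    "BucketVerdict",
    "cluster_boxplot_data",
]


@dataclass
class RelationMatrix:
    """Pairwise mean adjusted agreement among variables.

    ``values`` is the symmetrised matrix (element-wise mean with its
    transpose) used for clustering and heatmaps; ``directed`` keeps the
    raw row->column version.  Entries are clamped to [0, 1]; the
    diagonal is 1 by convention.
    """

    values: pd.DataFrame
    directed: pd.DataFrame
    symmetrized: bool = True

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def get(self, i: str, j: str) -> float:
        return float(self.values.loc[i, j])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path)
        return path


def mean_adjusted_agreement(
    results: SurrogateForestResults,
    variables: Sequence[str] | None = None,
    symmetrize: bool = True,
) -> RelationMatrix:
    """Mean adjusted agreement relation matrix of a fitted forest.

    Requires a forest grown with ``s >= 1``; rows of variables that
    never act as a primary splitter are 0.  ``variables`` restricts the
    returned matrix to a label subset (the full forest is still used).
    """
    if results.params.s < 1:
        raise ValueError("relation analysis requires a forest fitted with s >= 1 surrogates")
    model = results.model
    p = model.n_features
    acc = np.zeros((p, p))
    tree_count = np.zeros(p)
    vec_sum = np.zeros((p, p))  # scratch: per-tree sums per primary var
    node_count = np.zeros(p)
    for tree in results.trees:
        vec_sum[:] = 0.0
        node_count[:] = 0.0
        seen: set[int] = set()
        for node in range(tree.n_nodes):
            v = int(tree.var[node])
            if v < 0:
                continue
            seen.add(v)
            node_count[v] += 1
            ss = tree.surrogates[node]
            if ss is not None and len(ss):
                vec_sum[v, ss.variables] += ss.adjusted
        for v in seen:
            acc[v] += vec_sum[v] / node_count[v]
            tree_count[v] += 1
    with np.errstate(invalid="ignore"):
        rel = np.where(tree_count[:, None] > 0, acc / np.maximum(tree_count, 1)[:, None], 0.0)
    rel = np.clip(rel, 0.0, 1.0)
    np.fill_diagonal(rel, 1.0)
    directed = pd.DataFrame(rel, index=model.var_labels, columns=model.var_labels)
    if variables is not None:
        missing = [v for v in variables if v not in directed.index]
        if missing:
            raise ValueError(f"unknown variables: {missing}")
        keep = [l for l in model.var_labels if l in set(variables)]
        directed = directed.loc[keep, keep]
    sym = (directed + directed.T) / 2.0
    return RelationMatrix(
        values=sym if symmetrize else directed.copy(),
        directed=directed,
        symmetrized=symmetrize,
    )


def correlation_matrix(
    table: BucketTable, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of bucket intensities.

    The classical (STOCSY-style) comparator to the relation parameter.
    Zero-variance columns yield NaN entries.
    """
    if table.n_samples < 3:
        raise ValueError("correlation requires at least 3 samples")
    labels = table.labels if variables is None else [l for l in table.labels if l in set(variables)]
    sub = table.select(labels)
    X = sub.intensities
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=sub.labels, columns=sub.labels)


@dataclass
class RelationClustering:
    """Ward/Euclidean clustering of relation-matrix rows."""

    linkage: np.ndarray
    labels: pd.Series  # variable label -> cluster id (1-based)
    members: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        idx = list(self.labels.index)
        return [idx[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("cluster").rename_axis("bucket").to_frame()

    def dendrogram_text(self) -> str:
        lines = ["merge  height  members"]
        n = len(self.labels)
        for i, (a, b, h, size) in enumerate(self.linkage):
            lines.append(f"{n + i:5d}  {h:6.3f}  {int(a)} + {int(b)} ({int(size)})")
        return "\n".join(lines)


def cluster_relations(
    matrix: RelationMatrix, k: int | None = 4, height: float | None = None
) -> RelationClustering:
    """Hierarchical clustering of relation rows (Euclidean, Ward).

    Cut either at ``k`` clusters or at a merge ``height``.
    """
    values = matrix.values
    n = len(values)
    if n < 2:
        raise ValueError("clustering requires at least 2 variables")
    if height is None:
        if k is None:
            raise ValueError("either k or height is required")
        if not 1 <= k <= n:
            raise ValueError(f"k must be between 1 and {n}, got {k}")
    Z = hierarchy.linkage(values.to_numpy(), method="ward", metric="euclidean")
    if height is not None:
        flat = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=values.index, name="cluster")
    members: dict[int, list[str]] = {}
    for lab, cl in labels.items():
        members.setdefault(int(cl), []).append(lab)
    return RelationClustering(linkage=Z, labels=labels, members=dict(sorted(members.items())))


# ----------------------------------------------------------------------
# same-signal reduction


def _as_groups(groups) -> list[list[str]]:
    if isinstance(groups, Mapping):
        return [list(v) for _, v in sorted(groups.items())]
    return [list(g) for g in groups]


def reduce_same_signal(
    selected: Sequence[str],
    smd_scores: Mapping[str, float] | pd.Series,
    groups,
) -> list[str]:
    """Reduce same-signal bucket groups to one representative each.

    The representative is the group member with the lowest surrogate
    minimal depth (highest importance); ties break on bucket label
    order.  Selected labels outside any group pass through.  Returns
    representatives in the order of ``selected``.
    """
    glists = _as_groups(groups)
    for g in glists:
        if not g:
            raise ValueError("signal groups must be non-empty")
    sel = list(selected)
    sel_set = set(sel)
    rep_of: dict[str, str] = {}
    for g in glists:
        members = [l for l in g if l in sel_set]
        if not members:
            continue
        for l in members:
            if l not in smd_scores:
                raise ValueError(f"no SMD score for grouped bucket {l!r}")
        best = min(members, key=lambda l: (float(smd_scores[l]), l))
        for l in members:
            rep_of[l] = best
    out: list[str] = []
    for l in sel:
        rep = rep_of.get(l, l)
        if rep not in out:
            out.append(rep)
    return out


def adjacency_signal_groups(
    labels: Sequence[str],
    matrix: RelationMatrix,
    *,
    max_gap_ppm: float = 0.02,
    min_relation: float = 0.7,
) -> list[list[str]]:
    """Same-signal grouping without annotations.

    Connected components of the graph joining buckets whose centres lie
    within ``max_gap_ppm`` (two 0.01 ppm buckets — the maximal multiplet
    extent for J <= 18 Hz at 400 MHz) and whose relation is at least
    ``min_relation``.
    """
    labs = list(labels)
    centers = {l: parse_bucket_label(l).center_ppm for l in labs}
    parent = {l: l for l in labs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            if abs(centers[a] - centers[b]) <= max_gap_ppm + 1e-9 and matrix.get(a, b) >= min_relation:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for l in labs:
        comps.setdefault(find(l), []).append(l)
    return [sorted(v) for _, v in sorted(comps.items())]


# ----------------------------------------------------------------------
# superimposed-bucket disambiguation


@dataclass(frozen=True)
class BucketVerdict:
    status: str  # supported | unsupported | ambiguous
    max_relation: float
    reason: str = ""


def disambiguate_bucket(
    bucket: str,
    candidates: Mapping[str, Sequence[str]],
    matrix: RelationMatrix,
    *,
    low: float = 0.1,
    high: float = 0.3,
) -> dict[str, BucketVerdict]:
    """Which candidate metabolites drive a superimposed bucket?

    For each candidate metabolite the maximal relation between the
    bucket and the metabolite's *other* assigned buckets decides:
    ``supported`` at >= ``high``, ``unsupported`` at <= ``low``,
    otherwise ``ambiguous``.  A candidate without any other bucket in
    the matrix is ambiguous by construction.
    """
    verdicts: dict[str, BucketVerdict] = {}
    for met, others in candidates.items():
        others = [l for l in others if l != bucket and l in matrix.values.index]
        if not others:
            verdicts[met] = BucketVerdict(
                "ambiguous", float("nan"), "no other assigned bucket available"
            )
            continue
        rel = max(matrix.get(bucket, l) for l in others)
        if rel >= high:
            status = "supported"
        elif rel <= low:
            status = "unsupported"
        else:
            status = "ambiguous"
        verdicts[met] = BucketVerdict(status, rel)
    return verdicts


def cluster_boxplot_data(
    table: BucketTable, members: Mapping[int, Sequence[str]]
) -> pd.DataFrame:
    """Long-format per-cluster intensity data (bucket, sample, class,
    intensity, cluster) for boxplot reporting."""
    rows = []
    for cl, labels in sorted(members.items()):
        for label in labels:
            col = table.column(label)
            for sid, cls, val in zip(table.sample_ids, table.class_labels, col):
                rows.append((int(cl), label, sid, cls, float(val)))
    return pd.DataFrame(
        rows, columns=["cluster", "bucket", "sample_id", "class", "intensity"]
    )
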