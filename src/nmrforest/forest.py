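"""Classification random forest with per-node surrogate splits.

The engine behind the whole analysis: class-weighted bootstrap, Gini
splits on ``mtry`` candidate variables per node, and — unlike standard
forest implementations — up to ``s`` CART-style surrogate splits stored
at every internal node together with their adjusted agreements.  The
surrogates are what make surrogate minimal depth and the mean adjusted
agreement relation parameter computable downstream.

The public surface follows the statsmodels convention: build a
:class:`SurrogateForest` model from data (or a
:class:`~nmrforest.buckets.BucketTable`), call :meth:`~SurrogateForest.fit`,
and read everything off the returned :class:`SurrogateForestResults`.

Determinism: each tree draws from its own generator seeded by
``(seed, tree_index)``, so results are reproducible and independent of
the order in which trees are built.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._split import SurrogateSet, best_split_matrix, surrogate_search
from .buckets import BucketTable

__all__ = [
    "ForestParams",
    "default_params",
    "Tree",
    "SurrogateForest",
    "SurrogateForestResults",
    "ClassificationReport",
    "fit_forest",
    "oob_report",
    "impurity_importance",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ForestParams:
    """Forest hyperparameters.

    Defaults follow the bucketed-NMR study conventions: ``mtry`` is
    ``ceil(p^(3/4))`` (more candidates than the classification default
    sqrt(p), which benefits surrogate-based importance), ``s`` is
    ``round(0.05 p)`` surrogate splits per node with a floor of 1, and
    samples are weighted inversely to their class size so every class
    contributes equally to the bootstrap in expectation.
    """

    ntree: int = 10000
    mtry: int | None = None
    min_node_size: int = 1
    s: int = 0
    #: per-class weights (mapping), per-sample weights (array of length
    #: n), or None for uniform sampling
    case_weights: Mapping[str, float] | np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError(f"ntree must be >= 1, got {self.ntree}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError(f"mtry must be >= 1, got {self.mtry}")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.s < 0:
            raise ValueError("s must be >= 0")


def default_params(
    p: int,
    class_sizes: Mapping[str, int] | Sequence[int],
    *,
    ntree: int = 10000,
    min_node_size: int = 1,
    seed: int = 0,
) -> ForestParams:
    """Study-default parameters for ``p`` variables.

    ``mtry = ceil(p^(3/4))``, ``s = max(1, round(0.05 p))``; the case
    weight of every sample of class c is ``1 / (K * n_c)`` so classes
    are balanced in the bootstrap.
    """
    if p < 1:
        raise ValueError(f"number of variables must be >= 1, got {p}")
    if isinstance(class_sizes, Mapping):
        sizes = dict(class_sizes)
    else:
        sizes = {f"C{i + 1}": int(c) for i, c in enumerate(class_sizes)}
    k = len(sizes)
    weights = {c: 1.0 / (k * n_c) for c, n_c in sizes.items()}
    return ForestParams(
        ntree=ntree,
        mtry=min(p, math.ceil(p**0.75)),
        min_node_size=min_node_size,
        s=max(1, _round_half_up(0.05 * p)),
        case_weights=weights,
        seed=seed,
    )


@dataclass
class Tree:
    """One grown decision tree (arrays indexed by node id, root = 0)."""

    var: np.ndarray  # primary split variable, -1 for terminal nodes
    threshold: np.ndarray
    depth: np.ndarray
    left: np.ndarray  # child node ids, -1 for terminal
    right: np.ndarray
    counts: np.ndarray  # (n_nodes, K) in-bag class counts
    surrogates: list[SurrogateSet | None]
    inbag: np.ndarray  # bootstrap sample indices (with multiplicity)

    @property
    def n_nodes(self) -> int:
        return len(self.var)

    @property
    def is_internal(self) -> np.ndarray:
        return self.var >= 0

    @property
    def max_internal_depth(self) -> int:
        internal = self.is_internal
        return int(self.depth[internal].max()) if internal.any() else -1

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Per-sample class code via the primary splits (leaf majority,
        ties to the smaller class code)."""
        out = np.empty(len(X), dtype=np.int64)
        for i, x in enumerate(X):
            node = 0
            while self.var[node] >= 0:
                node = self.left[node] if x[self.var[node]] <= self.threshold[node] else self.right[node]
            out[i] = int(np.argmax(self.counts[node]))
        return out


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    params: ForestParams,
    weights: np.ndarray,
    rng: np.random.Generator,
    importance: np.ndarray,
) -> Tree:
    n, p = X.shape
    mtry = params.mtry or max(1, math.ceil(p**0.75))
    inbag = rng.choice(n, size=n, replace=True, p=weights)

    var: list[int] = []
    thr: list[float] = []
    depth: list[int] = []
    left: list[int] = []
    right: list[int] = []
    counts: list[np.ndarray] = []
    surrogates: list[SurrogateSet | None] = []

    def new_node(idx: np.ndarray, d: int) -> int:
        node = len(var)
        var.append(-1)
        thr.append(math.nan)
        depth.append(d)
        left.append(-1)
        right.append(-1)
        counts.append(np.bincount(y[idx], minlength=n_classes))
        surrogates.append(None)
        return node

    # iterative preorder growth; right child pushed first so the left
    # subtree is grown (and consumes random draws) first
    stack: list[tuple[np.ndarray, int, int, bool]] = [(inbag, 0, -1, False)]
    while stack:
        idx, d, parent, is_right = stack.pop()
        node = new_node(idx, d)
        if parent >= 0:
            (right if is_right else left)[parent] = node
        c = counts[node]
        n_node = len(idx)
        if n_node < max(2, 2 * params.min_node_size) or np.max(c) == n_node:
            continue
        cand = np.sort(rng.choice(p, size=min(mtry, p), replace=False))
        t, g, score = best_split_matrix(
            X[np.ix_(idx, cand)], y[idx], n_classes, params.min_node_size
        )
        j = int(np.argmax(score))
        if not np.isfinite(score[j]) or g[j] <= 0:
            continue
        v = int(cand[j])
        var[node] = v
        thr[node] = float(t[j])
        go_left = X[idx, v] <= thr[node]
        importance[v] += (n_node / n) * g[j]
        if params.s > 0:
            surrogates[node] = surrogate_search(X[idx], go_left, v, params.s)
        stack.append((idx[~go_left], d + 1, node, True))
        stack.append((idx[go_left], d + 1, node, False))

    return Tree(
        var=np.array(var, dtype=np.int64),
        threshold=np.array(thr),
        depth=np.array(depth, dtype=np.int64),
        left=np.array(left, dtype=np.int64),
        right=np.array(right, dtype=np.int64),
        counts=np.array(counts, dtype=np.int64),
        surrogates=surrogates,
        inbag=inbag,
    )


class SurrogateForest:
    """Surrogate-split random forest classifier (model object).

    Parameters
    ----------
    X : (n, p) feature matrix (bucket intensities).
    y : length-n class labels.
    params : :class:`ForestParams`; defaults to :func:`default_params`
        of the data at hand.
    var_labels : optional variable names (bucket labels).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        params: ForestParams | None = None,
        *,
        var_labels: Sequence[str] | None = None,
    ) -> None:
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-d")
        y = [str(v) for v in y]
        if len(y) != len(self.X):
            raise ValueError("X and y length mismatch")
        self.classes: list[str] = sorted(set(y))
        if len(self.classes) < 2:
            raise ValueError("supervised analysis requires at least 2 classes")
        code = {c: i for i, c in enumerate(self.classes)}
        self.y = np.array([code[v] for v in y], dtype=np.int64)
        self.y_labels = y
        n, p = self.X.shape
        if var_labels is None:
            var_labels = [f"x{i}" for i in range(p)]
        if len(var_labels) != p:
            raise ValueError("var_labels length mismatch")
        self.var_labels = [str(v) for v in var_labels]
        if params is None:
            sizes = {c: int((self.y == i).sum()) for i, c in enumerate(self.classes)}
            params = default_params(p, sizes)
        self.params = params

    @classmethod
    def from_bucket_table(
        cls, table: BucketTable, params: ForestParams | None = None
    ) -> "SurrogateForest":
        return cls(
            table.intensities, table.class_labels, params, var_labels=table.labels
        )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def _sample_weights(self) -> np.ndarray:
        cw = self.params.case_weights
        n = self.n_samples
        if cw is None:
            w = np.full(n, 1.0 / n)
        elif isinstance(cw, Mapping):
            per_class = {c: float(cw.get(c, 0.0)) for c in self.classes}
            w = np.array([per_class[self.classes[code]] for code in self.y])
        else:
            w = np.asarray(cw, dtype=np.float64)
            if w.shape != (n,):
                raise ValueError("per-sample case_weights must have length n")
        if np.any(w < 0) or not w.sum() > 0:
            raise ValueError("case weights must be >= 0 with positive sum")
        return w / w.sum()

    def fit(self, seed: int | None = None) -> "SurrogateForestResults":
        """Grow the forest; deterministic for a fixed seed."""
        seed = self.params.seed if seed is None else seed
        weights = self._sample_weights()
        importance = np.zeros(self.n_features)
        trees = []
        k = len(self.classes)
        for t in range(self.params.ntree):
            rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
            trees.append(
                _grow_tree(self.X, self.y, k, self.params, weights, rng, importance)
            )
        return SurrogateForestResults(
            model=self,
            trees=trees,
            params=self.params,
            seed=seed,
            raw_importance=importance / self.params.ntree,
        )


@dataclass
class ClassificationReport:
    """Out-of-bag classification diagnostics."""

    confusion: pd.DataFrame  # true class x predicted class
    accuracy: float
    oob_error: float
    sensitivity: pd.Series
    specificity: pd.Series
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Out-of-bag classification report",
            f"  accuracy: {self.accuracy * 100:.1f}%   OOB error: {self.oob_error * 100:.1f}%",
            "",
            self.confusion.to_string(),
            "",
            "  sensitivity [%]: "
            + "  ".join(f"{c}={v * 100:.1f}" for c, v in self.sensitivity.items()),
            "  specificity [%]: "
            + "  ".join(f"{c}={v * 100:.1f}" for c, v in self.specificity.items()),
        ]
        if self.n_excluded:
            lines.append(f"  samples never out-of-bag (excluded): {self.n_excluded}")
        return "\n".join(lines)


@dataclass
class SurrogateForestResults:
    """Fitted forest: trees, importances, and analysis entry points."""

    model: SurrogateForest
    trees: list[Tree]
    params: ForestParams
    seed: int
    raw_importance: np.ndarray

    # -- prediction ----------------------------------------------------
    def predict(self, X: np.ndarray) -> list[str]:
        X = np.asarray(X, dtype=np.float64)
        k = len(self.model.classes)
        votes = np.zeros((len(X), k), dtype=np.int64)
        for tree in self.trees:
            votes[np.arange(len(X)), tree.predict_codes(X)] += 1
        return [self.model.classes[i] for i in np.argmax(votes, axis=1)]

    def oob_votes(self) -> np.ndarray:
        """(n, K) vote counts restricted to trees where the sample is OOB."""
        n = self.model.n_samples
        k = len(self.model.classes)
        votes = np.zeros((n, k), dtype=np.int64)
        for tree in self.trees:
            oob = np.ones(n, dtype=bool)
            oob[tree.inbag] = False
            if not oob.any():
                continue
            idx = np.nonzero(oob)[0]
            votes[idx, tree.predict_codes(self.model.X[idx])] += 1
        return votes

    def oob_report(self) -> ClassificationReport:
        return oob_report(self)

    # -- importances ---------------------------------------------------
    def impurity_importance(self, mode: str = "raw") -> pd.Series:
        return impurity_importance(self, mode=mode)

    def surrogate_minimal_depth(self) -> pd.Series:
        from .smd import surrogate_minimal_depth

        return surrogate_minimal_depth(self)

    def mean_adjusted_agreement(self, variables=None, symmetrize: bool = True):
        from .relations import mean_adjusted_agreement

        return mean_adjusted_agreement(self, variables=variables, symmetrize=symmetrize)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        rep = self.oob_report()
        imp = pd.Series(self.raw_importance, index=self.model.var_labels)
        top = imp.sort_values(ascending=False).head(10)
        lines = [
            "SurrogateForest results",
            "=======================",
            f"samples: {self.model.n_samples}   variables: {self.model.n_features}   "
            f"classes: {len(self.model.classes)}",
            f"ntree: {self.params.ntree}   mtry: {self.params.mtry}   "
            f"s: {self.params.s}   min_node_size: {self.params.min_node_size}   "
            f"seed: {self.seed}",
            "",
            rep.summary(),
            "",
            "Top variables by Gini importance:",
            top.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def to_jsonl(self, path: str | Path) -> Path:
        """One JSON object per line per tree (nodes with surrogates)."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            header = {
                "classes": self.model.classes,
                "var_labels": self.model.var_labels,
                "ntree": self.params.ntree,
                "mtry": self.params.mtry,
                "s": self.params.s,
                "min_node_size": self.params.min_node_size,
                "seed": self.seed,
            }
            fh.write(json.dumps({"header": header}) + "\n")
            for tree in self.trees:
                surr = []
                for ss in tree.surrogates:
                    if ss is None:
                        surr.append(None)
                    else:
                        surr.append(
                            {
                                "var": ss.variables.tolist(),
                                "thr": ss.thresholds.tolist(),
                                "flip": ss.flip.astype(int).tolist(),
                                "adj": ss.adjusted.tolist(),
                            }
                        )
                fh.write(
                    json.dumps(
                        {
                            "var": tree.var.tolist(),
                            "thr": np.where(np.isnan(tree.threshold), None, tree.threshold).tolist(),
                            "depth": tree.depth.tolist(),
                            "left": tree.left.tolist(),
                            "right": tree.right.tolist(),
                            "counts": tree.counts.tolist(),
                            "inbag": tree.inbag.tolist(),
                            "surrogates": surr,
                        }
                    )
                    + "\n"
                )
        return path


def fit_forest(table: BucketTable, params: ForestParams | None = None) -> SurrogateForestResults:
    """Convenience: fit a surrogate forest on a bucket table."""
    if len(set(table.class_labels)) < 2:
        raise ValueError("classification requires at least 2 classes")
    return SurrogateForest.from_bucket_table(table, params).fit()


def oob_report(results: SurrogateForestResults) -> ClassificationReport:
    """Out-of-bag confusion matrix, accuracy, sensitivities, specificities.

    Each sample is predicted by majority vote over the trees in which it
    is out-of-bag; samples never OOB (possible at tiny ntree) are
    excluded with a warning.
    """
    model = results.model
    votes = results.oob_votes()
    covered = votes.sum(axis=1) > 0
    excluded_ids = [str(i) for i in np.nonzero(~covered)[0]]
    if not covered.all():
        warnings.warn(
            f"{len(excluded_ids)} samples were never out-of-bag and are excluded "
            "from the OOB report; increase ntree",
            stacklevel=2,
        )
    pred = np.argmax(votes[covered], axis=1)
    true = results.model.y[covered]
    k = len(model.classes)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (true, pred), 1)
    confusion = pd.DataFrame(conf, index=model.classes, columns=model.classes)
    total = conf.sum()
    accuracy = float(np.trace(conf)) / total if total else math.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.diag(conf) / conf.sum(axis=1)
        tn = total - conf.sum(axis=0) - conf.sum(axis=1) + np.diag(conf)
        fp = conf.sum(axis=0) - np.diag(conf)
        spec = tn / (tn + fp)
    return ClassificationReport(
        confusion=confusion,
        accuracy=accuracy,
        oob_error=1.0 - accuracy,
        sensitivity=pd.Series(sens, index=model.classes),
        specificity=pd.Series(spec, index=model.classes),
        n_excluded=len(excluded_ids),
        excluded_ids=excluded_ids,
    )


def impurity_importance(results: SurrogateForestResults, mode: str = "raw") -> pd.Series:
    """Gini impurity importance per variable.

    ``raw``: node-size-weighted Gini gains summed over all nodes and
    trees, divided by ntree.  ``corrected``: bias-corrected variant — the
    data are augmented with an independently permuted copy of every
    variable, the forest is refitted (without surrogates) at the same
    structural parameters, and each variable's importance is reduced by
    the importance its permuted twin earns.  ``permutation``: mean OOB
    accuracy decrease when the variable is permuted.
    """
    model = results.model
    labels = model.var_labels
    if mode == "raw":
        return pd.Series(results.raw_importance.copy(), index=labels)
    if mode == "corrected":
        p = model.n_features
        rng = np.random.default_rng(np.random.SeedSequence([results.seed, 999_331]))
        perm = np.empty_like(model.X)
        for j in range(p):
            perm[:, j] = model.X[rng.permutation(model.n_samples), j]
        # interleave twins among the real columns: deterministic
        # smaller-index tie-breaks would otherwise favour the first
        # block and bias the correction
        order = rng.permutation(2 * p)
        X_aug = np.hstack([model.X, perm])[:, order]
        aug_labels = labels + [f"{l}__perm" for l in labels]
        params = replace(
            results.params,
            mtry=min(2 * p, math.ceil((2 * p) ** 0.75)),
            s=0,
        )
        aug = SurrogateForest(
            X_aug,
            model.y_labels,
            params,
            var_labels=[aug_labels[i] for i in order],
        ).fit(seed=results.seed)
        raw = pd.Series(aug.raw_importance, index=aug.model.var_labels)
        return pd.Series(
            [raw[l] - raw[f"{l}__perm"] for l in labels], index=labels
        )
    if mode == "permutation":
        n = model.n_samples
        k = len(model.classes)
        imp = np.zeros(model.n_features)
        rng = np.random.default_rng(np.random.SeedSequence([results.seed, 777_017]))
        base_correct = np.zeros(model.n_features)
        for tree in results.trees:
            oob = np.ones(n, dtype=bool)
            oob[tree.inbag] = False
            idx = np.nonzero(oob)[0]
            if idx.size == 0:
                continue
            pred = tree.predict_codes(model.X[idx])
            base = (pred == model.y[idx]).mean()
            used = np.unique(tree.var[tree.var >= 0])
            for v in used:
                Xp = model.X[idx].copy()
                Xp[:, v] = Xp[rng.permutation(idx.size), v]
                acc = (tree.predict_codes(Xp) == model.y[idx]).mean()
                imp[v] += base - acc
        return pd.Series(imp / results.params.ntree, index=labels)
    raise ValueError(f"unknown importance mode {mode!r}")
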