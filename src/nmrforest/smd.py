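"""Surrogate minimal depth (SMD) variable selection.

Minimal depth scores a variable by the depth of the first node at which
a tree uses it — important variables split early.  Surrogate minimal
depth extends this by counting a variable as "used" at a node when it
is either the primary splitter or one of the node's surrogate splits,
so variables that carry the same information as a chosen splitter are
not overlooked.  Per tree, a variable that appears nowhere is assigned
the tree's maximum internal-node depth plus one; scores are averaged
over trees, lower meaning more important.

Selection thresholds come from an empirical null: permuted shadow
copies of real variables are appended, the forest is refitted under the
same seed discipline, and the threshold is a low quantile of the
shadow variables' SMD scores — a real variable must look more important
than essentially all provably uninformative ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .buckets import BucketTable
from .forest import ForestParams, SurrogateForest, SurrogateForestResults

__all__ = [
    "surrogate_minimal_depth",
    "classical_minimal_depth",
    "smd_threshold",
    "select_variables_smd",
    "SMDResult",
]


def _per_tree_depths(results: SurrogateForestResults, use_surrogates: bool) -> np.ndarray:
    """(ntree, p) first-appearance depth per tree, absent = max internal
    depth + 1."""
    p = results.model.n_features
    out = np.empty((len(results.trees), p))
    for t, tree in enumerate(results.trees):
        default = tree.max_internal_depth + 1
        depths = np.full(p, float(default))
        order = np.argsort(tree.depth, kind="stable")
        for node in order:
            v = tree.var[node]
            if v < 0:
                continue
            d = tree.depth[node]
            if d < depths[v]:
                depths[v] = d
            if use_surrogates and tree.surrogates[node] is not None:
                sv = tree.surrogates[node].variables
                np.minimum.at(depths, sv, float(d))
        out[t] = depths
    return out


def surrogate_minimal_depth(results: SurrogateForestResults) -> pd.Series:
    """Mean surrogate minimal depth per variable (lower = more important)."""
    if not results.trees:
        raise ValueError("empty forest")
    depths = _per_tree_depths(results, use_surrogates=True)
    return pd.Series(depths.mean(axis=0), index=results.model.var_labels)


def classical_minimal_depth(results: SurrogateForestResults) -> pd.Series:
    """Minimal depth from primary splits only (the s = 0 reduction)."""
    if not results.trees:
        raise ValueError("empty forest")
    depths = _per_tree_depths(results, use_surrogates=False)
    return pd.Series(depths.mean(axis=0), index=results.model.var_labels)


def _augmented_smd(
    model: SurrogateForest, n_shadow: int, seed: int
) -> tuple[pd.Series, pd.Series]:
    """SMD of real and shadow variables from one augmented forest.

    Real and shadow scores must come from the *same* fit: shadows in a
    wider forest appear systematically later than variables in the
    original forest, so a cross-fit comparison would bias the threshold.
    Within one fit, real and shadow variables are exchangeable under the
    null.
    """
    p = model.n_features
    n = model.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104_729]))
    src = rng.choice(p, size=n_shadow, replace=n_shadow > p)
    shadows = np.empty((n, n_shadow))
    for j, v in enumerate(src):
        shadows[:, j] = model.X[rng.permutation(n), v]
    labels = model.var_labels + [f"shadow_{j}" for j in range(n_shadow)]
    # interleave shadows among real columns at random positions: the
    # deterministic smaller-index tie-breaks would otherwise favour
    # whichever block comes first and bias the null comparison
    order = rng.permutation(p + n_shadow)
    X_aug = np.hstack([model.X, shadows])[:, order]
    aug = SurrogateForest(
        X_aug, model.y_labels, model.params,
        var_labels=[labels[i] for i in order],
    ).fit(seed=seed)
    smd_aug = surrogate_minimal_depth(aug)
    return smd_aug.loc[model.var_labels], smd_aug.drop(index=model.var_labels)


def smd_threshold(
    model: SurrogateForest,
    method: str = "shadow",
    *,
    n_shadow: int | None = None,
    quantile: float = 0.01,
    fixed_value: float | None = None,
    seed: int | None = None,
) -> tuple[float, pd.Series | None]:
    """Selection cutoff for SMD scores.

    ``shadow`` (default): append ``n_shadow`` permuted copies of
    randomly chosen real variables, refit with identical parameters and
    seed discipline, and return the ``quantile`` of the shadow SMD
    distribution (plus the shadow scores themselves).  Scores compared
    against this threshold should come from the same augmented fit (as
    :func:`select_variables_smd` does).  ``fixed``: return
    ``fixed_value`` unchanged.
    """
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        return float(fixed_value), None
    if method != "shadow":
        raise ValueError(f"unknown threshold method {method!r}")
    p = model.n_features
    if n_shadow is None:
        n_shadow = min(p, 200)
    if n_shadow < 10:
        warnings.warn(
            f"n_shadow = {n_shadow} gives an unstable null quantile", stacklevel=2
        )
    seed = model.params.seed if seed is None else seed
    _, shadow_smd = _augmented_smd(model, n_shadow, seed)
    return float(np.quantile(shadow_smd.to_numpy(), quantile, method="lower")), shadow_smd


@dataclass
class SMDResult:
    """SMD scores, threshold, and the selected variable set."""

    smd: pd.Series
    threshold: float
    selected: list[str]
    shadow_smd: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"smd": self.smd, "selected": self.smd.index.isin(self.selected)}
        ).rename_axis("bucket")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        sidecar = path.with_suffix(".json")
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump({"threshold": self.threshold, **self.params}, fh, indent=2)
        return path


def select_variables_smd(
    table: BucketTable | None = None,
    params: ForestParams | None = None,
    *,
    results: SurrogateForestResults | None = None,
    method: str = "shadow",
    n_shadow: int | None = None,
    quantile: float = 0.01,
    fixed_value: float | None = None,
    seed: int | None = None,
) -> SMDResult:
    """Fit (or reuse) a surrogate forest and select variables by SMD.

    A variable is selected when its SMD score is strictly below the
    threshold.  With the default shadow method, real and shadow scores
    are both taken from the augmented fit so the comparison is
    exchangeable under the null (see :func:`_augmented_smd`); the
    ``fixed`` method scores the given forest directly.  Either
    ``table`` (fitted here) or an already fitted ``results`` must be
    given.
    """
    if results is None:
        if table is None:
            raise ValueError("either a table or fitted results are required")
        results = SurrogateForest.from_bucket_table(table, params).fit(seed=seed)
    model = results.model
    seed = results.seed if seed is None else seed
    if method == "shadow":
        p = model.n_features
        eff_shadow = min(p, 200) if n_shadow is None else n_shadow
        if eff_shadow < 10:
            warnings.warn(
                f"n_shadow = {eff_shadow} gives an unstable null quantile", stacklevel=2
            )
        smd, shadow = _augmented_smd(model, eff_shadow, seed)
        threshold = float(np.quantile(shadow.to_numpy(), quantile, method="lower"))
    else:
        smd = surrogate_minimal_depth(results)
        threshold, shadow = smd_threshold(
            model, method, n_shadow=n_shadow, quantile=quantile,
            fixed_value=fixed_value, seed=seed,
        )
    selected = [l for l in model.var_labels if smd[l] < threshold]
    return SMDResult(
        smd=smd,
        threshold=threshold,
        selected=selected,
        shadow_smd=shadow,
        params={
            "method": method,
            "quantile": quantile,
            "n_shadow": None if shadow is None else int(len(shadow)),
            "ntree": results.params.ntree,
            "mtry": results.params.mtry,
            "s": results.params.s,
            "seed": results.seed,
        },
    )
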