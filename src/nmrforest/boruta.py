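"""Boruta all-relevant variable selection.

Boruta judges each variable individually: in every run a freshly
permuted shadow copy of each undecided variable is appended, a forest
is fitted, and a variable scores a *hit* when its importance exceeds
the best shadow importance.  Hit counts are tested against Bin(runs,
1/2) with two one-sided binomial tests; variables significantly above
chance are confirmed, significantly below are rejected (and dropped,
together with their shadows, from subsequent runs).  Whatever is still
undecided when the run budget is exhausted stays tentative.

Used here as the comparison selector next to surrogate minimal depth:
Boruta ignores variable relations, so it tends to confirm every member
of a group of mutually substitutable buckets.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .buckets import BucketTable
from .forest import ForestParams, SurrogateForest, default_params, impurity_importance

__all__ = ["boruta_select", "BorutaResult", "selection_overlap", "OverlapCounts", "decide"]


def decide(hits: int, runs: int, confidence: float, n_tests: int = 1) -> str:
    """Boruta decision for a hit trajectory.

    Two one-sided binomial tests against Bin(runs, 1/2) at level
    ``confidence / 2`` each (optionally Bonferroni-divided by
    ``n_tests``); monotone in ``confidence``.
    """
    level = confidence / 2.0 / max(1, n_tests)
    if binomtest(hits, runs, 0.5, alternative="greater").pvalue < level:
        return "confirmed"
    if binomtest(hits, runs, 0.5, alternative="less").pvalue < level:
        return "rejected"
    return "tentative"


@dataclass
class BorutaResult:
    """Decisions, hit counts, and run log of a Boruta selection."""

    decision: dict[str, str]  # label -> confirmed | rejected | tentative
    hits: dict[str, int]
    runs_participated: dict[str, int]
    n_runs: int
    params: dict = field(default_factory=dict)
    run_log: list[dict] = field(default_factory=list)

    @property
    def confirmed(self) -> list[str]:
        return [l for l, d in self.decision.items() if d == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [l for l, d in self.decision.items() if d == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [l for l, d in self.decision.items() if d == "tentative"]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.decision)
        return pd.DataFrame(
            {
                "decision": [self.decision[l] for l in labels],
                "hits": [self.hits[l] for l in labels],
                "runs": [self.runs_participated[l] for l in labels],
            },
            index=pd.Index(labels, name="bucket"),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        return path


def _shadow_of(X_col: np.ndarray, label: str, seed: int, run: int) -> np.ndarray:
    """Permuted copy with a permutation keyed by (seed, run, label), so
    shadows do not depend on column order."""
    ss = np.random.SeedSequence([seed, run, zlib.crc32(label.encode("utf-8"))])
    rng = np.random.default_rng(ss)
    return X_col[rng.permutation(len(X_col))]


def boruta_select(
    table: BucketTable,
    forest_params: ForestParams | None = None,
    *,
    importance_mode: str = "corrected",
    confidence: float = 0.01,
    max_runs: int = 157,
    seed: int | None = None,
    bonferroni: bool = False,
) -> BorutaResult:
    """Run Boruta selection on a bucket table.

    ``importance_mode`` is the impurity importance variant used to rank
    variables ("corrected" = bias-corrected Gini, the study default;
    "raw" is cheaper).  Surrogates are never needed here, so forests are
    fitted with s = 0 regardless of ``forest_params.s``.
    """
    if max_runs < 5:
        warnings.warn(
            f"max_runs = {max_runs} cannot reach a decision at confidence {confidence}",
            stacklevel=2,
        )
    labels = table.labels
    X = table.intensities
    n, p = X.shape
    if forest_params is None:
        forest_params = default_params(p, table.class_counts())
    seed = forest_params.seed if seed is None else seed

    undecided = list(labels)
    confirmed: list[str] = []
    decision = {l: "tentative" for l in labels}
    hits = {l: 0 for l in labels}
    runs_of = {l: 0 for l in labels}
    col = {l: j for j, l in enumerate(labels)}
    run_log: list[dict] = []
    run = 0
    while undecided and run < max_runs:
        run += 1
        active = confirmed + undecided  # confirmed keep informing the forest
        shadows = np.column_stack(
            [_shadow_of(X[:, col[l]], l, seed, run) for l in undecided]
        )
        X_run = np.hstack([X[:, [col[l] for l in active]], shadows])
        width = X_run.shape[1]
        # interleave shadows among the real columns so deterministic
        # smaller-index tie-breaks treat both groups alike
        order = np.random.default_rng(
            np.random.SeedSequence([seed, run, 48_611])
        ).permutation(width)
        shadow_labels = [f"{l}__shadow" for l in undecided]
        var_labels = [(active + shadow_labels)[i] for i in order]
        X_run = X_run[:, order]
        params = ForestParams(
            ntree=forest_params.ntree,
            mtry=min(width, math.ceil(width**0.75)),
            min_node_size=forest_params.min_node_size,
            s=0,
            case_weights=forest_params.case_weights,
            seed=seed,
        )
        res = SurrogateForest(
            X_run, table.class_labels, params, var_labels=var_labels
        ).fit(seed=np.random.SeedSequence([seed, run, 65_537]).generate_state(1)[0] % (2**31))
        imp = impurity_importance(res, mode="corrected" if importance_mode in ("corrected", "impurity_corrected") else importance_mode)
        shadow_max = float(imp[shadow_labels].max())
        n_tests = len(undecided) if bonferroni else 1
        still: list[str] = []
        for l in undecided:
            runs_of[l] += 1
            if imp[l] > shadow_max:
                hits[l] += 1
            verdict = decide(hits[l], runs_of[l], confidence, n_tests)
            if verdict == "confirmed":
                decision[l] = "confirmed"
                confirmed.append(l)
            elif verdict == "rejected":
                decision[l] = "rejected"
            else:
                still.append(l)
        run_log.append(
            {
                "run": run,
                "n_shadow": int(shadows.shape[1]),
                "max_shadow_importance": shadow_max,
                "n_confirmed": len(confirmed),
                "n_undecided": len(still),
            }
        )
        undecided = still

    return BorutaResult(
        decision=decision,
        hits=hits,
        runs_participated=runs_of,
        n_runs=run,
        params={
            "importance_mode": importance_mode,
            "confidence": confidence,
            "max_runs": max_runs,
            "ntree": forest_params.ntree,
            "seed": seed,
            "bonferroni": bonferroni,
        },
        run_log=run_log,
    )


class OverlapCounts(NamedTuple):
    n_common: int
    n_only_a: int
    n_only_b: int


def selection_overlap(a: Sequence[str], b: Sequence[str]) -> OverlapCounts:
    """Venn counts |a n b|, |a \\ b|, |b \\ a| of two selections."""
    sa, sb = set(a), set(b)
    return OverlapCounts(len(sa & sb), len(sa - sb), len(sb - sa))
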