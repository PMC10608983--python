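"""Node-level split and surrogate computations.

All comparisons that decide a split are made on ratios of small
integers (class counts, partition sizes).  Stored as IEEE doubles these
ratios order *exactly* for node sizes far beyond anything a bootstrap
of a few hundred samples produces (distinct rationals p/q with
q <= 2^20 differ by more than the double rounding error), so argmax
tie-breaking is deterministic: equal scores compare equal bit-for-bit
and the first (smallest threshold / smallest variable index) wins.

Conventions
-----------
* candidate thresholds are midpoints between consecutive distinct
  sorted values; samples with value <= threshold go left;
* split score maximised is ``sum_k cL_k^2/nL + sum_k cR_k^2/nR``
  (equivalent to maximising Gini gain at fixed parent);
* surrogate agreement counts the node samples (bootstrap multiplicity
  included) sent to the same side as the primary split, the better of
  the two side mappings; the adjusted agreement rescales it so the
  majority rule scores 0 and perfect mimicry scores 1:
  ``(A - m) / (1 - m)`` with ``m`` the larger primary side fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "best_split",
    "best_split_matrix",
    "adjusted_agreement",
    "surrogate_search",
    "SurrogateSet",
]


def best_split_matrix(
    Xn: np.ndarray, y: np.ndarray, n_classes: int, min_child: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best Gini split per column of a node matrix.

    Parameters
    ----------
    Xn : (n, m) values of the candidate variables at the node samples.
    y : (n,) integer class codes.
    n_classes : number of classes K.
    min_child : minimum samples required in each child.

    Returns
    -------
    thresholds : (m,) best threshold per column (nan if unsplittable).
    gains : (m,) Gini gain of that split.
    scores : (m,) the exact-ordering split score (-inf if unsplittable);
        compare these across columns, first maximum wins.
    """
    Xn = np.asarray(Xn, dtype=np.float64)
    y = np.asarray(y)
    n, m = Xn.shape
    if n < 2:
        nanv = np.full(m, np.nan)
        return nanv, np.zeros(m), np.full(m, -np.inf)
    order = np.argsort(Xn, axis=0, kind="stable")
    Xs = np.take_along_axis(Xn, order, axis=0)
    ys = y[order]  # (n, m)
    onehot = ys[..., None] == np.arange(n_classes)  # (n, m, K)
    cum = np.cumsum(onehot, axis=0, dtype=np.float64)
    tot = cum[-1]  # (m, K)
    cL = cum[:-1]  # (n-1, m, K)
    nL = np.arange(1, n, dtype=np.float64)[:, None]
    nR = n - nL
    a = np.einsum("kmc,kmc->km", cL, cL)
    cR = tot[None, :, :] - cL
    b = np.einsum("kmc,kmc->km", cR, cR)
    score = (a * nR + b * nL) / (nL * nR)
    valid = Xs[:-1] < Xs[1:]
    if min_child > 1:
        k = np.arange(1, n)[:, None]
        valid = valid & (k >= min_child) & (n - k >= min_child)
    score = np.where(valid, score, -np.inf)
    kbest = np.argmax(score, axis=0)  # first max -> smallest threshold
    cols = np.arange(m)
    best = score[kbest, cols]
    thresholds = 0.5 * (Xs[kbest, cols] + Xs[kbest + 1, cols])
    thresholds[~np.isfinite(best)] = np.nan
    parent = np.einsum("mc,mc->m", tot, tot) / (n * n)
    gains = np.where(np.isfinite(best), best / n - parent, 0.0)
    return thresholds, gains, best


def best_split(values, labels) -> tuple[float | None, float]:
    """Best Gini split of one variable at a node.

    Returns ``(threshold, gain)``; ``(None, 0.0)`` when the node is pure
    or the variable is constant.  Ties between equally good thresholds
    are broken towards the smaller threshold.
    """
    values = np.asarray(values, dtype=np.float64)
    _, y = np.unique(np.asarray(labels), return_inverse=True)
    k = int(y.max()) + 1 if y.size else 0
    if values.size < 2 or k < 2:
        return None, 0.0
    thr, gain, score = best_split_matrix(values[:, None], y, k)
    if not np.isfinite(score[0]) or gain[0] <= 0:
        return None, 0.0
    return float(thr[0]), float(gain[0])


def adjusted_agreement(
    primary_left: np.ndarray,
    values: np.ndarray,
    threshold: float,
    direction: str | None = None,
) -> float:
    """Adjusted agreement of a candidate split with a primary partition.

    ``direction`` is ``"same"`` (candidate-left maps to primary-left),
    ``"flip"``, or ``None`` to take the better of the two.  Raises if
    the primary partition is one-sided (the majority baseline m = 1
    makes the rescaling undefined).
    """
    primary_left = np.asarray(primary_left, dtype=bool)
    values = np.asarray(values, dtype=np.float64)
    n = primary_left.size
    n_left = int(primary_left.sum())
    big = max(n_left, n - n_left)
    if big == n:
        raise ValueError("primary partition is one-sided; adjusted agreement undefined")
    cand_left = values <= threshold
    same = int((cand_left == primary_left).sum())
    if direction == "same":
        agree = same
    elif direction == "flip":
        agree = n - same
    elif direction is None:
        agree = max(same, n - same)
    else:
        raise ValueError(f"direction must be 'same', 'flip' or None, got {direction!r}")
    return (agree - big) / (n - big)


@dataclass
class SurrogateSet:
    """Surrogate splits of one node, best first."""

    variables: np.ndarray  # int
    thresholds: np.ndarray  # float
    flip: np.ndarray  # bool; True: candidate-left -> primary-right
    adjusted: np.ndarray  # float in (0, 1]

    def __len__(self) -> int:
        return len(self.variables)


def surrogate_search(
    Xnode: np.ndarray,
    primary_left: np.ndarray,
    primary_var: int,
    s: int,
) -> SurrogateSet:
    """Find the s best surrogate splits for a node's primary partition.

    Scans every variable except the primary over the node samples; per
    variable, the threshold with maximal raw agreement (better of both
    directions, ties to the smaller threshold) is kept.  Variables are
    ranked by descending adjusted agreement (ties by ascending index)
    and only strictly positive adjusted agreements are stored.
    """
    if s <= 0:
        e = np.empty(0)
        return SurrogateSet(e.astype(int), e, e.astype(bool), e)
    X = np.asarray(Xnode, dtype=np.float64)
    pl = np.asarray(primary_left, dtype=bool)
    n, p = X.shape
    n_left = int(pl.sum())
    big = max(n_left, n - n_left)
    if big == n:
        raise ValueError("primary partition is one-sided")

    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    pls = pl[order]  # (n, p)
    cum = np.cumsum(pls, axis=0)  # ints
    k1 = np.arange(1, n)[:, None]  # samples in candidate-left
    agree_same = 2 * cum[:-1] - k1 + (n - n_left)
    agree = np.maximum(agree_same, n - agree_same)
    valid = Xs[:-1] < Xs[1:]
    agree = np.where(valid, agree, -1)
    kbest = np.argmax(agree, axis=0)  # first max -> smallest threshold
    cols = np.arange(p)
    best = agree[kbest, cols]
    same_at_best = agree_same[kbest, cols]
    flip = (n - same_at_best) > same_at_best  # tie -> keep same direction
    thr = 0.5 * (Xs[kbest, cols] + Xs[kbest + 1, cols])

    adj = np.where(best >= 0, (best - big) / float(n - big), -np.inf)
    adj[primary_var] = -np.inf
    rank = np.argsort(-adj, kind="stable")  # ties -> ascending variable index
    keep = rank[: min(s, p)]
    keep = keep[adj[keep] > 0]
    return SurrogateSet(
        variables=keep.astype(int),
        thresholds=thr[keep],
        flip=flip[keep],
        adjusted=adj[keep],
    )
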