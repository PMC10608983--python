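"""Independent brute-force oracles for node-level computations.

Everything here enumerates exhaustively and orders by exact rational
arithmetic (fractions.Fraction), sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def oracle_best_split(values, y, n_classes, min_child=1):
    """Exhaustive best Gini split of one variable.

    Returns (threshold, gain_fraction) or (None, Fraction(0)); ties
    between thresholds break towards the smaller threshold.
    """
    values = list(map(float, values))
    y = list(map(int, y))
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    xs = [values[i] for i in order]
    ys = [y[i] for i in order]
    best = None  # (score, threshold)
    for k in range(n - 1):
        if not xs[k] < xs[k + 1]:
            continue
        n_l, n_r = k + 1, n - k - 1
        if n_l < min_child or n_r < min_child:
            continue
        thr = (xs[k] + xs[k + 1]) / 2.0
        c_l = [0] * n_classes
        c_r = [0] * n_classes
        for i in range(n):
            (c_l if i <= k else c_r)[ys[i]] += 1
        score = Fraction(sum(c * c for c in c_l), n_l) + Fraction(
            sum(c * c for c in c_r), n_r
        )
        if best is None or score > best[0]:
            best = (score, thr)
    if best is None:
        return None, Fraction(0)
    tot = [0] * n_classes
    for v in y:
        tot[v] += 1
    gain = best[0] / n - Fraction(sum(c * c for c in tot), n * n)
    return best[1], gain


def oracle_node_split(X, y, n_classes, candidates, min_child=1):
    """Best (variable, threshold) over candidate columns; variable ties
    break towards the smaller index."""
    best = None  # (score, var, threshold)
    for j in sorted(candidates):
        thr, _ = oracle_best_split(X[:, j], y, n_classes, min_child)
        if thr is None:
            continue
        # recompute exact score for cross-variable comparison
        score = _split_score(X[:, j], y, n_classes, thr)
        if best is None or score > best[0]:
            best = (score, j, thr)
    return best  # None if nothing splits


def _split_score(values, y, n_classes, thr):
    c_l = [0] * n_classes
    c_r = [0] * n_classes
    for v, lab in zip(values, y):
        (c_l if v <= thr else c_r)[int(lab)] += 1
    n_l, n_r = sum(c_l), sum(c_r)
    return Fraction(sum(c * c for c in c_l), n_l) + Fraction(sum(c * c for c in c_r), n_r)


def oracle_surrogates(X, primary_left, primary_var, s):
    """Exhaustive surrogate list: all variables x all thresholds x both
    directions, exact-arithmetic ranking.

    Returns list of (var, threshold, flip, adjusted_float) sorted by
    descending adjusted agreement, ties ascending variable index; only
    adjusted > 0; at most s entries.
    """
    X = np.asarray(X, dtype=float)
    pl = [bool(b) for b in primary_left]
    n, p = X.shape
    n_left = sum(pl)
    big = max(n_left, n - n_left)
    assert big < n, "one-sided primary"
    entries = []
    for j in range(p):
        if j == primary_var:
            continue
        xs = sorted(set(X[:, j]))
        best = None  # (agree, threshold, flip); smaller threshold wins ties,
        # and at one threshold the un-flipped direction wins ties
        for a, b in zip(xs, xs[1:]):
            thr = (a + b) / 2.0
            same = sum((x <= thr) == lab for x, lab in zip(X[:, j], pl))
            agree, flip = (same, False) if same >= n - same else (n - same, True)
            if best is None or agree > best[0]:
                best = (agree, thr, flip)
        if best is None:
            continue
        adjusted = (best[0] - big) / (n - big)  # exact: small-integer ratio
        if adjusted > 0:
            entries.append((j, best[1], best[2], adjusted))
    entries.sort(key=lambda e: (-e[3], e[0]))
    return entries[:s]
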