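"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: explicit loops and double sums, no shared code with the
package internals they check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def brute_mutual_information(x, y) -> float:
    """MI in bits by an explicit double sum over the joint category table."""
    x = list(x)
    y = list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log2(pab / ((px[a] / n) * (py[b] / n)))
    return total


def brute_discretize(values, t=1.0):
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    out = []
    for v in values:
        if v > mean + t * sd:
            out.append(1)
        elif v < mean - t * sd:
            out.append(-1)
        else:
            out.append(0)
    return out


def brute_mrmr_order(matrix, groups, n_select, t=1.0, scheme="MID"):
    """Greedy mRMR by direct recomputation of D and mean-R at every step.

    ``matrix`` is genes x samples (2-D array-like); returns selected row
    indices in rank order.
    """
    matrix = np.asarray(matrix, dtype=float)
    cats = [brute_discretize(row, t) for row in matrix]
    groups = list(groups)
    rel = [brute_mutual_information(c, groups) for c in cats]
    selected: list[int] = []
    candidates = list(range(len(cats)))
    tie_tol = 1e-9  # scores equal in exact arithmetic: earliest gene wins
    for _ in range(n_select):
        scores = []
        for g in candidates:
            if selected:
                red = sum(brute_mutual_information(cats[g], cats[s])
                          for s in selected) / len(selected)
            else:
                red = 0.0
            if scheme == "MID":
                scores.append(rel[g] - red)
            else:
                scores.append(rel[g] / red if red > 0 else (
                    math.inf if rel[g] > 0 else 0.0))
        best = max(scores)
        band = best - tie_tol if math.isfinite(best) else best
        pick = candidates[next(i for i, s in enumerate(scores) if s >= band)]
        selected.append(pick)
        candidates.remove(pick)
    return selected


def brute_cosine_distance(x, y) -> float:
    dot = sum(a * b for a, b in zip(x, y))
    nx = math.sqrt(sum(a * a for a in x))
    ny = math.sqrt(sum(b * b for b in y))
    return 1.0 - dot / (nx * ny)


def brute_loocv(matrix, groups):
    """All-pairs LOOCV nearest-neighbor predictions (columns = samples)."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    groups = list(groups)
    predictions = []
    for i in range(n):
        best_j, best_d = None, None
        for j in range(n):
            if j == i:
                continue
            d = brute_cosine_distance(matrix[:, i], matrix[:, j])
            if best_d is None or d < best_d:  # strict <: ties keep lowest index
                best_j, best_d = j, d
        predictions.append(groups[best_j])
    return predictions


def brute_km_survival(times, events, t) -> float:
    """Product-limit S(t) by direct product over event times <= t."""
    times = list(times)
    events = list(events)
    s = 1.0
    for tau in sorted({ti for ti, ei in zip(times, events) if ei == 1}):
        if tau > t:
            break
        n_at_risk = sum(ti >= tau for ti in times)
        d = sum(ti == tau and ei == 1 for ti, ei in zip(times, events))
        s *= 1.0 - d / n_at_risk
    return s
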