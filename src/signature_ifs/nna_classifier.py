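"""Nearest-neighbor classification under the cosine-derived distance.

A sample is a real vector over the currently selected genes; the
dissimilarity between two samples is 1 - cos(angle) = 1 - <x, y>/(|x| |y|),
which lies in [0, 2] and is invariant to positive rescaling.  Classification
assigns a query the group of its single nearest training sample, and the
whole cohort is evaluated by leave-one-out cross-validation: each sample is
predicted from the remaining n - 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine-derived dissimilarity 1 - <x,y>/(|x| |y|), in [0, 2].

    Undefined (raises) for a zero-norm vector.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 1:
        raise ValueError("distance requires two equal-length 1-D vectors")
    nx = np.linalg.norm(xv)
    ny = np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine distance is undefined for a zero-norm vector")
    return float(1.0 - np.dot(xv, yv) / (nx * ny))


def predict_one(
    query: Sequence[float],
    train: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
) -> str:
    """Group of the nearest training sample (columns of ``train`` = samples).

    Ties go to the lowest training-sample index.
    """
    train_arr = np.asarray(train, dtype=float)
    labels = list(labels)
    if train_arr.ndim != 2 or train_arr.shape[1] == 0:
        raise ValueError("training set must be a non-empty features x samples matrix")
    if train_arr.shape[1] != len(labels):
        raise ValueError("one label per training sample is required")
    dists = [distance(query, train_arr[:, j]) for j in range(train_arr.shape[1])]
    return labels[int(np.argmin(dists))]


def loocv_predict(matrix: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    """Leave-one-out nearest-neighbor prediction of every sample.

    ``matrix`` is the expression matrix restricted to the selected genes
    (features x samples).  Each sample is predicted from the n - 1 others;
    the held-out sample never participates in its own neighbor search.

    Returns a prediction table with one row per sample: ``sample_id``,
    ``true_group``, ``predicted_group``, ``feature_count``.
    """
    values = matrix.to_numpy(dtype=float)
    n_features, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("leave-one-out needs >= 2 samples")
    if n_features < 1:
        raise ValueError("at least one feature is required")
    groups = np.asarray(groups)
    if groups.size != n_samples:
        raise ValueError("one group label per sample is required")
    norms = np.linalg.norm(values, axis=0)
    if np.any(norms == 0.0):
        bad = matrix.columns[int(np.flatnonzero(norms == 0.0)[0])]
        raise ValueError(f"sample '{bad}' has zero norm on the selected features")
    unit = values / norms
    dist = 1.0 - unit.T @ unit
    np.fill_diagonal(dist, np.inf)  # a sample is never its own neighbor
    nearest = np.argmin(dist, axis=1)  # first index on ties = lowest training index
    return pd.DataFrame(
        {
            "sample_id": matrix.columns,
            "true_group": groups,
            "predicted_group": groups[nearest],
            "feature_count": n_features,
        }
    )
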