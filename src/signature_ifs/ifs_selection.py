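"""Incremental feature selection over the mRMR-ranked list.

For every feature-set size k the top-k ranked genes are used to predict the
four groups by leave-one-out nearest neighbor; the predictions are then
merged two ways — by subtype (ABC vs GCB) and by risk (dead-labelled
predictions are high-risk, alive-labelled are low-risk) — giving, per k, a
subtype accuracy and a log-rank comparison of the observed survival of the
two predicted risk arms.  The resulting IFS curve is searched, below a
feature-count cap, for the size that jointly maximizes both criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from signature_ifs.nna_classifier import loocv_predict
from signature_ifs.survival_eval import logrank_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSelection:
    """The chosen feature-set size with its genes and two performance figures."""

    chosen_k: int
    gene_ids: tuple[str, ...]          # the first chosen_k genes in mRMR order
    subtype_accuracy: float
    logrank_p: float
    selection_window: tuple[int, int]  # [k_min, k_max) searched


def merge_subtype(groups: Sequence[str]) -> np.ndarray:
    """Project four-group labels onto the subtype axis (ABC / GCB)."""
    return np.array([g.split("-")[0] for g in np.asarray(groups, dtype=object)])


def merge_risk(groups: Sequence[str]) -> np.ndarray:
    """Project four-group labels onto the risk axis: dead -> high, alive -> low."""
    return np.array(
        ["high" if g.split("-")[1] == "dead" else "low"
         for g in np.asarray(groups, dtype=object)]
    )


def subtype_accuracy(predicted: Sequence[str], truth: Sequence[str]) -> float:
    """Overall subtype success rate: (correct ABC + correct GCB) / total."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size != true.size:
        raise ValueError("prediction / truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty prediction table")
    return float((pred == true).sum() / true.size)


def ifs_run(
    matrix: pd.DataFrame,
    ranked: pd.DataFrame,
    phenotype: pd.DataFrame,
) -> pd.DataFrame:
    """Build the dual IFS curve over nested top-k feature sets.

    Parameters
    ----------
    matrix
        Preprocessed genes x samples expression matrix.
    ranked
        mRMR ranking table (``gene_id`` column in rank order).
    phenotype
        Per-sample table with ``subtype``, ``status``, ``time``, ``event``;
        its index must match the matrix columns.

    Returns
    -------
    DataFrame with one row per k: ``k``, ``subtype_accuracy``,
    ``logrank_statistic``, ``logrank_p``, ``neg_log10_p``.  A k whose
    predictions put every sample into one risk arm records statistic 0,
    p = 1 (logged as a warning) so the curve stays index-complete.
    """
    if len(ranked) == 0:
        raise ValueError("ranked feature list is empty")
    phenotype = phenotype.loc[matrix.columns]
    true_groups = (phenotype["subtype"] + "-" + phenotype["status"]).to_numpy()
    true_subtype = phenotype["subtype"].to_numpy()
    times = phenotype["time"].to_numpy(dtype=float)
    events = phenotype["event"].to_numpy(dtype=int)

    gene_order = list(ranked["gene_id"])
    records = []
    for k in range(1, len(gene_order) + 1):
        sub = matrix.loc[gene_order[:k]]
        pred = loocv_predict(sub, true_groups)
        predicted = pred["predicted_group"].to_numpy()
        acc = subtype_accuracy(merge_subtype(predicted), true_subtype)
        risk = merge_risk(predicted)
        high = risk == "high"
        if high.all() or not high.any():
            logger.warning("IFS k=%d: one predicted risk group is empty; p set to 1", k)
            stat, p = 0.0, 1.0
        else:
            res = logrank_test(times[high], events[high], times[~high], events[~high])
            stat, p = res.statistic, res.p_value
        records.append((k, acc, stat, p, -np.log10(p)))
    return pd.DataFrame(
        records,
        columns=["k", "subtype_accuracy", "logrank_statistic", "logrank_p", "neg_log10_p"],
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def select_balanced(
    curve: pd.DataFrame,
    ranked: pd.DataFrame,
    k_max: int = 100,
    weights: tuple[float, float] = (1.0, 1.0),
) -> SignatureSelection:
    """Pick the feature count that balances subtype accuracy and survival separation.

    Within the window k in [1, k_max) the two curve metrics (subtype
    accuracy, -log10 log-rank p) are min-max normalized and summed with the
    given weights; the k with the highest score wins, smallest k on ties.
    A metric constant over the window contributes 0 everywhere.  A fully
    constant curve yields chosen_k = 1 with a warning.
    """
    window = curve[curve["k"] < k_max]
    if window.empty:
        raise ValueError(f"IFS curve does not cover any k < {k_max}")
    acc = window["subtype_accuracy"].to_numpy(dtype=float)
    nlp = window["neg_log10_p"].to_numpy(dtype=float)
    score = weights[0] * _minmax(acc) + weights[1] * _minmax(nlp)
    if np.ptp(acc) == 0 and np.ptp(nlp) == 0:
        logger.warning("IFS curve is constant over the window; choosing k = 1")
    best = int(np.argmax(score))  # first max = smallest k on ties
    row = window.iloc[best]
    chosen_k = int(row["k"])
    return SignatureSelection(
        chosen_k=chosen_k,
        gene_ids=tuple(ranked["gene_id"].iloc[:chosen_k]),
        subtype_accuracy=float(row["subtype_accuracy"]),
        logrank_p=float(row["logrank_p"]),
        selection_window=(1, k_max),
    )
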