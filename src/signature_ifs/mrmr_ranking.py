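"""Maximum-Relevance-Minimum-Redundancy (mRMR) feature ranking.

Expression values are discretized gene-by-gene into three categories at
mean +/- t * sd, and genes are ranked greedily: the first pick maximizes
mutual information with the four-group class label (relevance D); every
subsequent pick maximizes D - R (the difference form, "MID"), where R is the
mean mutual information with the already-selected genes.  A quotient form
("MIQ", D / R) is available behind a switch.  All mutual information is the
plug-in estimate on empirical frequencies, in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DiscretizationConfig:
    """Three-bin discretization threshold multiplier: cut at mean +/- t * sd."""

    t: float = 1.0

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"discretization threshold t must be > 0, got {self.t}")


def discretize(values: Sequence[float], t: float = 1.0) -> np.ndarray:
    """Map a real vector to categories {-1, 0, +1} at mean +/- t * sd.

    The standard deviation uses the n-1 denominator.  A constant vector maps
    to all zeros.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("discretize needs >= 2 values")
    if not np.isfinite(x).all():
        raise ValueError("discretize requires finite values")
    mean = x.mean()
    sd = x.std(ddof=1)
    out = np.zeros(x.size, dtype=np.int8)
    out[x > mean + t * sd] = 1
    out[x < mean - t * sd] = -1
    return out


def _mi_from_codes(x: np.ndarray, y: np.ndarray, kx: int, ky: int) -> float:
    """Plug-in MI in bits from non-negative integer codes with arities kx, ky."""
    n = x.size
    joint = np.bincount(x * ky + y, minlength=kx * ky).astype(float).reshape(kx, ky)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def _as_codes(v: Sequence) -> tuple[np.ndarray, int]:
    arr = np.asarray(v)
    _, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if codes.size else 0


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Empirical mutual information I(x; y) in bits (0 log 0 := 0).

    Symmetric, non-negative, and I(x, x) equals the empirical entropy of x.
    """
    cx, kx = _as_codes(x)
    cy, ky = _as_codes(y)
    if cx.size != cy.size:
        raise ValueError(f"length mismatch: {cx.size} vs {cy.size}")
    if cx.size == 0:
        raise ValueError("empty vectors")
    return _mi_from_codes(cx, cy, kx, ky)


def relevance(gene: Sequence, classes: Sequence) -> float:
    """Relevance D of a gene: mutual information with the class variable."""
    return mutual_information(gene, classes)


def redundancy(gene: Sequence, selected: Sequence[Sequence]) -> float:
    """Redundancy R: mean mutual information with the selected genes (0 if none)."""
    selected = list(selected)
    if not selected:
        return 0.0
    return float(np.mean([mutual_information(gene, s) for s in selected]))


# scores equal in exact arithmetic can differ by summation order; treat
# anything this close to the step maximum as a tie (gaps between genuinely
# distinct MI scores on real data are orders of magnitude larger)
_TIE_TOL = 1e-9


def rank_features(
    matrix: pd.DataFrame,
    groups: Sequence[str],
    n_select: int = 500,
    disc: DiscretizationConfig = DiscretizationConfig(),
    scheme: str = "MID",
) -> pd.DataFrame:
    """Greedy mRMR ranking of genes against the four-group label.

    Parameters
    ----------
    matrix
        Genes x samples expression matrix.
    groups
        One class label per sample (the subtype x status cross).
    n_select
        Length of the returned ranked list (candidate pool size).
    disc
        Discretization threshold configuration.
    scheme
        ``"MID"`` scores candidates by D - R, ``"MIQ"`` by D / R (the first
        pick is pure relevance under both; an MIQ candidate with R == 0 and
        D > 0 scores +inf).

    Returns
    -------
    DataFrame with columns ``rank`` (1-based), ``gene_id``, ``relevance``,
    ``redundancy`` and ``score``, in greedy selection order.  Ties at any
    step go to the gene earliest in the input order.
    """
    if n_select <= 0:
        raise ValueError(f"n_select must be positive, got {n_select}")
    n_genes, n_samples = matrix.shape
    if n_select > n_genes:
        raise ValueError(f"n_select={n_select} exceeds gene count {n_genes}")
    if scheme not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR scheme '{scheme}'")
    groups = np.asarray(groups)
    if groups.size != n_samples:
        raise ValueError("one group label per sample is required")

    values = matrix.to_numpy(dtype=float)
    # per-gene 3-bin codes in {0,1,2}
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    codes = np.ones_like(values, dtype=np.intp)
    codes[values > means + disc.t * sds] = 2
    codes[values < means - disc.t * sds] = 0
    class_codes, n_classes = _as_codes(groups)

    rel = np.array([_mi_from_codes(codes[g], class_codes, 3, n_classes)
                    for g in range(n_genes)])

    selected: list[int] = []
    rows = []
    mi_sum = np.zeros(n_genes)  # summed MI against already-selected genes
    remaining = np.ones(n_genes, dtype=bool)
    for rank in range(1, n_select + 1):
        if not selected:
            red = np.zeros(n_genes)
        else:
            red = mi_sum / len(selected)
        if scheme == "MID":
            score = rel - red
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(red > 0, rel / red,
                                 np.where(rel > 0, np.inf, 0.0))
        masked = np.where(remaining, score, -np.inf)
        # ties (within fp noise of the step maximum) go to the earliest gene
        best = masked.max()
        tie_band = best - _TIE_TOL if np.isfinite(best) else best
        pick = int(np.flatnonzero(masked >= tie_band)[0])
        selected.append(pick)
        remaining[pick] = False
        rows.append((rank, matrix.index[pick], rel[pick], red[pick], masked[pick]))
        if rank < n_select:
            picked_codes = codes[pick]
            mi_sum += np.array([
                _mi_from_codes(codes[g], picked_codes, 3, 3) if remaining[g] else 0.0
                for g in range(n_genes)
            ])
    return pd.DataFrame(rows, columns=["rank", "gene_id", "relevance", "redundancy", "score"])
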