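"""Expression / phenotype table I/O and preprocessing.

An expression matrix is a genes x samples :class:`pandas.DataFrame` of
normalized log-scale intensities: the index holds unique gene (or probe)
identifiers, the columns hold unique sample identifiers.  A phenotype table
is a DataFrame indexed by sample id with columns ``subtype`` (``ABC`` or
``GCB``), ``status`` (``dead`` or ``alive``), ``time`` (follow-up, > 0) and
``event`` (0/1, with ``dead`` implying ``event == 1``).

Preprocessing is order-exact: duplicate probes are averaged to genes, then
low-intensity genes are filtered, then samples are quantile-normalized.

The on-disk format is plain UTF-8 TSV with a ``gene_id`` header cell for
expression and a ``sample_id`` column for phenotype; no quoting, so a
write -> read round trip reproduces the matrix at full printed precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPES = ("ABC", "GCB")
STATUSES = ("dead", "alive")
#: the four-group classification variable: subtype crossed with vital status
FOUR_GROUPS = ("ABC-dead", "ABC-alive", "GCB-dead", "GCB-alive")

PHENOTYPE_COLUMNS = ("subtype", "status", "time", "event")


class ParseError(ValueError):
    """Malformed expression or phenotype file; message carries the line number."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    The first header cell is the gene-id column name (conventionally
    ``gene_id``), the remaining header cells are sample ids.  Raises
    :class:`ParseError` naming the offending line for duplicate sample
    columns, ragged rows or non-numeric cells.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}, line 1: header needs a gene-id column and >= 1 sample")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ParseError(f"{path}, line 1: duplicated sample column '{sid}'")
        seen.add(sid)
    n_cols = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}, line {lineno}: expected {n_cols} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return pd.DataFrame(values, index=pd.Index(gene_ids, name=header[0] or "gene_id"),
                        columns=sample_ids)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix as TSV (header cell ``gene_id``, repr precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        values = matrix.to_numpy()
        for gid, row in zip(matrix.index, values):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype TSV (sample_id, subtype, status, time, event)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id", *PHENOTYPE_COLUMNS) if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicated sample_id '{dup}'")
    table = table.set_index("sample_id")
    bad = ~table["subtype"].isin(SUBTYPES)
    if bad.any():
        raise ParseError(f"{path}: invalid subtype '{table['subtype'][bad].iloc[0]}'")
    bad = ~table["status"].isin(STATUSES)
    if bad.any():
        raise ParseError(f"{path}: invalid status '{table['status'][bad].iloc[0]}'")
    table["time"] = table["time"].astype(float)
    table["event"] = table["event"].astype(int)
    if (table["time"] <= 0).any():
        raise ParseError(f"{path}: follow-up times must be > 0")
    if ~table["event"].isin((0, 1)).all():
        raise ParseError(f"{path}: event indicator must be 0 or 1")
    inconsistent = (table["status"] == "dead") & (table["event"] != 1)
    if inconsistent.any():
        raise ParseError(
            f"{path}: sample '{table.index[inconsistent][0]}' is dead but event != 1"
        )
    return table


def write_phenotype(phenotype: pd.DataFrame, path: str | Path) -> None:
    phenotype.to_csv(path, sep="\t", index_label="sample_id")


def four_group_labels(phenotype: pd.DataFrame) -> pd.Series:
    """Derive the four-group label ``subtype-status`` per sample."""
    return phenotype["subtype"].str.cat(phenotype["status"], sep="-")


def average_duplicate_probes(
    matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe rows to genes by arithmetic mean.

    Probes absent from ``probe_to_gene`` are dropped.  Output gene order
    follows the first appearance of each gene among the mapped probes.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    mapped = [p for p in matrix.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    sub = matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene_id")
    out = sub.groupby(genes, sort=False).mean()
    logger.info("average_duplicate_probes: %d probes -> %d genes", len(matrix), len(out))
    return out


def filter_low_intensity(
    matrix: pd.DataFrame,
    min_mean: float | None = None,
    min_mean_quantile: float = 0.25,
) -> pd.DataFrame:
    """Drop genes whose across-sample mean falls below a threshold.

    If ``min_mean`` is not given the threshold is the ``min_mean_quantile``
    quantile of gene means (default: drop the bottom 25% of genes).  Gene
    order is preserved; removing every gene raises.
    """
    means = matrix.mean(axis=1)
    if min_mean is None:
        min_mean = float(np.quantile(means.to_numpy(), min_mean_quantile))
    if not np.isfinite(min_mean):
        raise ValueError("min_mean must be finite")
    keep = means >= min_mean
    if not keep.any():
        raise ValueError(
            f"low-intensity filter at min_mean={min_mean} removed every gene; "
            "lower the threshold"
        )
    out = matrix.loc[keep]
    logger.info("filter_low_intensity: kept %d / %d genes (min_mean=%g)",
                len(out), len(matrix), min_mean)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean distribution of order statistics.

    After normalization each column's sorted value vector equals the
    across-column mean of order statistics.  Ties within a column receive the
    mean of the reference values their ranks span, which makes the transform
    idempotent.  Requires >= 2 samples.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    ref = np.take_along_axis(values, order, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        o = order[:, j]
        s = values[o, j]
        # tie groups: runs of equal values share the mean of their ref span
        starts = np.r_[0, np.flatnonzero(np.diff(s) != 0) + 1]
        counts = np.diff(np.r_[starts, n_genes])
        group_means = np.add.reduceat(ref, starts) / counts
        out[o, j] = np.repeat(group_means, counts)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess(
    matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, str] | None = None,
    min_mean: float | None = None,
    min_mean_quantile: float = 0.25,
) -> pd.DataFrame:
    """Probe averaging, then low-intensity filtering, then quantile normalization."""
    if probe_to_gene is not None:
        matrix = average_duplicate_probes(matrix, probe_to_gene)
    matrix = filter_low_intensity(matrix, min_mean=min_mean,
                                  min_mean_quantile=min_mean_quantile)
    return quantile_normalize(matrix)
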