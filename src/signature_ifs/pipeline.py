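"""End-to-end orchestration: simulate -> preprocess -> rank -> IFS -> select -> survival.

A run is described by a :class:`RunConfig` (JSON-compatible key-value
config; every field has a CLI flag).  All intermediate artifacts are
persisted as TSV next to a JSON report, so every number in the report can
be recomputed from the persisted files with the individual subcommands.
Identical config + seed reproduces every output file byte-identically; for
that reason the persisted ``run.log`` records stage order and record counts
but no wall-clock times (timings go to the console logger only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from signature_ifs import expression_io
from signature_ifs.expression_io import four_group_labels
from signature_ifs.ifs_selection import ifs_run, merge_risk, select_balanced
from signature_ifs.mrmr_ranking import DiscretizationConfig, rank_features
from signature_ifs.nna_classifier import loocv_predict
from signature_ifs.survival_eval import km_estimate, logrank_test
from signature_ifs.synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    When ``expression`` / ``phenotype`` paths are unset, a synthetic cohort
    is generated from ``simulation`` (whose seed is overridden by ``seed``).
    """

    out_dir: str = "signature_ifs_run"
    expression: str | None = None
    phenotype: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    run_preprocess: bool = True
    min_mean: float | None = None
    min_mean_quantile: float = 0.25
    discretization_t: float = 1.0
    mrmr_scheme: str = "MID"
    n_select: int = 100
    k_max: int = 100
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute every enabled stage in order; returns the JSON report dict.

    On a stage failure the partial outputs are retained and ``MANIFEST``
    marks the run incomplete; the raised :class:`StageError` names the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log_lines: list[str] = []
    stage = "setup"

    def _finish_stage(name: str, line: str, t0: float) -> None:
        log_lines.append(f"{name}: {line}")
        logger.info("%s: %s (%.2fs)", name, line, _time.perf_counter() - t0)

    def _persist(path: Path) -> None:
        manifest.append(path.name)

    try:
        # ----- input stage: load or simulate -------------------------------
        t0 = _time.perf_counter()
        if config.expression is not None:
            stage = "load"
            if config.phenotype is None:
                raise ValueError("an expression path requires a phenotype path")
            matrix = expression_io.read_expression(config.expression)
            phenotype = expression_io.read_phenotype(config.phenotype)
            _finish_stage("load", f"{matrix.shape[0]} genes x {matrix.shape[1]} samples", t0)
        else:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            dataset = simulate(sim_cfg)
            matrix, phenotype = dataset.expression, dataset.phenotype
            for path in dataset.write(out_dir).values():
                _persist(path)
            _finish_stage("simulate", f"{matrix.shape[0]} genes x {matrix.shape[1]} samples", t0)
        missing = [s for s in matrix.columns if s not in phenotype.index]
        if missing:
            raise ValueError(f"samples missing from phenotype table: {missing[:5]}")
        phenotype = phenotype.loc[matrix.columns]

        # ----- preprocess ---------------------------------------------------
        if config.run_preprocess:
            stage = "preprocess"
            t0 = _time.perf_counter()
            before = matrix.shape[0]
            matrix = expression_io.filter_low_intensity(
                matrix, min_mean=config.min_mean,
                min_mean_quantile=config.min_mean_quantile)
            matrix = expression_io.quantile_normalize(matrix)
            path = out_dir / "preprocessed_expression.tsv"
            expression_io.write_expression(matrix, path)
            _persist(path)
            _finish_stage("preprocess", f"{before} -> {matrix.shape[0]} genes", t0)

        # ----- mRMR ranking -------------------------------------------------
        stage = "rank"
        t0 = _time.perf_counter()
        groups = four_group_labels(phenotype).to_numpy()
        n_select = min(config.n_select, matrix.shape[0])
        ranked = rank_features(
            matrix, groups, n_select=n_select,
            disc=DiscretizationConfig(t=config.discretization_t),
            scheme=config.mrmr_scheme)
        path = out_dir / "mrmr_ranking.tsv"
        ranked.to_csv(path, sep="\t", index=False)
        _persist(path)
        _finish_stage("rank", f"{n_select} genes ranked", t0)

        # ----- IFS ----------------------------------------------------------
        stage = "ifs"
        t0 = _time.perf_counter()
        curve = ifs_run(matrix, ranked, phenotype)
        path = out_dir / "ifs_curve.tsv"
        curve.to_csv(path, sep="\t", index=False)
        _persist(path)
        _finish_stage("ifs", f"curve over k=1..{len(curve)}", t0)

        # ----- signature selection ------------------------------------------
        stage = "select"
        t0 = _time.perf_counter()
        selection = select_balanced(curve, ranked, k_max=config.k_max)
        sig_path = out_dir / "signature.tsv"
        ranked.iloc[: selection.chosen_k].to_csv(sig_path, sep="\t", index=False)
        _persist(sig_path)
        _finish_stage("select", f"chosen_k={selection.chosen_k}", t0)

        # ----- survival of the chosen signature -----------------------------
        stage = "survival"
        t0 = _time.perf_counter()
        pred = loocv_predict(matrix.loc[list(selection.gene_ids)], groups)
        pred_path = out_dir / "predictions.tsv"
        pred.to_csv(pred_path, sep="\t", index=False)
        _persist(pred_path)
        risk = merge_risk(pred["predicted_group"].to_numpy())
        times = phenotype["time"].to_numpy(float)
        events = phenotype["event"].to_numpy(int)
        for arm in ("high", "low"):
            mask = risk == arm
            if mask.any() and events[mask].sum() > 0:
                km = km_estimate(times[mask], events[mask])
                km_table = pd.DataFrame({
                    "time": km.event_times, "at_risk": km.at_risk,
                    "events": km.events, "survival": km.survival})
            else:
                km_table = pd.DataFrame(
                    columns=["time", "at_risk", "events", "survival"])
            path = out_dir / f"km_{arm}_risk.tsv"
            km_table.to_csv(path, sep="\t", index=False)
            _persist(path)
        high = risk == "high"
        if high.any() and not high.all():
            lr = logrank_test(times[high], events[high], times[~high], events[~high])
            lr_stat, lr_p = lr.statistic, lr.p_value
        else:
            lr_stat, lr_p = 0.0, 1.0
        _finish_stage("survival", f"high={int(high.sum())} low={int((~high).sum())}", t0)

        # ----- report -------------------------------------------------------
        stage = "report"
        report = {
            "config": config.to_dict(),
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "chosen_k": selection.chosen_k,
            "gene_ids": list(selection.gene_ids),
            "subtype_accuracy": selection.subtype_accuracy,
            "logrank_statistic": lr_stat,
            "logrank_p": lr_p,
            "selection_window": list(selection.selection_window),
        }
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        _persist(report_path)
        log_path = out_dir / "run.log"
        log_path.write_text("".join(line + "\n" for line in log_lines))
        _persist(log_path)
        (out_dir / "MANIFEST").write_text(
            "status: complete\n" + "".join(f"{n}\n" for n in sorted(manifest)))
        return report
    except Exception as exc:
        (out_dir / "MANIFEST").write_text(
            f"status: incomplete (failed at stage '{stage}': {exc})\n"
            + "".join(f"{n}\n" for n in sorted(manifest)))
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
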