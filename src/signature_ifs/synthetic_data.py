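"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a four-group lymphoma cohort — ABC-dead, ABC-alive,
GCB-dead, GCB-alive — at configurable scale.  Expression is additive
Gaussian: baseline noise N(0, noise_sd^2) per gene and sample, plus a mean
shift of ``effect_size`` on subtype-informative genes in GCB samples, on
survival-informative genes in alive samples, and on both axes for shared
genes.  Survival times are exponential with hazard ``baseline_hazard`` for
the alive-labelled groups and ``baseline_hazard * hazard_ratio`` for the
dead-labelled ones, administratively censored at an independent
Uniform(0, censor_time_max) draw; dead-labelled samples are forced to an
observed event by redrawing their event time until it precedes censoring,
so the vital-status label is always consistent with the event column.

Default group sizes follow the 94 : 73 : 49 : 134 proportions of the cohort
the pipeline targets, scaled down by four.  Generation is a pure function of
the seed: one named pseudo-random stream, no other entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from signature_ifs.expression_io import FOUR_GROUPS, write_expression, write_phenotype


class ConfigurationError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the additive mean shift applied to informative genes
    (with the default ``noise_sd`` of 1 it equals the standardized mean
    difference).  ``baseline_hazard`` is in events per time unit; the
    dead-labelled groups get ``baseline_hazard * hazard_ratio``.
    """

    n_genes: int = 500
    group_sizes: tuple[int, int, int, int] = (24, 18, 12, 34)  # ABC-dead, ABC-alive, GCB-dead, GCB-alive
    n_subtype_genes: int = 10
    n_survival_genes: int = 10
    n_shared_genes: int = 0
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_hazard: float = 0.08
    hazard_ratio: float = 3.0
    censor_time_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.group_sizes) != 4 or any(g <= 0 for g in self.group_sizes):
            raise ConfigurationError(f"group_sizes must be four positive counts, got {self.group_sizes}")
        if sum(self.group_sizes) < 8:
            raise ConfigurationError("group_sizes must sum to >= 8 (>= 2 per group) for leave-one-out")
        for name in ("n_subtype_genes", "n_survival_genes", "n_shared_genes"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_subtype_genes + self.n_survival_genes + self.n_shared_genes > self.n_genes:
            raise ConfigurationError("informative gene counts exceed n_genes")
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError(f"baseline_hazard must be > 0, got {self.baseline_hazard}")
        if self.hazard_ratio < 1:
            raise ConfigurationError(f"hazard_ratio must be >= 1, got {self.hazard_ratio}")
        if self.censor_time_max <= 0:
            raise ConfigurationError(f"censor_time_max must be > 0, got {self.censor_time_max}")


@dataclass(frozen=True)
class SyntheticDataset:
    expression: pd.DataFrame  # genes x samples
    phenotype: pd.DataFrame   # indexed by sample_id: subtype, status, time, event
    truth: pd.DataFrame       # gene_id, axis in {subtype, survival, both}

    def write(self, out_dir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
        """Write expression, phenotype and truth TSVs; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": out_dir / f"{prefix}_expression.tsv",
            "phenotype": out_dir / f"{prefix}_phenotype.tsv",
            "truth": out_dir / f"{prefix}_truth.tsv",
        }
        write_expression(self.expression, paths["expression"])
        write_phenotype(self.phenotype, paths["phenotype"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def null_logrank_pvalues(
    n_sims: int,
    group_size: int = 30,
    baseline_hazard: float = 0.08,
    censor_time_max: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Log-rank p-values from repeated null cohorts (effect 0, hazard ratio 1).

    Each replicate simulates a cohort with no informative genes and a single
    hazard, then compares the observed survival of the two alive-labelled
    true subtype groups (ABC-alive vs GCB-alive, ``group_size`` samples
    each).  Those two groups are i.i.d. with independent uniform censoring,
    so the comparison is an exact null and the returned p-values gauge the
    type-I error of the log-rank test.  The dead-labelled groups are excluded
    because their forced-event mechanism conditions the event time on the
    censoring draw, which is not the independent-censoring null.
    """
    from signature_ifs.survival_eval import logrank_test

    if n_sims <= 0 or group_size < 2:
        raise ConfigurationError("n_sims must be positive and group_size >= 2")
    pvals = np.empty(n_sims)
    for i in range(n_sims):
        cfg = SimulationConfig(
            n_genes=1, group_sizes=(2, group_size, 2, group_size),
            n_subtype_genes=0, n_survival_genes=0, n_shared_genes=0,
            effect_size=0.0, hazard_ratio=1.0,
            baseline_hazard=baseline_hazard, censor_time_max=censor_time_max,
            seed=seed + i)
        ph = simulate(cfg).phenotype
        alive = ph[ph["status"] == "alive"]
        abc = alive["subtype"] == "ABC"
        res = logrank_test(alive["time"][abc], alive["event"][abc],
                           alive["time"][~abc], alive["event"][~abc])
        pvals[i] = res.p_value
    return pvals


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one cohort; byte-identical across calls with the same config."""
    rng = np.random.default_rng(config.seed)
    n_samples = sum(config.group_sizes)
    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]

    group_per_sample = np.repeat(FOUR_GROUPS, config.group_sizes)
    subtype = np.array([g.split("-")[0] for g in group_per_sample])
    status = np.array([g.split("-")[1] for g in group_per_sample])
    is_gcb = subtype == "GCB"
    is_alive = status == "alive"
    is_dead = ~is_alive

    n_inform = config.n_subtype_genes + config.n_survival_genes + config.n_shared_genes
    informative_idx = rng.choice(config.n_genes, size=n_inform, replace=False)
    sub_idx = informative_idx[: config.n_subtype_genes]
    surv_idx = informative_idx[config.n_subtype_genes:
                               config.n_subtype_genes + config.n_survival_genes]
    shared_idx = informative_idx[config.n_subtype_genes + config.n_survival_genes:]

    values = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    values[np.ix_(sub_idx, np.flatnonzero(is_gcb))] += config.effect_size
    values[np.ix_(surv_idx, np.flatnonzero(is_alive))] += config.effect_size
    values[np.ix_(shared_idx, np.flatnonzero(is_gcb))] += config.effect_size
    values[np.ix_(shared_idx, np.flatnonzero(is_alive))] += config.effect_size

    hazards = np.where(is_dead, config.baseline_hazard * config.hazard_ratio,
                       config.baseline_hazard)
    event_time = rng.exponential(1.0 / hazards)
    censor_time = rng.uniform(0.0, config.censor_time_max, size=n_samples)
    # dead-labelled samples must have an observed event: redraw until uncensored
    for i in np.flatnonzero(is_dead):
        tries = 0
        while event_time[i] > censor_time[i]:
            event_time[i] = rng.exponential(1.0 / hazards[i])
            tries += 1
            if tries > 100_000:  # unreachable for any sane hazard; hard stop
                event_time[i] = censor_time[i]
                break
    event = (event_time <= censor_time).astype(int)
    time = np.minimum(event_time, censor_time)
    time = np.maximum(time, np.finfo(float).tiny)  # guard time > 0

    expression = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                              columns=sample_ids)
    phenotype = pd.DataFrame(
        {"subtype": subtype, "status": status, "time": time, "event": event},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    axis = (["subtype"] * len(sub_idx) + ["survival"] * len(surv_idx)
            + ["both"] * len(shared_idx))
    truth = pd.DataFrame(
        {"gene_id": [gene_ids[i] for i in informative_idx], "axis": axis}
    ).sort_values("gene_id", kind="stable").reset_index(drop=True)
    return SyntheticDataset(expression=expression, phenotype=phenotype, truth=truth)
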