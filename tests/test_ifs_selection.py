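import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from signature_ifs.expression_io import FOUR_GROUPS, quantile_normalize
from signature_ifs.ifs_selection import (
    ifs_run,
    merge_risk,
    merge_subtype,
    select_balanced,
    subtype_accuracy,
)
from signature_ifs.mrmr_ranking import rank_features
from signature_ifs.synthetic_data import SimulationConfig, simulate
from conftest import make_expression
from oracles import brute_loocv


def make_curve(ks, accs, ps):
    return pd.DataFrame({
        "k": ks, "subtype_accuracy": accs,
        "logrank_statistic": np.zeros(len(ks)),
        "logrank_p": ps, "neg_log10_p": -np.log10(ps)})


def ranking_frame(genes):
    return pd.DataFrame({"rank": np.arange(1, len(genes) + 1), "gene_id": genes,
                         "relevance": 0.0, "redundancy": 0.0, "score": 0.0})


class TestMerges:
    @pytest.mark.parametrize("group, subtype, risk", [
        ("ABC-dead", "ABC", "high"),
        ("ABC-alive", "ABC", "low"),
        ("GCB-dead", "GCB", "high"),
        ("GCB-alive", "GCB", "low"),
    ])
    def test_mapping(self, group, subtype, risk):
        assert merge_subtype([group])[0] == subtype
        assert merge_risk([group])[0] == risk

    def test_merges_partition_all_samples(self):
        rng = np.random.default_rng(0)
        groups = rng.choice(FOUR_GROUPS, size=50)
        subtype = merge_subtype(groups)
        risk = merge_risk(groups)
        assert (subtype == "ABC").sum() + (subtype == "GCB").sum() == 50
        assert (risk == "high").sum() + (risk == "low").sum() == 50


class TestSubtypeAccuracy:
    def test_partial_count(self):
        pred = ["ABC", "ABC", "GCB", "ABC"]
        true = ["ABC", "ABC", "GCB", "GCB"]
        assert subtype_accuracy(pred, true) == pytest.approx(0.75)

    def test_extremes_and_validation(self):
        assert subtype_accuracy(["ABC"] * 3, ["ABC"] * 3) == 1.0
        assert subtype_accuracy(["ABC"] * 3, ["GCB"] * 3) == 0.0
        with pytest.raises(ValueError):
            subtype_accuracy([], [])


def _phenotype(groups, times, events):
    subtype = [g.split("-")[0] for g in groups]
    status = [g.split("-")[1] for g in groups]
    return pd.DataFrame(
        {"subtype": subtype, "status": status,
         "time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=pd.Index([f"s{j}" for j in range(len(groups))], name="sample_id"))


class TestIfsRun:
    def test_perfectly_separating_gene_gives_k1_accuracy_one(self):
        # within-group vectors closer than across: use 2 genes whose joint
        # direction differs per group; k=1 uses only the first ranked gene,
        # whose sign pattern alone separates subtype perfectly
        groups = np.repeat(FOUR_GROUPS, 3)
        g0 = np.repeat([10.0, 9.0, -10.0, -9.0], 3)   # ABC positive, GCB negative
        g1 = np.repeat([1.0, -1.0, 1.0, -1.0], 3)
        matrix = make_expression(np.vstack([g0, g1]))
        pheno = _phenotype(groups, np.arange(1, 13), [1, 0] * 6)
        pheno.index = matrix.columns
        curve = ifs_run(matrix, ranking_frame(["g0", "g1"]), pheno)
        assert len(curve) == 2
        assert curve["subtype_accuracy"].iloc[0] == 1.0

    def test_single_risk_group_records_degenerate_p(self, caplog):
        groups = np.repeat(["ABC-alive", "GCB-alive"], 3)
        rng = np.random.default_rng(2)
        matrix = make_expression(rng.normal(size=(2, 6)))
        pheno = _phenotype(groups, np.arange(1, 7), [0] * 6)
        pheno.index = matrix.columns
        curve = ifs_run(matrix, ranking_frame(["g0", "g1"]), pheno)
        assert (curve["logrank_p"] == 1.0).all()
        assert (curve["logrank_statistic"] == 0.0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_for_every_k(self, seed):
        rng = np.random.default_rng(500 + seed)
        n_genes, n_samples = 5, 12
        values = rng.normal(size=(n_genes, n_samples))
        groups = rng.choice(FOUR_GROUPS, size=n_samples)
        times = rng.exponential(5, n_samples)
        events = rng.integers(0, 2, n_samples)
        events[[g.endswith("dead") for g in groups]] = 1
        matrix = make_expression(values)
        pheno = _phenotype(groups, times, events)
        pheno.index = matrix.columns
        ranked = ranking_frame(list(matrix.index))
        curve = ifs_run(matrix, ranked, pheno)
        for k in range(1, n_genes + 1):
            pred = np.array(brute_loocv(values[:k], groups))
            acc = np.mean([p.split("-")[0] == g.split("-")[0]
                           for p, g in zip(pred, groups)])
            row = curve[curve["k"] == k].iloc[0]
            assert row["subtype_accuracy"] == pytest.approx(acc, abs=1e-12)
            high = np.array([p.endswith("dead") for p in pred])
            if high.all() or not high.any():
                assert row["logrank_p"] == 1.0
            else:
                ref = lifelines_logrank(times[high], times[~high],
                                        event_observed_A=events[high],
                                        event_observed_B=events[~high])
                assert row["logrank_p"] == pytest.approx(ref.p_value, abs=1e-8)


class TestSelectBalanced:
    def test_dominant_point_wins(self):
        ks = np.arange(1, 61)
        accs = np.where(ks == 35, 0.99, 0.8)
        ps = np.where(ks == 35, 1e-9, 1e-3).astype(float)
        sel = select_balanced(make_curve(ks, accs, ps),
                              ranking_frame([f"g{i}" for i in ks]), k_max=100)
        assert sel.chosen_k == 35
        assert len(sel.gene_ids) == 35
        assert sel.gene_ids[0] == "g1"

    def test_flat_accuracy_follows_the_p_curve(self):
        ks = np.arange(1, 81)
        accs = np.full(80, 0.9)
        # p improves strictly up to k=40 then worsens
        ps = 10.0 ** -(40 - np.abs(ks - 40))
        sel = select_balanced(make_curve(ks, accs, ps),
                              ranking_frame([f"g{i}" for i in ks]), k_max=100)
        assert sel.chosen_k == 40

    def test_score_tie_prefers_smaller_k(self):
        ks = np.arange(1, 11)
        accs = np.array([0.5, 0.9, 0.5, 0.9, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        ps = np.array([1.0, 1e-4, 1.0, 1e-4, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        sel = select_balanced(make_curve(ks, accs, ps),
                              ranking_frame([f"g{i}" for i in ks]), k_max=100)
        assert sel.chosen_k == 2

    def test_constant_curve_falls_back_to_k1(self, caplog):
        ks = np.arange(1, 6)
        sel = select_balanced(make_curve(ks, np.full(5, 0.7), np.full(5, 0.5)),
                              ranking_frame([f"g{i}" for i in ks]))
        assert sel.chosen_k == 1

    def test_window_excludes_k_at_and_above_k_max(self):
        ks = np.arange(1, 21)
        accs = np.where(ks >= 10, 1.0, 0.5)
        ps = np.where(ks >= 10, 1e-8, 0.5).astype(float)
        sel = select_balanced(make_curve(ks, accs, ps),
                              ranking_frame([f"g{i}" for i in ks]), k_max=10)
        # k=10 dominates but sits outside [1, 10); best within window is k<10
        assert sel.chosen_k < 10
        assert sel.selection_window == (1, 10)


def test_end_to_end_recovery_on_informative_cohort():
    """A strongly informative synthetic cohort yields a signature with high
    subtype accuracy and strong survival separation."""
    cfg = SimulationConfig(n_genes=120, group_sizes=(20, 20, 20, 20),
                           n_subtype_genes=8, n_survival_genes=8,
                           n_shared_genes=0, effect_size=2.0,
                           hazard_ratio=3.0, seed=42)
    ds = simulate(cfg)
    matrix = quantile_normalize(ds.expression)
    groups = (ds.phenotype["subtype"] + "-" + ds.phenotype["status"]).to_numpy()
    ranked = rank_features(matrix, groups, n_select=60)
    curve = ifs_run(matrix, ranked, ds.phenotype)
    sel = select_balanced(curve, ranked, k_max=60)
    assert sel.subtype_accuracy >= 0.85
    assert sel.logrank_p <= 1e-4
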