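import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from stabilome import nbstats, stability
from stabilome.counts_io import (
    Arm,
    CountMatrix,
    ExpressionMatrix,
    ExpressionUnit,
    SampleSheet,
)

from conftest import nb_draw, two_time_dataset


def expr_matrix(values: dict, genes) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes),
                            ExpressionUnit.NORM_COUNTS)


def one_time_sheet(time_h=1.0):
    return SampleSheet(pd.DataFrame({
        "sample_id": ["t1", "t2", "a1", "a2"],
        "time_h": [time_h] * 4,
        "arm": ["TNF", "TNF", "TNF_ACTD", "TNF_ACTD"],
        "replicate": [1, 2, 1, 2],
    }))


class TestStabilityRatio:
    def test_identical_arms_give_one(self):
        expr = expr_matrix({"t1": [100.0], "t2": [100.0],
                            "a1": [100.0], "a2": [100.0]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert tab.loc["g", "S"] == pytest.approx(1.0)
        assert tab.loc["g", "stability_class"] == 5

    def test_quarter_ratio(self):
        expr = expr_matrix({"t1": [200.0], "t2": [200.0],
                            "a1": [50.0], "a2": [50.0]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert tab.loc["g", "S"] == pytest.approx(0.25)

    def test_replicates_averaged_per_arm_before_ratio(self):
        expr = expr_matrix({"t1": [100.0], "t2": [300.0],
                            "a1": [40.0], "a2": [60.0]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert tab.loc["g", "S_raw"] == pytest.approx(50.0 / 200.0)

    def test_zero_denominator_excluded(self):
        expr = expr_matrix({"t1": [0.0], "t2": [0.0],
                            "a1": [5.0], "a2": [5.0]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert bool(tab.loc["g", "excluded"])
        assert "zero" in tab.loc["g", "reason"]

    def test_raw_above_one_clipped_for_class_only(self):
        expr = expr_matrix({"t1": [100.0], "t2": [100.0],
                            "a1": [130.0], "a2": [130.0]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert tab.loc["g", "S_raw"] == pytest.approx(1.3)
        assert tab.loc["g", "S"] == pytest.approx(1.0)
        assert tab.loc["g", "stability_class"] == 5

    def test_missing_arm_errors(self):
        expr = expr_matrix({"t1": [1.0], "t2": [1.0],
                            "a1": [1.0], "a2": [1.0]}, ["g"])
        with pytest.raises(ValueError, match="both arms"):
            stability.stability_ratio(expr, one_time_sheet(), 3.0)

    def test_first_order_decay_closed_form(self):
        # deterministic expected counts: S must equal exp(-lambda*t_chase)
        lam, t_chase = 0.231, 3.0
        tnf = 5000.0
        actd = tnf * np.exp(-lam * t_chase)
        expr = expr_matrix({"t1": [tnf], "t2": [tnf],
                            "a1": [actd], "a2": [actd]}, ["g"])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        assert tab.loc["g", "S_raw"] == pytest.approx(
            np.exp(-lam * t_chase), rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize("s,cls", [
        (0.0, 1), (0.15, 1), (0.1999, 1), (0.2, 2), (0.39, 2),
        (0.4, 3), (0.6, 4), (0.79, 4), (0.8, 5), (0.85, 5), (1.0, 5),
    ])
    def test_bin_edges(self, s, cls):
        assert stability.classify_stability(s) == cls

    def test_clipping_rule(self):
        assert stability.classify_stability(1.3) == 5
        assert stability.classify_stability(-0.2) == 1

    def test_composition_all_stable(self):
        comp = stability.stabilome_composition(pd.Series([5, 5, 5]))
        assert comp["fraction"].tolist() == [0, 0, 0, 0, 1]

    def test_composition_half_half(self):
        comp = stability.stabilome_composition(pd.Series([1, 1, 5, 5]))
        assert comp["fraction"].tolist() == [0.5, 0, 0, 0, 0.5]

    def test_composition_sums_to_one(self):
        rng = np.random.default_rng(0)
        comp = stability.stabilome_composition(
            pd.Series(rng.integers(1, 6, size=500)))
        assert comp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_composition_errors(self):
        with pytest.raises(ValueError, match="no classified"):
            stability.stabilome_composition(pd.Series([], dtype=int))

    def test_known_mixture_recovered_from_counts(self):
        # genes sampled at depth 500 around class-centre stabilities
        rng = np.random.default_rng(1)
        G = 5000
        target = np.array([0.1, 0.1, 0.1, 0.1, 0.6])
        cls_true = rng.choice(5, p=target, size=G)
        s_true = np.array([0.1, 0.3, 0.5, 0.7, 0.9])[cls_true]
        tnf = np.full(G, 500.0)
        expr = expr_matrix({
            "t1": rng.poisson(tnf), "t2": rng.poisson(tnf),
            "a1": rng.poisson(tnf * s_true), "a2": rng.poisson(tnf * s_true),
        }, [f"g{i}" for i in range(G)])
        tab = stability.stability_ratio(expr, one_time_sheet(), 1.0)
        comp = stability.stabilome_composition(
            tab.loc[~tab["excluded"], "stability_class"])
        np.testing.assert_allclose(comp["fraction"], target, atol=0.03)


class TestActdResponse:
    def test_unstable_gene_detected_down(self):
        rng = np.random.default_rng(2)
        G = 300
        s = np.full(G, 1.0)
        s[:20] = 0.1  # truly destabilized genes at high depth
        cm, sheet = two_time_dataset(np.full(G, 1000.0), 0.02,
                                     s_early=s, s_late=s, seed=3)
        res = stability.actd_response_test(cm, sheet, 1.0)
        assert res.loc[[f"g{i:04d}" for i in range(20)],
                       "significant_down"].all()

    def test_stable_genes_mostly_not_significant(self):
        G = 400
        cm, sheet = two_time_dataset(np.full(G, 500.0), 0.05,
                                     s_early=np.ones(G), s_late=np.ones(G),
                                     seed=4)
        res = stability.actd_response_test(cm, sheet, 1.0)
        assert (~res["significant_down"]).mean() >= 0.85

    def test_expression_filter_excludes_low_genes(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "t1": [80, 500], "t2": [80, 500],
            "a1": [80, 500], "a2": [80, 500]},
            index=["low", "high"])
        cm = CountMatrix(df)
        sheet = one_time_sheet()
        res = stability.actd_response_test(cm, sheet, 1.0, min_counts=100)
        assert "low" not in res.index and "high" in res.index

    def test_single_replicate_errors(self):
        cm = CountMatrix(pd.DataFrame({"t1": [5], "a1": [5]}))
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": ["t1", "a1"], "time_h": [1.0, 1.0],
            "arm": ["TNF", "TNF_ACTD"], "replicate": [1, 1]}))
        with pytest.raises(ValueError, match="2 replicates"):
            stability.actd_response_test(cm, sheet, 1.0)


@pytest.fixture(scope="module")
def workflow():
    G = 400
    s_early = np.full(G, 0.9)
    s_late = np.full(G, 0.9)
    s_early[:50] = 0.2   # unstable early, stabilized late
    s_late[:50] = 0.8
    s_early[50:100] = 0.45  # unstable early, destabilized further
    s_late[50:100] = 0.1
    cm, sheet = two_time_dataset(np.full(G, 800.0), 0.02,
                                 s_early=s_early, s_late=s_late, seed=7)
    return stability.two_step_stabilization_workflow(cm, sheet)


class TestTwoStepWorkflow:
    def test_stabilized_called(self, workflow):
        stabilized = set(workflow["stabilized"])
        expected = {f"g{i:04d}" for i in range(50)}
        assert len(expected & stabilized) >= 45

    def test_destabilized_called(self, workflow):
        destab = set(workflow["destabilized"])
        expected = {f"g{i:04d}" for i in range(50, 100)}
        assert len(expected & destab) >= 45

    def test_stable_genes_not_in_step1(self, workflow):
        step1 = set(workflow["actd_down_early"])
        stable = {f"g{i:04d}" for i in range(100, 400)}
        assert len(step1 & stable) / len(stable) < 0.15

    def test_gene_absent_at_late_dropped(self):
        G = 50
        basal = np.full(G, 800.0)
        s_early = np.full(G, 0.9)
        s_early[:5] = 0.2  # a minority of unstable genes, g0000 among them
        cm, sheet = two_time_dataset(basal, 0.02,
                                     s_early=s_early,
                                     s_late=np.full(G, 0.5), seed=9)
        # silence gene 0 in the late stimulation arm
        df = cm.counts.copy()
        late_tnf = [s for s in df.columns if s.startswith("tnf_72")]
        df.loc["g0000", late_tnf] = 3
        res = stability.two_step_stabilization_workflow(
            CountMatrix(df), sheet)
        assert "g0000" in res["dropped_not_expressed_late"]

    def test_sigfilter_variant_is_subset(self, workflow):
        tab = workflow["table"]
        assert (tab["destabilized_sigfilter"] <= tab["destabilized"]).all()


class TestDifferentialStability:
    def test_recovers_beta_delta(self):
        G_sig, G_null = 80, 320
        G = G_sig + G_null
        s_early = np.r_[np.full(G_sig, 0.125), np.full(G_null, 0.6)]
        s_late = np.r_[np.full(G_sig, 0.5), np.full(G_null, 0.6)]
        cm, sheet = two_time_dataset(np.full(G, 1000.0), 0.05,
                                     s_early=s_early, s_late=s_late, seed=10)
        res = stability.differential_stability_test(cm, sheet)
        sig = res.loc[res.index[:G_sig]]
        assert sig["beta_delta"].median() == pytest.approx(np.log(4),
                                                           rel=0.15)
        assert (sig["padj"] < 0.1).mean() >= 0.9
        assert (sig["direction"] == "stabilized").mean() >= 0.9

    def test_null_pvalues_uniform_and_degree_centred(self):
        G = 500
        rng = np.random.default_rng(11)
        basal = np.exp(rng.uniform(np.log(100), np.log(2000), G))
        cm, sheet = two_time_dataset(basal, 0.02 + 2.0 / basal,
                                     s_early=np.full(G, 0.5),
                                     s_late=np.full(G, 0.5), seed=12)
        res = stability.differential_stability_test(cm, sheet)
        assert kstest(res["pvalue"], "uniform").pvalue > 0.01
        assert abs(res["stabilization_degree"].median()) < 0.1

    def test_low_normalized_counts_excluded(self):
        G = 60
        basal = np.full(G, 500.0)
        basal[0] = 8.0  # below the normalized-count filter
        cm, sheet = two_time_dataset(basal, 0.02,
                                     s_early=np.full(G, 0.5),
                                     s_late=np.full(G, 0.5), seed=13)
        res = stability.differential_stability_test(cm, sheet)
        assert "g0000" not in res.index
        assert "g0000" in res.attrs["excluded"].index

    def test_direction_antisymmetric_under_time_swap(self):
        G = 120
        s_early = np.full(G, 0.6)
        s_late = np.full(G, 0.6)
        s_early[:30] = 0.15
        s_late[:30] = 0.7
        cm, sheet = two_time_dataset(np.full(G, 900.0), 0.03,
                                     s_early=s_early, s_late=s_late, seed=14)
        fwd = stability.differential_stability_test(cm, sheet,
                                                    early_h=1.0, late_h=72.0)
        rev = stability.differential_stability_test(cm, sheet,
                                                    early_h=72.0, late_h=1.0)
        common = fwd.index.intersection(rev.index)
        np.testing.assert_allclose(
            fwd.loc[common, "stabilization_degree"],
            -rev.loc[common, "stabilization_degree"], atol=1e-9)
        flip = {"stabilized": "destabilized",
                "destabilized": "stabilized", "unchanged": "unchanged"}
        assert (rev.loc[common, "direction"]
                == fwd.loc[common, "direction"].map(flip)).all()

    def test_same_time_points_rejected(self):
        cm, sheet = two_time_dataset(np.full(10, 100.0), 0.05,
                                     s_early=np.full(10, 0.5),
                                     s_late=np.full(10, 0.5), seed=15)
        with pytest.raises(ValueError, match="differ"):
            stability.differential_stability_test(cm, sheet,
                                                  early_h=1.0, late_h=1.0)


class TestRanking:
    def frame(self, degrees, padjs):
        return pd.DataFrame({
            "stabilization_degree": degrees,
            "padj": padjs,
        }, index=[f"gene{i+1}" for i in range(len(degrees))]).rename_axis(
            "gene_id")

    def test_sorted_by_degree_descending(self):
        tab = stability.rank_stabilized(self.frame([2.0, 3.0, 1.0],
                                                   [0.1, 0.1, 0.1]))
        assert list(tab.index) == ["gene2", "gene1", "gene3"]

    def test_tie_broken_by_padj(self):
        tab = stability.rank_stabilized(self.frame([2.0, 2.0],
                                                   [0.05, 0.01]))
        assert list(tab.index) == ["gene2", "gene1"]

    def test_top_n_truncates(self):
        tab = stability.rank_stabilized(
            self.frame([3.0, 2.0, 1.0], [0.1] * 3), top_n=2)
        assert len(tab) == 2

    def test_top_n_too_large_warns_returns_all(self):
        with pytest.warns(UserWarning, match="exceeds"):
            tab = stability.rank_stabilized(
                self.frame([1.0, 2.0], [0.1, 0.1]), top_n=10)
        assert len(tab) == 2

    def test_degrees_monotone_in_output(self):
        rng = np.random.default_rng(16)
        tab = stability.rank_stabilized(
            self.frame(rng.normal(size=50), rng.uniform(size=50)), top_n=40)
        assert len(tab) == 40
        deg = tab["stabilization_degree"].to_numpy()
        assert (np.diff(deg) <= 1e-12).all()
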