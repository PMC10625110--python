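import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtreg.screen import (
    auc,
    auc_table,
    classify_inhibitors,
    migration_logfc_series,
    scatter_distance,
    summarize_kinases,
    tumor_volume,
)


class TestScatterDistance:
    def test_two_symmetric_cells(self):
        assert scatter_distance(np.array([[0.0, 0.0], [2.0, 0.0]])) == pytest.approx(1.0)

    def test_single_cell_zero(self):
        assert scatter_distance(np.array([[5.0, 3.0]])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scatter_distance(np.empty((0, 2)))

    def test_pairwise_against_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2))
        ds = [
            np.linalg.norm(pts[i] - pts[j])
            for i in range(50)
            for j in range(i + 1, 50)
        ]
        assert scatter_distance(pts, method="pairwise") == pytest.approx(np.mean(ds))
        # mean pairwise distance dominates mean distance-to-centroid
        assert scatter_distance(pts, method="pairwise") >= scatter_distance(pts, "centroid")


def _distance_frame(treated_by_rep, control, inhibitor="I1"):
    """Build a distance table on the 4 h grid for one genotype x inducer."""
    times = np.arange(len(control)) * 4.0
    rows = []
    for rep, dvals in enumerate(treated_by_rep):
        for t, d in zip(times, dvals):
            rows.append(("WT", "DMOG", inhibitor, rep, t, d))
    for t, d in zip(times, control):
        rows.append(("WT", "DMOG", "UNTREATED", 0, t, d))
    return pd.DataFrame(
        rows, columns=["genotype", "inducer", "inhibitor", "replicate", "time_h", "distance"]
    )


class TestLogFCSeries:
    def test_exact_twofold(self):
        ctrl = [10.0, 20.0, 30.0]
        dist = _distance_frame([[20.0, 40.0, 60.0]], ctrl)
        s = migration_logfc_series(None, "WT", "DMOG", "I1", distances=dist)
        assert np.allclose(s["logfc"], 1.0)

    def test_treated_equals_control(self):
        ctrl = [10.0, 20.0, 30.0]
        dist = _distance_frame([ctrl], ctrl)
        s = migration_logfc_series(None, "WT", "DMOG", "I1", distances=dist)
        assert np.allclose(s["logfc"], 0.0)

    def test_replicates_averaged_after_log(self):
        # reps at 4x and 1x control: mean of logs is 1, log of means is ~1.32
        ctrl = [10.0, 10.0]
        dist = _distance_frame([[40.0, 40.0], [10.0, 10.0]], ctrl)
        s = migration_logfc_series(None, "WT", "DMOG", "I1", distances=dist)
        assert np.allclose(s["logfc"], 1.0)

    def test_zero_distance_floored_and_flagged(self):
        dist = _distance_frame([[0.0, 20.0]], [10.0, 10.0])
        s = migration_logfc_series(None, "WT", "DMOG", "I1", distances=dist)
        assert s["floored"].iloc[0]
        assert np.isfinite(s["logfc"]).all()

    def test_missing_control_errors(self):
        dist = _distance_frame([[10.0, 10.0]], [10.0, 10.0])
        dist = dist[dist["inhibitor"] != "UNTREATED"]
        with pytest.raises(ValueError, match="untreated control"):
            migration_logfc_series(None, "WT", "DMOG", "I1", distances=dist)


class TestAUC:
    def test_constant_one_over_48h(self):
        t = np.arange(0, 49, 4.0)
        assert auc((t, np.ones_like(t))) == pytest.approx(48.0, abs=1e-9)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 49, 4.0)
        assert auc((t, t / 24.0)) == pytest.approx(48.0, abs=1e-9)

    def test_zero_and_errors(self):
        t = np.arange(0, 49, 4.0)
        assert auc((t, np.zeros_like(t))) == 0.0
        with pytest.raises(ValueError, match="increasing"):
            auc(([0.0, 8.0, 4.0], [1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="2 timepoints"):
            auc(([0.0], [1.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=13, max_size=13),
        st.lists(st.floats(-5, 5), min_size=13, max_size=13),
        st.floats(-3, 3),
        st.floats(-3, 3),
    )
    def test_linearity(self, f, g, a, b):
        t = np.arange(13) * 4.0
        f, g = np.array(f), np.array(g)
        lhs = auc((t, a * f + b * g))
        rhs = a * auc((t, f)) + b * auc((t, g))
        assert lhs == pytest.approx(rhs, abs=1e-8)


def _auc_frame(wt, kd, inducer="DMOG"):
    inhibitors = [f"I{i}" for i in range(len(wt))]
    rows = [("WT", inducer, inh, v) for inh, v in zip(inhibitors, wt)] + [
        ("KD", inducer, inh, v) for inh, v in zip(inhibitors, kd)
    ]
    return pd.DataFrame(rows, columns=["genotype", "inducer", "inhibitor", "auc"])


class TestClassification:
    WT = [-10.0, -8.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0]

    def test_toy_panel_independent(self):
        cls = classify_inhibitors(_auc_frame(self.WT, self.WT))
        # q25 = -6.5 by linear interpolation; I0 at -10 <= q25 in both panels
        assert cls.thresholds.loc["DMOG", "q25_WT"] == pytest.approx(-6.5)
        assert cls.final.loc["I0", "category"] == "independent_inhibitor"

    def test_toy_panel_dependent_inhibitor(self):
        kd = list(self.WT)
        kd[0] = 0.0  # above q25 of the KD panel
        cls = classify_inhibitors(_auc_frame(self.WT, kd))
        assert cls.final.loc["I0", "category"] == "dependent_inhibitor"

    def test_toy_panel_dependent_activator(self):
        kd = list(self.WT)
        kd[4] = 10.0  # WT at median (-2 < q75), KD at panel maximum (>= q75)
        cls = classify_inhibitors(_auc_frame(self.WT, kd))
        assert cls.final.loc["I4", "category"] == "dependent_activator"

    def test_toy_panel_matches_quantile_oracle(self):
        """Every category equals direct percentile computation + rule order."""
        rng = np.random.default_rng(9)
        wt = rng.normal(size=20)
        kd = rng.normal(size=20)
        cls = classify_inhibitors(_auc_frame(list(wt), list(kd)))
        q25w, q75w = np.percentile(wt, [25, 75])
        q25k, q75k = np.percentile(kd, [25, 75])
        for i in range(20):
            if wt[i] <= q25w and kd[i] <= q25k:
                expect = "independent_inhibitor"
            elif wt[i] <= q25w and kd[i] > q25k:
                expect = "dependent_inhibitor"
            elif wt[i] < q75w and kd[i] >= q75k:
                expect = "dependent_activator"
            else:
                expect = "unclassified"
            assert cls.final.loc[f"I{i}", "category"] == expect

    def test_cross_inducer_intersection(self):
        kd = list(self.WT)
        kd[0] = 0.0
        both = pd.concat(
            [_auc_frame(self.WT, self.WT, "DMOG"), _auc_frame(self.WT, kd, "TGFB")]
        )
        cls = classify_inhibitors(both)
        # independent under DMOG but dependent under TGFB -> final unclassified
        per = cls.per_inducer.set_index(["inducer", "inhibitor"])["category"]
        assert per.loc[("DMOG", "I0")] == "independent_inhibitor"
        assert per.loc[("TGFB", "I0")] == "dependent_inhibitor"
        assert cls.final.loc["I0", "category"] == "unclassified"

    def test_shift_invariance_of_one_genotype(self):
        rng = np.random.default_rng(3)
        wt, kd = list(rng.normal(size=16)), list(rng.normal(size=16))
        base = classify_inhibitors(_auc_frame(wt, kd)).final
        shifted = classify_inhibitors(_auc_frame([v + 7.5 for v in wt], kd)).final
        pd.testing.assert_frame_equal(base, shifted)

    def test_panel_mismatch_errors(self):
        frame = _auc_frame(self.WT, self.WT)
        with pytest.raises(ValueError, match="unmatched"):
            classify_inhibitors(frame[~((frame["genotype"] == "KD") & (frame["inhibitor"] == "I0"))])


class TestKinaseSummary:
    def test_family_counts(self):
        cls = classify_inhibitors(_auc_frame([-10.0, -9.0, 0, 1, 2, 3, 4, 5],
                                             [-10.0, -9.0, 0, 1, 2, 3, 4, 5]))
        ik = pd.DataFrame({"inhibitor": ["I0", "I1"], "kinase": ["K1", "K2"]})
        kf = pd.DataFrame({"kinase": ["K1", "K2"], "family": ["TK", "TK"]})
        out = summarize_kinases(cls, ik, kf)
        row = out[(out["category"] == "independent_inhibitor") & (out["family"] == "TK")]
        assert row["n_kinases"].iloc[0] == 2
        assert (row["arm"] == "EMT-promoting").all()

    def test_empty_classification_gives_empty_table(self):
        cls = classify_inhibitors(_auc_frame([0.0, 1, 2, 3], [3.0, 2, 1, 0]))
        cls.final["category"] = "unclassified"
        ik = pd.DataFrame({"inhibitor": ["I0"], "kinase": ["K1"]})
        kf = pd.DataFrame({"kinase": ["K1"], "family": ["TK"]})
        assert summarize_kinases(cls, ik, kf).empty


class TestTumorVolume:
    def test_formula(self):
        assert tumor_volume(10, 5) == 125.0
        assert tumor_volume(2, 2) == 4.0

    def test_swap_with_warning(self):
        # swapped calipers give the same volume as the correct orientation
        with pytest.warns(UserWarning, match="swap"):
            assert tumor_volume(5, 10) == 125.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(0, 1)


def test_screen_recovery_small_world(small_screen):
    """Planted categories are recovered on the scaled-down synthetic screen."""
    tracks, truth, _, _ = small_screen
    cls = classify_inhibitors(auc_table(tracks))
    merged = cls.final.join(truth)
    planted = merged[merged["planted_category"] != "null"]
    assert (planted["category"] == planted["planted_category"]).mean() >= 0.8
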