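import numpy as np
import pandas as pd
import pytest
from scipy import stats

import longomics as lo


def _event_metadata():
    """One subject, one infection: healthy visits around an onset at day 300."""
    rows = [
        ("h0", "S1", 90, "healthy", None, np.nan),  # 210 d before onset: excluded
        ("h1", "S1", 150, "healthy", None, np.nan),  # preH
        ("h2", "S1", 250, "healthy", None, np.nan),  # preH
        ("e1", "S1", 304, "infection", "EV1", 5.0),  # EE
        ("e2", "S1", 306, "infection", "EV1", 7.0),  # EL
        ("e3", "S1", 320, "infection", "EV1", 21.0),  # RE
        ("h3", "S1", 400, "healthy", None, np.nan),  # postH
        ("h4", "S1", 600, "healthy", None, np.nan),  # beyond 186 d after: excluded
    ]
    return lo.VisitMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"],
        )
    )


class TestCategorizeVisits:
    def test_day_windows(self):
        cat = lo.categorize_visits(_event_metadata(), "EV1").set_index("sample_id")
        assert cat.loc["e1", "category"] == "EE"
        assert cat.loc["e2", "category"] == "EL"
        assert cat.loc["e3", "category"] == "RE"

    def test_healthy_window_186_days(self):
        cat = lo.categorize_visits(_event_metadata(), "EV1")
        ids = set(cat["sample_id"])
        assert "h1" in ids and "h2" in ids and "h3" in ids
        assert "h0" not in ids  # 210 days before onset
        assert "h4" not in ids  # > 186 days after last event visit
        by = cat.set_index("sample_id")["category"]
        assert by["h1"] == "preH" and by["h3"] == "postH"

    def test_event_without_stage_visits_rejected(self):
        meta = _event_metadata()
        t = meta.table.copy()
        t.loc[t["event_id"] == "EV1", "event_day"] = 50.0  # outside all windows
        with pytest.raises(ValueError, match="no visits"):
            lo.categorize_visits(lo.VisitMetadata(t), "EV1")

    def test_shared_healthy_visit_serves_both_events(self):
        t = _event_metadata().table.copy()
        extra = pd.DataFrame(
            [
                ("f1", "S1", 452, "infection", "EV2", 3.0),
            ],
            columns=t.columns[:6],
        )
        extra["is_qc"] = False
        meta = lo.VisitMetadata(pd.concat([t, extra], ignore_index=True))
        c1 = lo.categorize_visits(meta, "EV1")
        c2 = lo.categorize_visits(meta, "EV2")
        # h3 (day 400) is postH for EV1 and preH for EV2
        assert c1.set_index("sample_id")["category"]["h3"] == "postH"
        assert c2.set_index("sample_id")["category"]["h3"] == "preH"


class TestBaselineCorrect:
    def test_arithmetic(self):
        cat = lo.categorize_visits(_event_metadata(), "EV1")
        values = pd.Series(
            {"h1": 1.0, "h2": 3.0, "e1": 4.0, "e2": 2.0, "e3": 2.0, "h3": 2.0}
        )
        corr = lo.baseline_correct(values, cat)
        # baseline mean over {h1, h2, h3} = 2
        by = corr.set_index(corr["category"])["x_corrected"]
        assert by["EE"] == pytest.approx(2.0)
        assert by["EL"] == pytest.approx(0.0)
        assert corr["n_baseline"].unique().tolist() == [3]

    def test_subject_without_baseline_dropped(self):
        cat = lo.categorize_visits(_event_metadata(), "EV1")
        cat = cat[~cat["category"].isin(["preH", "postH"])]
        values = pd.Series({"e1": 4.0, "e2": 2.0, "e3": 2.0})
        corr = lo.baseline_correct(values, cat)
        assert len(corr) == 0
        assert corr.attrs["dropped_units"] == [("S1", "EV1")]


class TestAUCStatistic:
    def test_all_zero_corrected_gives_zero_statistic(self):
        res = lo.auc_statistic(
            np.zeros(4), ["EE", "EE", "EL", "RE"], [0, 0, 0, 0], np.full(4, 3.0), 1.0
        )
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_invariant_to_per_subject_constant(self):
        """mu_i cancels: shifting a subject's raw values leaves the statistic fixed."""
        rng = np.random.default_rng(5)
        meta = _event_metadata()
        cat = lo.categorize_visits(meta, "EV1")
        base = pd.Series(rng.normal(size=6), index=["h1", "h2", "h3", "e1", "e2", "e3"])
        shifted = base + 7.3  # single subject: one per-subject constant
        def stat(v):
            corr = lo.baseline_correct(v, cat)
            b = corr.attrs["baselines"]
            s2 = lo.pooled_baseline_variance(b["x_baseline"], b["unit"])
            return lo.auc_statistic(
                corr["x_corrected"], corr["category"], corr["unit"],
                corr["n_baseline"].to_numpy(float), s2,
            )["statistic"]
        assert stat(shifted) == pytest.approx(stat(base), abs=1e-12)

    def test_constant_feature_sigma_zero_flagged(self):
        res = lo.auc_statistic(np.ones(2), ["EE", "EL"], [0, 0], np.full(2, 2.0), 1.0)
        assert np.isfinite(res["statistic"])
        with pytest.raises(ValueError):
            lo.auc_statistic(np.ones(2), ["EE", "EL"], [0, 0], np.full(2, 2.0), 0.0)

    def test_missing_category_still_defined(self):
        res = lo.auc_statistic(
            np.array([1.0, -1.0]), ["EE", "EE"], [0, 1], np.full(2, 3.0), 1.0
        )
        assert res["cat_counts"]["EL"] == 0
        assert np.isfinite(res["statistic"])

    def test_closed_form_mean_under_shift(self):
        """Injected stage shifts move the statistic by the predicted amount."""
        effect = {"EE": 0.5, "EL": 0.5, "RE": 0.5}
        pred = lo.predicted_shift_mean(effect)
        sims = lo.simulate_null_auc(400, effect=effect, seed=9)
        assert sims.mean() == pytest.approx(pred, abs=4 * 1.1 / np.sqrt(400))

    def test_null_mean_zero_variance_one(self):
        sims = lo.simulate_null_auc(1500, seed=4)
        assert abs(sims.mean()) < 0.09
        assert 0.85 < sims.var() < 1.15


class TestStagePairedTest:
    def test_textbook_pairs(self):
        cat = pd.DataFrame(
            {
                "sample_id": ["a1", "b1", "c1", "a0", "b0", "c0"],
                "subject_id": ["A", "B", "C", "A", "B", "C"],
                "event_id": ["E"] * 6,
                "category": ["EE", "EE", "EE", "preH", "preH", "preH"],
            }
        )
        values = pd.Series({"a1": 2.0, "b1": 3.0, "c1": 4.0, "a0": 1.0, "b0": 1.0, "c0": 1.0})
        res = lo.stage_paired_test(values, cat, "EE")
        assert res["mean_diff"] == pytest.approx(2.0)
        assert res["t"] == pytest.approx(2 * np.sqrt(3))
        assert res["df"] == 2
        # matches the reference paired-t implementation
        ref = stats.ttest_rel([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res["t"] == pytest.approx(ref.statistic, abs=1e-12)
        assert res["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_pairs_give_t_zero(self):
        cat = pd.DataFrame(
            {
                "sample_id": ["a1", "b1", "a0", "b0"],
                "subject_id": ["A", "B", "A", "B"],
                "event_id": ["E"] * 4,
                "category": ["EE", "EE", "postH", "postH"],
            }
        )
        values = pd.Series({"a1": 1.0, "b1": 2.0, "a0": 1.0, "b0": 2.0})
        res = lo.stage_paired_test(values, cat, "EE")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_single_pair_rejected(self):
        cat = pd.DataFrame(
            {
                "sample_id": ["a1", "a0"],
                "subject_id": ["A", "A"],
                "event_id": ["E"] * 2,
                "category": ["EE", "preH"],
            }
        )
        with pytest.raises(ValueError, match=">=2 subjects"):
            lo.stage_paired_test(pd.Series({"a1": 1.0, "a0": 0.0}), cat, "EE")


class TestFdrAdjust:
    def test_single_p(self):
        assert lo.fdr_adjust([0.05]) == pytest.approx([0.05])

    def test_bh_by_hand(self):
        q = lo.fdr_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_order_invariance(self):
        p = np.array([0.2, 0.01, 0.04, 0.8])
        q = lo.fdr_adjust(p)
        perm = [2, 0, 3, 1]
        q_perm = lo.fdr_adjust(p[perm])
        assert np.allclose(q_perm, q[perm])

    def test_monotone_and_idempotent(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        q = lo.fdr_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
        assert np.allclose(lo.fdr_adjust(q), lo.fdr_adjust(q))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lo.fdr_adjust([])
        with pytest.raises(ValueError):
            lo.fdr_adjust([0.0, 0.5])


class TestLrTimeTest:
    def test_power_on_common_slope(self):
        rng = np.random.default_rng(0)
        rows, vals = [], {}
        for s in range(5):
            for v in range(6):
                sid = f"s{s}_{v}"
                day = 1 + 30 * v
                rows.append((sid, f"S{s}", day, "healthy", None, np.nan))
                vals[sid] = 0.05 * day + rng.normal(0, 0.5) + s
        meta = pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"]
        )
        res = lo.lr_time_test(pd.Series(vals), meta)
        assert res["p"] < 1e-6 and res["coef_time"] > 0

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(1)
        rows = []
        for s in range(6):
            for v in range(5):
                rows.append((f"s{s}_{v}", f"S{s}", 1 + 30 * v, "healthy", None, np.nan))
        meta = pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"]
        )
        hits = 0
        reps = 200
        for _ in range(reps):
            vals = pd.Series(rng.normal(size=len(meta)).tolist(), index=meta["sample_id"])
            hits += lo.lr_time_test(vals, meta)["p"] < 0.05
        # binomial 99% envelope around 0.05 with 200 reps
        assert 0.01 <= hits / reps <= 0.10


class TestAUCDeviationTestModel:
    def test_recovers_planted_responders(self, small_cohort):
        ck = lo.log_transform(small_cohort["matrices"]["cytokine"])
        res = lo.AUCDeviationTest(ck, small_cohort["metadata"], event_type="infection").fit()
        assert len(res.table) > 0
        assert set(res.table.columns) >= {"feature", "statistic", "p", "q", "m_EE", "m_EL", "m_RE"}
        assert "Personal-baseline deviation" in res.summary()
        # statistics of null features concentrate near N(0,1)
        null_feats = set(res.table["feature"]) - set(small_cohort["truth"].responders["cytokine"])
        null_stats = res.table.set_index("feature").loc[sorted(null_feats), "statistic"]
        assert abs(null_stats.mean()) < 0.6
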