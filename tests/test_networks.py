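import numpy as np
import pandas as pd
import pytest

import longomics as lo


def ancova_rmcorr_oracle(x, y, subjects):
    """Brute-force ANCOVA: y ~ C(subject) + x, r from the sums of squares."""
    import statsmodels.api as sm

    df = pd.DataFrame({"x": x, "y": y, "s": subjects})
    dummies = pd.get_dummies(df["s"], dtype=float)
    X_full = np.column_stack([dummies.to_numpy(), df["x"].to_numpy()])
    X_red = dummies.to_numpy()
    fit_full = sm.OLS(df["y"].to_numpy(), X_full).fit()
    fit_red = sm.OLS(df["y"].to_numpy(), X_red).fit()
    ss_err = fit_full.ssr
    ss_measure = fit_red.ssr - fit_full.ssr
    r = np.sign(fit_full.params[-1]) * np.sqrt(ss_measure / (ss_measure + ss_err))
    dof = len(df) - df["s"].nunique() - 1
    from scipy import stats

    F = ss_measure / (ss_err / dof)
    p = stats.f.sf(F, 1, dof)
    return float(r), int(dof), float(p)


class TestRmcorr:
    def test_matches_brute_force_ancova_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            k = rng.integers(3, 7)
            n_per = rng.integers(3, 6)
            subj = np.repeat(np.arange(k), n_per)
            x = rng.normal(size=k * n_per)
            y = rng.normal(size=k * n_per) + 0.4 * x
            mine = lo.rmcorr(x, y, subj)
            r, dof, p = ancova_rmcorr_oracle(x, y, subj)
            assert mine["r"] == pytest.approx(r, abs=1e-10)
            assert mine["df"] == dof
            assert mine["p"] == pytest.approx(p, abs=1e-10)

    def test_parallel_lines_give_exactly_one(self):
        subj = np.repeat([0, 1, 2], 4)
        x = np.tile(np.arange(4.0), 3)
        y = 2.0 * x + np.repeat([0.0, 5.0, -3.0], 4)
        assert lo.rmcorr(x, y, subj)["r"] == 1.0
        assert lo.rmcorr(x, -y, subj)["r"] == -1.0

    def test_zero_within_subject_slope(self):
        subj = np.repeat([0, 1], 4)
        x = np.tile(np.arange(4.0), 2)
        y = np.repeat([1.0, 2.0], 4)
        with pytest.raises(ValueError, match="variation"):
            lo.rmcorr(x, y, subj)  # y has no within-subject variation
        y2 = y + np.tile([0.1, -0.1, 0.1, -0.1], 2)  # variation orthogonal to x
        assert abs(lo.rmcorr(x, y2, subj)["r"]) < 0.6

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subj = np.repeat(np.arange(5), 6)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        mine = lo.rmcorr(x, y, subj)
        ref = pg.rm_corr(pd.DataFrame({"x": x, "y": y, "s": subj}), x="x", y="y", subject="s")
        assert mine["r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert mine["p"] == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            lo.rmcorr([1.0, 2.0], [1.0, 2.0], [0, 1])

    def test_ci_contains_r(self):
        rng = np.random.default_rng(9)
        subj = np.repeat(np.arange(6), 5)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        res = lo.rmcorr(x, y, subj)
        assert res["ci"][0] <= res["r"] <= res["ci"][1]


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        mine = lo.partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert mine["r"] == pytest.approx(ref.statistic, abs=1e-12)
        assert mine["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_independent_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        c = rng.normal(size=200)  # independent of both
        plain = lo.partial_correlation(x, y)["r"]
        partial = lo.partial_correlation(x, y, c)["r"]
        assert partial == pytest.approx(plain, abs=0.02)

    def test_variable_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(5)
        c = rng.normal(size=50)
        x = rng.normal(size=50)
        res = lo.partial_correlation(x, c, c)
        assert abs(res["r"]) < 1e-8

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            lo.partial_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], np.ones((3, 2)))


class TestSspgAssociation:
    def test_planted_sspg_signal_detected(self, healthy_only_cohort):
        meta, pheno, subjects = healthy_only_cohort
        rng = np.random.default_rng(6)
        sspg = pheno.table.set_index("subject_id")["sspg"]
        subj_of = meta.table.set_index("sample_id")["subject_id"]
        n = len(meta.table)
        planted = sspg.reindex(subj_of).to_numpy() / 50.0 + rng.normal(0, 0.5, n)
        null_feats = rng.normal(size=(10, n))
        vals = np.vstack([planted, null_feats])
        m = lo.OmicsMatrix(
            "clinical",
            pd.DataFrame(
                np.exp(vals / 5.0),
                index=[f"f{i}" for i in range(vals.shape[0])],
                columns=meta.sample_ids,
            ),
        )
        table = lo.sspg_association(lo.log_transform(m), meta, pheno)
        row = table.set_index("feature").loc["f0"]
        assert bool(row["significant"])
        assert (~table.set_index("feature").loc[[f"f{i}" for i in range(1, 11)], "significant"]).mean() > 0.8

    def test_ir_dummy_screen_detects_group_shift(self, healthy_only_cohort):
        meta, pheno, subjects = healthy_only_cohort
        rng = np.random.default_rng(7)
        ir = pheno.table.set_index("subject_id")["ir_is"] == "IR"
        subj_of = meta.table.set_index("sample_id")["subject_id"]
        shift = ir.reindex(subj_of).to_numpy().astype(float)  # 1 sigma group shift
        vals = (shift + rng.normal(0, 1, len(meta.table)))[None, :]
        m = lo.OmicsMatrix("clinical", pd.DataFrame(np.exp(vals / 5), columns=meta.sample_ids))
        table = lo.sspg_association(lo.log_transform(m), meta, pheno, target="ir_is")
        assert table["q"].iloc[0] < 0.1


class TestSparCC:
    def test_three_taxa_rejected(self):
        counts = pd.DataFrame(np.ones((3, 10)))
        with pytest.raises(ValueError, match="4 taxa"):
            lo.SparCC(counts)

    def test_planted_pair_recovered(self):
        counts = lo.generate_compositional_ome(
            20, 200, [(0, 1, 0.8)], depth=10000, seed=5
        )
        res = lo.SparCC(counts, n_iter=10, n_bootstrap=0, seed=1).fit()
        assert res.correlations.iloc[0, 1] == pytest.approx(0.8, abs=0.15)

    def test_independent_pairs_concentrate_near_zero(self):
        counts = lo.generate_compositional_ome(20, 200, [], depth=10000, seed=6)
        res = lo.SparCC(counts, n_iter=10, n_bootstrap=0, seed=2).fit()
        off = res.correlations.to_numpy().copy()
        np.fill_diagonal(off, 0.0)
        assert np.abs(off).mean() < 0.1

    def test_bootstrap_pvalues_separate_signal_from_noise(self):
        counts = lo.generate_compositional_ome(
            10, 120, [(0, 1, 0.85)], depth=10000, seed=8
        )
        res = lo.SparCC(counts, n_iter=5, n_bootstrap=30, seed=3).fit()
        assert res.pvalues.iloc[0, 1] <= 2 / 31
        edges = res.edges()
        null_p = edges[~((edges.feature_a == "taxon_000") & (edges.feature_b == "taxon_001"))]["p"]
        assert null_p.median() > 0.2


class TestClrRmcorrEdges:
    @staticmethod
    def _paired_data(coupled=True, group_subjects=None, seed=0):
        rng = np.random.default_rng(seed)
        n_s, n_v = 12, 6
        rows = []
        k = 0
        for s in range(n_s):
            for v in range(n_v):
                rows.append((f"x{k:04d}", f"S{s:02d}", 1 + 60 * v, "healthy", None, np.nan))
                k += 1
        meta = lo.VisitMetadata(
            pd.DataFrame(
                rows,
                columns=["sample_id", "subject_id", "day", "visit_class", "event_id", "event_day"],
            )
        )
        sample_ids = [r[0] for r in rows]
        subj_ids = np.repeat([f"S{s:02d}" for s in range(n_s)], n_v)
        driver = rng.normal(0, 1, len(rows))
        micro_latent = rng.normal(0, 1, (6, len(rows)))
        if coupled:
            mask = np.ones(len(rows), dtype=bool)
            if group_subjects is not None:
                mask = np.isin(subj_ids, group_subjects)
            micro_latent[0, mask] += 1.5 * driver[mask]
        comp = np.exp(micro_latent)
        rel = comp / comp.sum(axis=0, keepdims=True)
        micro = lo.OmicsMatrix(
            "gut16S",
            pd.DataFrame(rel, index=[f"f{i}" for i in range(6)], columns=sample_ids),
        )
        host_vals = np.vstack([driver + np.repeat(rng.normal(0, 1, n_s), n_v), rng.normal(0, 1, (3, len(rows)))])
        host = lo.OmicsMatrix(
            "cytokine",
            pd.DataFrame(
                np.exp(host_vals), index=[f"f{i}" for i in range(4)], columns=sample_ids
            ),
        )
        return micro, host, meta

    def test_planted_taxon_host_edge_detected(self):
        micro, host, meta = self._paired_data(coupled=True)
        table = lo.clr_rmcorr_edges(lo.clr_transform(micro), lo.log_transform(host), meta)
        row = table.set_index(["feature_a", "feature_b"]).loc[("f0", "f0")]
        assert bool(row["significant"])

    def test_uncoupled_data_rarely_called(self):
        micro, host, meta = self._paired_data(coupled=False, seed=3)
        table = lo.clr_rmcorr_edges(lo.clr_transform(micro), lo.log_transform(host), meta)
        assert table["significant"].mean() < 0.2

    def test_group_restriction(self):
        is_subj = [f"S{s:02d}" for s in range(6)]
        micro, host, meta = self._paired_data(coupled=True, group_subjects=is_subj, seed=4)
        sspg = [100.0] * 6 + [200.0] * 6
        pheno = lo.SubjectPhenotype(
            pd.DataFrame({"subject_id": [f"S{s:02d}" for s in range(12)], "sspg": sspg})
        )
        t_is = lo.clr_rmcorr_edges(
            lo.clr_transform(micro), lo.log_transform(host), meta, pheno, group="IS"
        )
        t_ir = lo.clr_rmcorr_edges(
            lo.clr_transform(micro), lo.log_transform(host), meta, pheno, group="IR"
        )
        key = ("f0", "f0")
        assert bool(t_is.set_index(["feature_a", "feature_b"]).loc[key, "significant"])
        assert not bool(t_ir.set_index(["feature_a", "feature_b"]).loc[key, "significant"])
        diff = lo.differential_edges(t_is, t_ir)
        labels = diff.set_index(["feature_a", "feature_b"])["label"]
        assert labels.loc[key] == "IS-unique"


class TestDifferentialEdges:
    @staticmethod
    def _table(qs):
        rows = []
        for (a, b), q in qs.items():
            rows.append({"feature_a": a, "feature_b": b, "r": 0.5, "q": q})
        return pd.DataFrame(rows)

    def test_identical_tables_give_empty_set(self):
        t = self._table({("a", "b"): 0.01, ("a", "c"): 0.5})
        assert len(lo.differential_edges(t, t.copy())) == 0

    def test_unique_edge_labelled(self):
        t_is = self._table({("a", "b"): 0.01, ("a", "c"): 0.5})
        t_ir = self._table({("a", "b"): 0.9, ("a", "c"): 0.5})
        diff = lo.differential_edges(t_is, t_ir)
        assert len(diff) == 1
        assert diff["label"].iloc[0] == "IS-unique"

    def test_node_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        pairs = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
        t_is = self._table({p: rng.uniform(0, 0.2) for p in pairs})
        t_ir = self._table({p: rng.uniform(0, 0.2) for p in pairs})
        diff = lo.differential_edges(t_is, t_ir)
        counts = diff.attrs["node_counts"]
        brute = {}
        for _, row in t_is.iterrows():
            if row["q"] < 0.05:
                for n in (row["feature_a"], row["feature_b"]):
                    brute[n] = brute.get(n, 0) + 1
        assert counts["IS"] == brute

    def test_mismatched_universe_rejected(self):
        t1 = self._table({("a", "b"): 0.01})
        t2 = self._table({("a", "c"): 0.01})
        with pytest.raises(ValueError, match="universe"):
            lo.differential_edges(t1, t2)


class TestGroupInteraction:
    def test_detects_slope_difference(self):
        rng = np.random.default_rng(1)
        subj = np.repeat(np.arange(10), 8)
        groups = np.where(subj < 5, "IS", "IR")
        x = rng.normal(size=80)
        slope = np.where(groups == "IS", 1.0, -1.0)
        y = slope * x + rng.normal(0, 0.3, 80)
        res = lo.group_interaction_test(x, y, subj, groups)
        assert res["p"] < 1e-6
        assert res["coef_interaction"] == pytest.approx(-2.0, abs=0.3)
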