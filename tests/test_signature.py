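"""Discovery pipeline: DEG filter, eligibility, resampling, screen, L1, consensus."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cafsig import (Classifier, DegCriteria, StabilityParams, SyntheticParams,
                    exclude_short_followup, filter_degs, fit_l1_signature,
                    generate_cohort, generate_paired_fibroblast_profiles,
                    stability_select, stratified_resample, univariate_screen)
from conftest import make_cohort_from_arrays


def _paired_frame(ncf: np.ndarray, caf: np.ndarray, genes) -> pd.DataFrame:
    n_pairs = ncf.shape[1]
    cols = pd.MultiIndex.from_tuples(
        [(f"P{i}", arm) for i in range(n_pairs) for arm in ("NCF", "CAF")],
        names=["pair", "arm"])
    data = np.empty((len(genes), 2 * n_pairs))
    data[:, 0::2] = ncf
    data[:, 1::2] = caf
    return pd.DataFrame(data, index=genes, columns=cols)


class TestFilterDegs:
    def test_low_abundance_gene_excluded(self):
        # 10-fold change but mean log expression 3.2 < 4
        rng = np.random.default_rng(0)
        ncf = rng.normal(0, 0.05, size=(2, 6)) + np.array([[1.55], [8.0]])
        caf = ncf + np.array([[np.log2(10)], [0.0]])
        paired = _paired_frame(ncf, caf, ["lowgene", "flat"])
        assert "lowgene" not in filter_degs(paired)

    def test_toy_fixture_matches_hand_computation(self):
        rng = np.random.default_rng(1)
        genes = ["planted"] + [f"flat{i}" for i in range(9)]
        base = np.array([[8.0]] * 10)
        ncf = base + rng.normal(0, 0.05, size=(10, 6))
        caf = base + rng.normal(0, 0.05, size=(10, 6))
        caf[0] += 2.0  # log2 effect 2
        paired = _paired_frame(ncf, caf, genes)

        result = filter_degs(paired, DegCriteria())
        # independent oracle: paired t + BH computed directly
        t, p = stats.ttest_rel(caf, ncf, axis=1)
        q = multipletests(p, method="fdr_bh")[1]
        fold = np.mean(2.0 ** (caf - ncf), axis=1)
        expect = [g for g, qi, fi in zip(genes, q, fold)
                  if qi < 0.05 and (fi > 2 or fi < 0.5)]
        assert result == expect == ["planted"]

    def test_exact_twofold_change_excluded(self):
        # fold change exactly 2.0 fails the strict ">2-fold" criterion
        ncf = np.tile(np.array([[8.0], [8.0]]), (1, 6))
        caf = ncf.copy()
        caf[0] += 1.0  # exactly 2-fold in every pair
        caf[1] += np.array([1.0, 1.1, 0.9, 1.2, 0.8, 1.05])  # mean fold > 2
        paired = _paired_frame(ncf, caf, ["exact2", "above2"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = filter_degs(paired)
        assert "exact2" not in result
        assert "above2" in result

    def test_unpaired_columns_error(self):
        paired = _paired_frame(np.zeros((2, 3)), np.zeros((2, 3)), ["a", "b"])
        broken = paired.copy()
        broken.columns = pd.MultiIndex.from_tuples(
            [("P0", "NCF"), ("P0", "CAF"), ("P1", "NCF"),
             ("P2", "CAF"), ("P2", "NCF"), ("P3", "CAF")])
        with pytest.raises(ValueError, match="unpaired"):
            filter_degs(broken)

    def test_requires_three_pairs(self):
        paired = _paired_frame(np.zeros((2, 2)), np.ones((2, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="pairs"):
            filter_degs(paired)


class TestExcludeShortFollowup:
    def _cohort(self, rec, dfs):
        n = len(rec)
        return make_cohort_from_arrays(
            np.zeros((n, 2)),
            {"stage": ["II"] * n, "recurrence": rec,
             "dfs_time": dfs, "dfs_event": rec,
             "dss_time": dfs, "dss_event": [0] * n})

    def test_nonrecurrent_short_followup_removed(self):
        c = self._cohort([0, 0], [30.0, 40.0])
        out = exclude_short_followup(c, 3.0)
        assert out.n_samples == 1
        assert out.clinical["dfs_time"].iloc[0] == 40.0

    def test_recurrent_always_retained(self):
        c = self._cohort([1, 0], [6.0, 50.0])
        assert exclude_short_followup(c, 3.0).n_samples == 2

    def test_160_to_135(self):
        rec = [1] * 48 + [0] * 112
        dfs = [20.0] * 48 + [30.0] * 25 + [48.0] * 87
        c = self._cohort(rec, dfs)
        out = exclude_short_followup(c, 3.0)
        assert out.n_samples == 135

    def test_missing_followup_error_lists_ids(self):
        c = self._cohort([0, 0], [np.nan, 40.0])
        with pytest.raises(ValueError, match="P001"):
            exclude_short_followup(c, 3.0)


class TestStratifiedResample:
    def _cohort(self, n2=64, n3=71):
        n = n2 + n3
        return make_cohort_from_arrays(
            np.zeros((n, 2)),
            {"stage": ["II"] * n2 + ["III"] * n3,
             "recurrence": [0] * n, "dfs_time": [48.0] * n,
             "dfs_event": [0] * n})

    def test_stage_proportional_sizes(self):
        c = self._cohort()
        train, test = stratified_resample(c, 2 / 3, "stage", seed=0)
        stages = c.clinical["stage"]
        assert (stages.loc[train] == "II").sum() == 43  # round(2/3*64)
        assert (stages.loc[train] == "III").sum() == 47  # round(2/3*71)
        assert sorted(train + test) == sorted(c.clinical.index)
        assert not set(train) & set(test)

    def test_three_sample_stratum(self):
        c = self._cohort(3, 4)
        train, test = stratified_resample(c, 2 / 3, "stage", seed=1)
        stages = c.clinical["stage"]
        assert (stages.loc[train] == "II").sum() == 2
        assert (stages.loc[test] == "II").sum() == 1

    def test_deterministic_given_seed(self):
        c = self._cohort()
        assert stratified_resample(c, 2 / 3, "stage", 5) == \
            stratified_resample(c, 2 / 3, "stage", 5)

    def test_singleton_stratum_error(self):
        c = self._cohort(1, 5)
        with pytest.raises(ValueError, match="stratum"):
            stratified_resample(c, 2 / 3, "stage", 0)


class TestUnivariateScreen:
    def _cohort(self, x, y):
        return make_cohort_from_arrays(
            np.asarray(x, dtype=float).reshape(-1, 1),
            {"stage": ["II"] * len(y), "recurrence": list(y),
             "dfs_time": [48.0] * len(y), "dfs_event": list(y)},
            genes=["g"])

    def test_2x2_fixture_matches_closed_form_and_statsmodels(self):
        # expression 0/1; counts: x=0 -> (20 no-rec, 10 rec); x=1 -> (10, 20)
        x = [0] * 30 + [1] * 30
        y = [0] * 20 + [1] * 10 + [0] * 10 + [1] * 20
        cohort = self._cohort(x, y)
        res = univariate_screen(cohort, ["g"], p_threshold=0.05, return_all=True)
        # closed form for the 2x2 logistic Wald test
        beta = np.log((20 / 10) / (10 / 20))
        se = np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        p_expected = 2 * stats.norm.sf(abs(beta / se))
        assert res.loc["g", "p"] == pytest.approx(p_expected, abs=1e-3)

        import statsmodels.api as sm
        xs = (np.array(x) - np.mean(x)) / np.std(x, ddof=1)
        fit = sm.Logit(np.array(y), sm.add_constant(xs)).fit(disp=0)
        assert res.loc["g", "p"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_matches_statsmodels_on_continuous_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-(x - 0.3)))).astype(int)
        cohort = self._cohort(x, y)
        res = univariate_screen(cohort, ["g"], 0.05, return_all=True)
        import statsmodels.api as sm
        xs = (x - x.mean()) / x.std(ddof=1)
        fit = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
        assert res.loc["g", "p"] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_perfect_predictor_passes_with_zero_p(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 30 + [1] * 30)
        x = y + rng.normal(0, 1e-3, size=60)
        res = univariate_screen(self._cohort(x, y), ["g"], 1e-10, return_all=True)
        assert res.loc["g", "p"] == 0.0
        assert bool(res.loc["g", "passed"])

    def test_constant_gene_excluded_with_warning(self):
        y = [0] * 5 + [1] * 5
        cohort = self._cohort([2.0] * 10, y)
        with pytest.warns(UserWarning, match="constant"):
            res = univariate_screen(cohort, ["g"], 0.05, return_all=True)
        assert "g" not in res.index

    def test_null_type_i_rate_calibrated(self):
        rng = np.random.default_rng(12)
        n, g = 200, 1000
        X = rng.normal(size=(n, g))
        y = (rng.uniform(size=n) < 0.35).astype(int)
        cohort = make_cohort_from_arrays(
            X, {"stage": ["II"] * n, "recurrence": y,
                "dfs_time": [48.0] * n, "dfs_event": y})
        res = univariate_screen(cohort, None, 0.01, return_all=True)
        k = int(res["passed"].sum())
        lo = stats.binom.ppf(0.005, g, 0.01)
        hi = stats.binom.ppf(0.995, g, 0.01)
        assert lo <= k <= hi


class TestFitL1:
    def _data(self, seed=0, n=90):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
        info = z[:, None] + rng.normal(0, 0.5, size=(n, 2))
        noise = rng.normal(size=(n, 4))
        X = pd.DataFrame(np.c_[info, noise],
                         columns=["inf1", "inf2", "n1", "n2", "n3", "n4"])
        return X, y

    def test_infinite_penalty_empty_selection(self):
        X, y = self._data()
        assert fit_l1_signature(X, y, Cs=np.array([1e-8])) == []

    def test_selected_subset_and_duplicate_informative_kept(self):
        X, y = self._data(seed=5)
        X["inf1_dup"] = X["inf1"]
        sel = fit_l1_signature(X, y, seed=1)
        assert set(sel) <= set(X.columns)
        assert {"inf1", "inf1_dup", "inf2"} & set(sel)

    def test_single_class_error(self):
        X, _ = self._data()
        with pytest.raises(ValueError, match="single class"):
            fit_l1_signature(X, np.zeros(len(X), dtype=int))

    def test_cv_min_rule_is_sparser_or_equal(self):
        X, y = self._data(seed=9)
        dense = fit_l1_signature(X, y, seed=2, penalty_rule="dense_1se")
        sparse = fit_l1_signature(X, y, seed=2, penalty_rule="cv_min")
        assert len(sparse) <= len(dense)


class TestStabilitySelect:
    @pytest.fixture(scope="class")
    def run(self):
        params = SyntheticParams(n_samples=120, n_genes=30)
        cohort, _ = generate_cohort(params, seed=3)
        sp = StabilityParams(n_iterations=40, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, clf, records = stability_select(cohort, sp)
        return cohort, table, clf, records

    def test_selected_subset_of_screened(self, run):
        _, _, _, records = run
        for r in records:
            assert set(r.selected_genes) <= set(r.screened_genes)
            assert not set(r.train_ids) & set(r.test_ids)

    def test_counts_sum_property(self, run):
        _, table, _, records = run
        assert table["count"].sum() == sum(len(r.selected_genes) for r in records)
        assert ((table["frequency"] >= 0) & (table["frequency"] <= 1)).all()
        assert np.allclose(table["frequency"], table["count"] / len(records))

    def test_consensus_contains_planted_signal(self, run):
        _, _, clf, _ = run
        planted = {"PDLIM3", "AMIGO2", "SLC7A2", "ULBP2", "CCL11"}
        assert planted <= set(clf.gene_ids)

    def test_directions_from_outcome_fallback(self, run):
        _, _, clf, _ = run
        signs = dict(clf.genes)
        assert signs["CCL11"] == -1
        for g in ("PDLIM3", "AMIGO2", "SLC7A2", "ULBP2"):
            assert signs[g] == +1

    def test_directions_from_paired_profiles(self):
        params = SyntheticParams(n_samples=120, n_genes=30)
        cohort, _ = generate_cohort(params, seed=3)
        paired = generate_paired_fibroblast_profiles(params, 10, seed=3)
        sp = StabilityParams(n_iterations=15, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, clf, _ = stability_select(cohort, sp, paired_profiles=paired)
        signs = dict(clf.genes)
        assert signs.get("CCL11", -1) == -1

    def test_frequency_threshold_one_empties_consensus(self):
        params = SyntheticParams(n_samples=120, n_genes=20)
        cohort, _ = generate_cohort(params, seed=1)
        sp = StabilityParams(n_iterations=10, seed=1,
                             frequency_threshold=0.999999)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, clf, _ = stability_select(cohort, sp)
        always = table.index[table["frequency"] >= 1.0]
        assert set(clf.gene_ids) == set(always)

    def test_deterministic_given_seed(self):
        params = SyntheticParams(n_samples=120, n_genes=20)
        cohort, _ = generate_cohort(params, seed=2)
        sp = StabilityParams(n_iterations=10, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1, c1, _ = stability_select(cohort, sp)
            t2, c2, _ = stability_select(cohort, sp)
        pd.testing.assert_frame_equal(t1, t2)
        assert c1.genes == c2.genes


class TestClassifierType:
    def test_roundtrip_dict(self):
        clf = Classifier([("A", 1), ("B", -1)], cutoff=1.5)
        assert Classifier.from_dict(clf.to_dict()).genes == clf.genes

    def test_invalid_coefficient(self):
        with pytest.raises(ValueError, match="[+-]1"):
            Classifier([("A", 2)], cutoff=0.0).validate()

    def test_duplicate_gene(self):
        with pytest.raises(ValueError, match="duplicated"):
            Classifier([("A", 1), ("A", -1)]).validate()


class TestConsensusIterationStability:
    def test_consensus_stable_under_fewer_iterations(self):
        """The consensus gene set barely moves between a short and a 3x
        longer resampling run on the same cohort (scaled-down check)."""
        params = SyntheticParams(n_samples=120, n_genes=20)
        same = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(3):
                cohort, _ = generate_cohort(params, seed=40 + seed)
                short = stability_select(
                    cohort, StabilityParams(n_iterations=60, seed=seed))[1]
                long_ = stability_select(
                    cohort, StabilityParams(n_iterations=180, seed=seed))[1]
                same += set(short.gene_ids) == set(long_.gene_ids)
        assert same >= 2
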