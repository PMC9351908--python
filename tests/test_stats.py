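"""Outcome statistics: test routing, logistic closed forms, ROC identities,
combined predictor, and the full study pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibwave.stats import (
    DEFAULT_CUTOFF_DF_I,
    DEFAULT_CUTOFF_FWA_V1,
    combined_predictor,
    fit_logistic,
    roc_analysis,
    run_study,
    univariate_screen,
)
from fibwave.synthetic import CohortSimParams, gen_cohort


def cohort_2x2(n00, n01, n10, n11, xname="x", yname="y"):
    """Cohort with binary predictor/outcome counts: n_xy patients with
    x, y taking those values."""
    rows = []
    for (x, y), n in zip(((0, 0), (0, 1), (1, 0), (1, 1)), (n00, n01, n10, n11)):
        rows += [{xname: x, yname: y}] * n
    return pd.DataFrame(rows)


class TestUnivariateScreen:
    def test_chi_square_hand_value(self):
        # 2x2 table (30,10 / 10,30): chi-square without continuity = 20.0
        c = cohort_2x2(30, 10, 10, 30)
        res = univariate_screen(c, ["x"], "y")[0]
        assert res.test_name == "chi-square"
        assert res.statistic == pytest.approx(20.0, abs=1e-9)

    def test_fisher_on_sparse_table(self):
        c = cohort_2x2(20, 2, 2, 1)  # expected min cell 3*3/25 < 5
        res = univariate_screen(c, ["x"], "y")[0]
        assert res.test_name == "fisher"
        assert 0.0 <= res.p_value <= 1.0

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(50, 10, 60)
        c = pd.DataFrame({"m": np.r_[vals, vals], "y": np.r_[np.zeros(60), np.ones(60)]})
        res = univariate_screen(c, ["m"], "y")[0]
        assert res.p_value > 0.99

    def test_normality_gates_test_choice(self):
        rng = np.random.default_rng(1)
        c = pd.DataFrame({
            "gauss": rng.normal(0, 1, 300),
            "skewed": rng.lognormal(0, 1.5, 300),
            "y": rng.integers(0, 2, 300),
        })
        res = {r.variable: r for r in univariate_screen(c, ["gauss", "skewed"], "y")}
        assert res["gauss"].test_name == "t"
        assert res["skewed"].test_name == "mann-whitney"

    def test_constant_variable_flagged(self):
        c = pd.DataFrame({"m": np.ones(40), "y": np.r_[np.zeros(20), np.ones(20)]})
        res = univariate_screen(c, ["m"], "y")[0]
        assert res.flags.get("constant")
        assert np.isnan(res.p_value)

    def test_screen_type_i_error_calibrated(self):
        # same normal law in both groups: rejection rate ~5% at alpha=.05
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            c = pd.DataFrame({
                "m": rng.normal(70, 25, 130),
                "y": np.r_[np.zeros(44), np.ones(86)],
            })
            rejections += univariate_screen(c, ["m"], "y")[0].p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08


class TestFitLogistic:
    def test_2x2_closed_form(self):
        # counts (20,10 / 10,20): OR = ad/bc = 4
        c = cohort_2x2(20, 10, 10, 20)
        fit = fit_logistic(c, ["x"], "y")
        assert fit.odds_ratio["x"] == pytest.approx(4.0, rel=1e-6)

    def test_arbitrary_2x2_matches_ad_bc(self):
        for n in ((35, 12, 8, 25), (50, 30, 20, 40)):
            c = cohort_2x2(*n)
            a, b, d, e = n  # x=0: a controls, b cases; x=1: d controls, e cases
            fit = fit_logistic(c, ["x"], "y")
            assert fit.odds_ratio["x"] == pytest.approx((a * e) / (b * d), rel=1e-6)

    def test_null_consistency_large_n(self):
        rng = np.random.default_rng(5)
        n = 10000
        c = pd.DataFrame({"x": rng.normal(0, 1, n), "y": rng.integers(0, 2, n)})
        fit = fit_logistic(c, ["x"], "y")
        assert 0.95 <= fit.odds_ratio["x"] <= 1.05

    def test_rescaling_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(int)
        c = pd.DataFrame({"x": x, "xs": 10.0 * x, "y": y})
        b1 = np.log(fit_logistic(c, ["x"], "y").odds_ratio["x"])
        b2 = np.log(fit_logistic(c, ["xs"], "y").odds_ratio["xs"])
        assert b1 == pytest.approx(10.0 * b2, rel=1e-6)

    def test_separation_flagged(self):
        c = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                          "y": np.r_[np.zeros(20), np.ones(20)]})
        fit = fit_logistic(c, ["x"], "y")
        assert not fit.converged or fit.flags.get("non_reportable")
        assert not fit.ci95


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10) * 5]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        r = roc_analysis(scores, labels, "higher")
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 0.0 < r.cutoff <= 5.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_mannwhitney(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(0, 1, 80), 1)  # rounding forces ties
        labels = rng.integers(0, 2, 80)
        if labels.sum() in (0, 80):
            labels[0] = 1 - labels[0]
        r = roc_analysis(scores, labels, "higher")
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = labels.sum(), (1 - labels).sum()
        assert r.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_orientation_flip(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 100) + np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        hi = roc_analysis(scores, labels, "higher")
        lo = roc_analysis(scores, labels, "lower")
        assert hi.auc == pytest.approx(1.0 - lo.auc, abs=1e-12)
        assert hi.auc > 0.5

    def test_null_auc_permutations(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 1, 130)
        aucs = []
        for _ in range(200):
            labels = rng.permutation(np.r_[np.zeros(44, int), np.ones(86, int)])
            aucs.append(roc_analysis(scores, labels, "higher").auc)
        assert np.mean(aucs) == pytest.approx(0.50, abs=0.02)

    def test_youden_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(5, 1, 120)
        labels = (scores + rng.normal(0, 1, 120) > 5).astype(int)
        r1 = roc_analysis(scores, labels, "higher")
        r2 = roc_analysis(np.exp(scores), labels, "higher")
        assert r2.sensitivity == r1.sensitivity
        assert r2.specificity == r1.specificity
        assert r2.cutoff == pytest.approx(np.exp(r1.cutoff), rel=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(10.0), np.ones(10, int), "higher")


class TestCombinedPredictor:
    def make_cohort(self, seed, n=200, conj_driven=True):
        rng = np.random.default_rng(seed)
        fwa = rng.normal(70, 25, n)
        df = rng.normal(5.7, 1.0, n)
        conj = (fwa < DEFAULT_CUTOFF_FWA_V1) & (df > DEFAULT_CUTOFF_DF_I)
        if conj_driven:
            p = np.where(conj, 0.75, 0.18)
        else:
            p = np.full(n, 0.3)
        y = (rng.random(n) < p).astype(int)
        return pd.DataFrame({"fwa_v1": fwa, "df_i": df, "y": y})

    def test_conjunction_is_elementwise_and(self):
        c = self.make_cohort(0)
        fits = combined_predictor(c, "y")
        # rebuild indicators to compare
        low = (c.fwa_v1 < DEFAULT_CUTOFF_FWA_V1).astype(int)
        high = (c.df_i > DEFAULT_CUTOFF_DF_I).astype(int)
        assert fits["combined"].predictors[0] == "low_fwa_and_high_df"
        assert (low & high).sum() > 0  # planted stratum nonempty

    def test_conjunction_outperforms_singles_when_planted(self):
        wins = 0
        n_rep = 60
        for seed in range(n_rep):
            c = self.make_cohort(seed)
            fits = combined_predictor(c, "y")
            single = fits["single_indicators"].odds_ratio
            comb = fits["combined"].odds_ratio
            if not comb or not single:
                continue
            if comb["low_fwa_and_high_df"] > max(single["low_fwa_v1"],
                                                 single["high_df_i"]):
                wins += 1
        assert wins > n_rep / 2

    def test_published_default_cutoffs(self):
        assert DEFAULT_CUTOFF_FWA_V1 == 60.38
        assert DEFAULT_CUTOFF_DF_I == 5.70


class TestRunStudy:
    def test_planted_cohort_end_to_end(self):
        cohort = gen_cohort(CohortSimParams(n_patients=400, seed=9))
        report = run_study(cohort)
        term = report["endpoint_termination"]
        assert not term["univariate"].empty
        # the planted strong effects should screen in at n=400
        assert "df_i" in term["significant"]
        for roc in term["roc"].values():
            assert 0.0 <= roc.auc <= 1.0
            assert roc.ci95[0] <= roc.auc <= roc.ci95[1]
        assert "combined_model" in report

    def test_deterministic_given_cohort(self):
        cohort = gen_cohort(CohortSimParams(seed=4))
        r1 = run_study(cohort)
        r2 = run_study(cohort)
        pd.testing.assert_frame_equal(
            r1["endpoint_termination"]["univariate"],
            r2["endpoint_termination"]["univariate"],
        )

    def test_missing_outcome_rejected(self):
        cohort = gen_cohort(CohortSimParams(seed=1)).drop(
            columns=["endpoint_recurrence"]
        )
        with pytest.raises(ValueError, match="endpoint_recurrence"):
            run_study(cohort)
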