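"""Evaluation procedures: ROC/AUC, DeLong, PR, enrichment, deciles, additivity."""

import itertools
import math

import numpy as np
import pytest

from comir.evaluate import (
    additivity_regression,
    compare_auc,
    decile_ecdf_analysis,
    enrichment_pvalue,
    precision_recall,
    roc_auc,
    sensitivity_vs_threshold,
)
from comir.simulate import simulate_transfection_fc


def pairwise_auc(scores, labels):
    """O(n^2) oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 11, 12, 13], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_anti_ordered_scores(self):
        res = roc_auc([11, 12, 13, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.auc == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 25))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.4).astype(int)
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCompareAuc:
    def test_identical_scores_not_significant(self):
        scores = [1.0, 3.0, 2.0, 5.0, 4.0, 0.5]
        labels = [0, 1, 0, 1, 1, 0]
        res = compare_auc(scores, scores, labels, method="delong")
        assert res.diff == 0.0
        assert res.p_value == 1.0
        res_b = compare_auc(scores, scores, labels, method="bootstrap", seed=0)
        assert res_b.p_value == 1.0

    def test_perfect_vs_random_significant(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 100)
        perfect = labels + rng.normal(0, 0.05, 200)
        random_scores = rng.normal(size=200)
        res = compare_auc(perfect, random_scores, labels, method="delong")
        assert res.p_value < 0.01
        assert res.diff > 0.3

    def test_delong_and_bootstrap_agree_roughly(self):
        # moderate planted difference so both methods resolve the p-value
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 100)
        a = labels * 0.5 + rng.normal(0, 1, 200)
        b = labels * 0.3 + rng.normal(0, 1, 200)
        p_d = compare_auc(a, b, labels, method="delong").p_value
        p_b = compare_auc(a, b, labels, method="bootstrap", seed=1).p_value
        assert p_d > 0 and p_b > 0
        assert abs(math.log10(p_d) - math.log10(max(p_b, 5e-4))) <= 1.0

    def test_degenerate_variance_reported(self):
        # constant scores on both sides: zero variance, zero difference
        res = compare_auc([1, 1, 1, 1], [1, 1, 1, 1], [0, 1, 0, 1])
        assert res.note == "degenerate variance"
        assert res.p_value == 1.0


class TestPrecisionRecall:
    def test_perfect_classifier_precision_one_everywhere(self):
        res = precision_recall([1, 2, 3, 11, 12, 13], [0, 0, 0, 1, 1, 1])
        assert np.all(res.precision[res.recall > 0] == 1.0)

    def test_constant_scores_single_point_at_prevalence(self):
        res = precision_recall([5.0] * 8, [0, 0, 1, 0, 1, 0, 0, 0])
        assert len(res.precision) == 1
        assert res.precision[0] == pytest.approx(2 / 8)
        assert res.recall[0] == 1.0

    def test_matches_threshold_enumeration(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        res = precision_recall(scores, labels)
        for prec, rec, thr in zip(res.precision, res.recall, res.thresholds):
            called = scores >= thr
            assert prec == pytest.approx(labels[called].sum() / called.sum())
            assert rec == pytest.approx(labels[called].sum() / labels.sum())


class TestSensitivityVsThreshold:
    def test_extreme_thresholds(self):
        all_scores = [0.1, 0.5, 0.9]
        pos_scores = [0.5, 0.9]
        res = sensitivity_vs_threshold(all_scores, pos_scores, grid=[0.0, 1.0])
        assert res.frac_pos[0] == 1.0
        assert res.frac_pos[-1] == 0.0
        assert res.not_standard_roc

    def test_hand_computed_fractions(self):
        all_scores = list(range(10))
        pos_scores = [7, 8, 9]
        res = sensitivity_vs_threshold(all_scores, pos_scores, grid=[2.0, 7.5, 8.5])
        assert list(res.frac_pos) == [1.0, pytest.approx(2 / 3), pytest.approx(1 / 3)]
        assert list(res.frac_all) == [0.8, 0.2, 0.1]

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sensitivity_vs_threshold([1.0, 2.0], [])


class TestEnrichment:
    def test_full_overlap_small_universe(self):
        # P(drawing all 5 of the 5-gene set in 5 draws from 10) = 1/C(10,5)
        assert enrichment_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_literal_enumeration_tiny_universe(self):
        # exhaustive enumeration over all C(10, 4) draws
        universe = range(10)
        gene_set = set(range(5))
        n_pred, k = 4, 2
        hits = sum(
            1 for draw in itertools.combinations(universe, n_pred)
            if len(gene_set & set(draw)) >= k
        )
        expected = hits / math.comb(10, n_pred)
        assert enrichment_pvalue(10, 5, n_pred, k) == pytest.approx(expected, abs=1e-12)

    def test_expected_overlap_not_significant(self):
        # overlap exactly at its expectation lands mid-distribution
        p = enrichment_pvalue(60, 20, 30, 10)
        assert 0.05 < p < 0.75

    def test_zero_predictions_give_p_one(self):
        assert enrichment_pvalue(100, 10, 0, 0) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="overlap exceeds"):
            enrichment_pvalue(10, 3, 4, 5)


class TestDecileEcdf:
    def test_identical_samples_give_zero_distance(self, rng):
        ref = rng.normal(size=100)
        scores = np.arange(100, dtype=float)
        measure = np.tile(ref[:10], 10)
        out = decile_ecdf_analysis(scores, measure, measure[:10])
        # decile 1 = the ten highest-score genes, same values as reference
        assert out.loc[1, "ks_d"] == 0.0

    def test_shifted_top_decile_has_largest_distance(self, rng):
        n = 1000
        scores = np.arange(n, dtype=float)[::-1]  # first genes = decile 1
        measure = rng.normal(size=n)
        measure[:100] -= 1.0  # shift the top decile down
        ref = rng.normal(size=400)
        out = decile_ecdf_analysis(scores, measure, ref)
        assert out["ks_d"].idxmax() == 1
        assert out.loc[1, "wilcoxon_p"] < 1e-6

    def test_small_decile_flagged_and_skipped(self, rng):
        out = decile_ecdf_analysis(
            np.arange(12, dtype=float), rng.normal(size=12), rng.normal(size=50)
        )
        assert out["flagged"].any()
        assert out.loc[out["flagged"], "ks_p"].isna().all()


class TestAdditivityRegression:
    def test_noiseless_additive_model_recovered(self):
        fc = simulate_transfection_fc(100, a=0.5, b=0.3, c=0.0, noise_sd=0.0, seed=1)
        fit = additivity_regression(fc["fc_l"], fc["fc_m"], fc["fc_lm"])
        assert "fc_l:fc_m" not in fit.retained
        assert fit.coef_reduced["fc_l"] == pytest.approx(0.5, abs=1e-8)
        assert fit.coef_reduced["fc_m"] == pytest.approx(0.3, abs=1e-8)
        assert fit.r2_full == pytest.approx(1.0)

    def test_planted_interaction_retained(self):
        for seed in range(10):
            fc = simulate_transfection_fc(500, a=0.5, b=0.3, c=0.5,
                                          noise_sd=0.1, seed=seed)
            fit = additivity_regression(fc["fc_l"], fc["fc_m"], fc["fc_lm"])
            assert "fc_l:fc_m" in fit.retained

    def test_pure_noise_reduces_to_intercept(self):
        fc = simulate_transfection_fc(300, a=0.0, b=0.0, c=0.0, noise_sd=1.0, seed=4)
        fit = additivity_regression(fc["fc_l"], fc["fc_m"], fc["fc_lm"])
        assert fit.retained == []
        assert set(fit.coef_reduced) == {"const"}

    def test_r2_never_increases_along_elimination(self):
        fc = simulate_transfection_fc(200, a=0.2, b=0.0, c=0.0, noise_sd=0.5, seed=9)
        fit = additivity_regression(fc["fc_l"], fc["fc_m"], fc["fc_lm"])
        r2s = [fit.r2_full] + [r2 for _, _, r2 in fit.trace]
        assert all(b <= a + 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_collinear_design_warns(self):
        x = np.linspace(-1, 1, 50)
        with pytest.warns(UserWarning, match="collinear"):
            additivity_regression(x, 2 * x, x)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            additivity_regression([1.0] * 5, [1.0] * 5, [1.0] * 5)
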