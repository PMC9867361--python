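"""Metrics, cross-validation, descriptives, correlations and box plots."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervitex.cohort import ABNORMAL, NORMAL, cohort_frame
from cervitex.classify import train_c45
from cervitex.evaluate import (ConfusionMatrix, band_summaries,
                               boxplot_summary, confusion,
                               correlation_vs_response, describe, kfold_cv,
                               metrics)


class TestConfusion:
    def test_cohort_scores_with_painfree_positive(self, cohort_df):
        preds = (cohort_df.gep_h >= 0.5).astype(int).tolist()
        cm = confusion(preds, cohort_df.input_class.tolist(),
                       positive_class=NORMAL)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (8, 34, 4, 0)

    def test_perfect_predictions(self):
        cm = confusion([0, 1, 0], [0, 1, 0])
        assert cm.FP == 0 and cm.FN == 0

    def test_all_positive_predictions_count_total(self, cohort_df):
        preds = [ABNORMAL] * len(cohort_df)
        cm = confusion(preds, cohort_df.input_class.tolist(),
                       positive_class=ABNORMAL)
        assert cm.TP + cm.FP == 46

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0], [0, 1])


class TestMetrics:
    def test_published_test_matrix(self):
        # 16-sample held-out evaluation of the cost-sensitive tree
        cm = ConfusionMatrix(TP=13, FP=0, TN=2, FN=1, positive_class=ABNORMAL)
        rep = metrics(cm)
        assert rep.accuracy == pytest.approx(15 / 16)
        disp = rep.display()
        assert disp["accuracy_pct"] == 94
        assert disp["weighted_precision"] == 0.96
        assert disp["weighted_recall"] == 0.94

    def test_perfect_matrix_all_ones(self):
        rep = metrics(ConfusionMatrix(TP=5, FP=0, TN=5, FN=0))
        assert rep.accuracy == rep.weighted_precision == rep.weighted_f1 == 1.0

    def test_uniform_matrix(self):
        rep = metrics(ConfusionMatrix(TP=1, FP=1, TN=1, FN=1))
        assert rep.per_class[ABNORMAL].precision == 0.5
        assert rep.per_class[ABNORMAL].recall == 0.5
        assert rep.accuracy == 0.5

    def test_zero_division_flagged_not_raised(self):
        rep = metrics(ConfusionMatrix(TP=0, FP=0, TN=4, FN=2))
        assert rep.undefined_components          # precision of positive class
        assert not math.isnan(rep.weighted_recall)

    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           tn=st.integers(0, 30), fn=st.integers(0, 30))
    @settings(max_examples=60, deadline=None)
    def test_weighted_recall_equals_accuracy(self, tp, fp, tn, fn):
        # algebraic identity for binary confusion matrices
        if tp + fp + tn + fn == 0:
            return
        rep = metrics(ConfusionMatrix(tp, fp, tn, fn))
        if not rep.undefined_components:
            assert rep.weighted_recall == pytest.approx(rep.accuracy)

    def test_accuracy_equals_agreement_rate(self, rng):
        preds = rng.integers(0, 2, 60).tolist()
        truths = rng.integers(0, 2, 60).tolist()
        rep = metrics(confusion(preds, truths))
        assert rep.accuracy == pytest.approx(
            np.mean([p == t for p, t in zip(preds, truths)]))


class TestKFold:
    def _toy(self):
        import pandas as pd
        return pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                             "input_class": [0, 0, 0, 1, 1, 1]})

    def test_leave_one_out_fold_sizes(self):
        df = self._toy()
        cv = kfold_cv(df, lambda tr: train_c45(tr, features=["x"], min_leaf=1),
                      k=6)
        ran = len(cv.fold_confusions)
        assert ran + len(cv.flagged_folds) == 6
        assert all(c.total == 1 for c in cv.fold_confusions)

    def test_same_seed_same_folds(self, cohort_df):
        cv1 = kfold_cv(cohort_df, lambda tr: train_c45(tr), k=9, seed=4)
        cv2 = kfold_cv(cohort_df, lambda tr: train_c45(tr), k=9, seed=4)
        assert [vars(c) for c in cv1.fold_confusions] == \
            [vars(c) for c in cv2.fold_confusions]

    def test_nine_fold_cohort_accuracy_plausible(self, cohort_df):
        cv = kfold_cv(cohort_df, lambda tr: train_c45(tr), k=9, seed=0)
        assert 0.7 <= cv.report.accuracy <= 1.0

    def test_bad_k_rejected(self, cohort_df):
        with pytest.raises(ValueError):
            kfold_cv(cohort_df, lambda tr: train_c45(tr), k=1)


class TestDescribe:
    def test_cohort_age_column(self, cohort_df):
        d = describe(cohort_df.age)
        assert round(d.mean, 2) == 36.89
        assert d.min == 24 and d.max == 58
        assert round(d.sd, 2) == 8.28
        assert round(d.se, 2) == 1.22      # sd / sqrt(n), as printed

    def test_cohort_angle1_column(self, cohort_df):
        d = describe(cohort_df.angle_1)
        assert round(d.mean, 2) == 79.56
        assert d.min == 38.29 and d.max == 101.89

    def test_constant_column(self):
        d = describe([7.0, 7.0, 7.0])
        assert d.sd == 0.0 and d.se == 0.0 and d.mean == 7.0

    def test_permutation_invariant(self, rng):
        v = rng.normal(0, 1, 20)
        d1, d2 = describe(v), describe(rng.permutation(v))
        assert d1.mean == pytest.approx(d2.mean, rel=1e-12)
        assert d1.sd == pytest.approx(d2.sd, rel=1e-12)
        assert (d1.n, d1.min, d1.max) == (d2.n, d2.min, d2.max)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestCorrelation:
    def test_identity_gives_one(self):
        r = correlation_vs_response([0, 1, 0, 1, 1], [0, 1, 0, 1, 1])
        assert r == pytest.approx(1.0)

    def test_constant_values_flagged(self):
        assert math.isnan(correlation_vs_response([3, 3, 3, 3], [0, 1, 0, 1]))

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert correlation_vs_response(x, y) == pytest.approx(expected)

    def test_pearson_affine_invariance(self, rng):
        x = rng.normal(0, 1, 30)
        y = (x + rng.normal(0, 1, 30) > 0).astype(float)
        r1 = correlation_vs_response(x, y)
        r2 = correlation_vs_response(3.0 * x + 11.0, y)
        assert r1 == pytest.approx(r2)

    def test_spearman_available(self, cohort_df):
        r = correlation_vs_response(cohort_df.angle_1, cohort_df.input_class,
                                    method="spearman")
        assert -1 <= r <= 1


class TestBoxplots:
    def test_all_equal_cell(self):
        s = boxplot_summary([4.0] * 6)
        assert s.IQR == 0 and not s.mild_outliers and not s.extreme_outliers

    def test_extreme_outlier_flagged(self):
        s = boxplot_summary([1, 2, 3, 4, 5, 6, 7, 100])
        assert s.extreme_outliers == [100.0]
        assert not s.mild_outliers

    def test_linear_interpolation_quartiles(self):
        s = boxplot_summary(list(range(1, 9)))
        assert s.Q2 == 4.5
        assert s.Q1 == pytest.approx(2.75) and s.Q3 == pytest.approx(6.25)

    def test_whiskers_at_most_extreme_inliers(self):
        s = boxplot_summary([1, 2, 3, 4, 5, 6, 7, 100])
        assert s.whisker_low == 1.0 and s.whisker_high == 7.0

    def test_band_summaries_cover_cohort_cells(self, cohort):
        out = band_summaries(cohort)
        assert set(out) >= {"age", "angle_1", "contrast"}
        cells = out["angle_1"]
        # band 1 holds the 8 pain-free subjects
        assert cells[(1, NORMAL)].n == 8
        assert sum(c.n for c in cells.values()) == 46
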