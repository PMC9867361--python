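"""Rule set, symbolic sigmoid scorer, and cost-sensitive tree induction."""

import math

import numpy as np
import pandas as pd
import pytest

from cervitex.cohort import ABNORMAL, NORMAL, cohort_frame
from cervitex.classify import (CANDIDATE_PARSES, CervicalPainTree, CostMatrix,
                               classify_gep, classify_rules, entropy, gep_h,
                               gep_y, information_gain, matching_rules,
                               printed_rules, resolve_gep_parse,
                               threshold_candidates, train_c45, usage_category,
                               GEPModel)
from cervitex.evaluate import confusion


class TestUsageCategory:
    @pytest.mark.parametrize("h, cat", [
        (0.5, "1_hours"), (1.0, "1_hours"),
        (1.5, "2_hours"), (2.0, "2_hours"),
        (2.5, "2_to_8_10"), (4.0, "2_to_8_10"), (7.9, "2_to_8_10"),
        (8.0, "8_10_hours"), (9.0, "8_10_hours"),
    ])
    def test_mapping(self, h, cat):
        assert usage_category(h) == cat

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            usage_category(-0.1)


class TestPrintedRules:
    def test_low_usage_is_normal(self, record_factory):
        d = classify_rules(record_factory(h_mean=1.0, age=50))
        assert d.label == NORMAL and d.detail == 1

    def test_heavy_young_user_is_abnormal(self, record_factory):
        d = classify_rules(record_factory(h_mean=9.0, age=25))
        assert d.label == ABNORMAL and d.detail == 3

    def test_high_contrast_over_27_is_abnormal(self, record_factory):
        d = classify_rules(record_factory(h_mean=4.0, age=30, contrast=0.5))
        assert d.label == ABNORMAL and d.detail == 7

    def test_uncovered_record_gets_flagged_default(self, record_factory):
        # heavy user, over 27, low contrast, small angle: no rule fires
        rec = record_factory(h_mean=9.0, age=30, contrast=0.1, angle_1=60.0)
        assert matching_rules(rec, printed_rules()) == []
        d = classify_rules(rec)
        assert d.label == ABNORMAL and d.flagged and d.detail is None

    def test_every_cohort_record_fires_exactly_one_rule(self, cohort):
        rules = printed_rules()
        assert all(len(matching_rules(r, rules)) == 1 for r in cohort)

    def test_single_antecedent_records_return_that_label(self, record_factory):
        # records built to satisfy exactly one rule always get its label
        rules = printed_rules()
        probes = [
            (record_factory(h_mean=0.5, age=40), 1),
            (record_factory(h_mean=2.0, age=40), 2),
            (record_factory(h_mean=8.5, age=20), 3),
            (record_factory(h_mean=5.0, age=20), 4),
            (record_factory(h_mean=5.0, age=40, contrast=0.1, angle_1=60.0), 5),
            (record_factory(h_mean=5.0, age=40, contrast=0.1, angle_1=90.0), 6),
            (record_factory(h_mean=5.0, age=40, contrast=0.9), 7),
        ]
        for rec, idx in probes:
            assert matching_rules(rec, rules) == [idx]
            assert classify_rules(rec, rules).label == rules.rules[idx - 1].label


class TestSigmoidScore:
    def test_midpoint(self):
        assert gep_h(7.28 / 1797.29) == pytest.approx(0.5, abs=1e-12)

    def test_limits_saturate(self):
        assert gep_h(1e6) == 1.0
        assert gep_h(-1e6) == 0.0

    def test_zero_score(self):
        assert gep_h(0.0) == pytest.approx(1 / (1 + math.exp(7.28)), rel=1e-12)

    def test_strictly_monotone(self):
        ys = np.linspace(-0.01, 0.02, 50)
        hs = [gep_h(y) for y in ys]
        assert all(b > a for a, b in zip(hs, hs[1:]))


class TestSymbolicExpression:
    def test_nonpositive_correlation_undefined(self, record_factory):
        assert math.isnan(gep_y(record_factory(correlation=0.0)))

    def test_reference_parse_finite_positive(self, record_factory):
        rec = record_factory(h_mean=2.5, contrast=0.822, homogeneity=0.868,
                             correlation=0.711, energy=0.432)
        y = gep_y(rec, "reference")
        assert math.isfinite(y) and y > 0

    def test_monotone_in_energy(self, record_factory):
        # the expression is linear in energy with a positive denominator
        ys = [gep_y(record_factory(energy=e)) for e in (0.2, 0.4, 0.6)]
        assert ys[0] < ys[1] < ys[2]


class TestParseResolution:
    def test_degenerate_candidate_never_beats_selection(self, cohort):
        res = resolve_gep_parse(cohort)
        assert res.residuals[res.chosen] <= res.residuals["no_denominator"]

    def test_selection_or_fallback(self, cohort):
        res = resolve_gep_parse(cohort)
        assert res.agreements[res.chosen] >= 42 or res.fallback

    def test_deterministic(self, cohort):
        a = resolve_gep_parse(cohort)
        b = resolve_gep_parse(cohort)
        assert a.chosen == b.chosen and a.residuals == b.residuals

    def test_fallback_scores_reproduce_printed_column(self, cohort):
        res = resolve_gep_parse(cohort)
        if res.fallback:
            assert [res.model.score(r) for r in cohort] == \
                [r.gep_h for r in cohort]


class TestClassifyGEP:
    def test_printed_scores_classify(self, cohort):
        model = GEPModel(printed_score_mode=True)
        assert classify_gep(cohort[0], model).label == ABNORMAL    # H = 0.006
        assert classify_gep(cohort[34], model).label == NORMAL     # H = 0.694

    def test_boundary_is_normal(self, record_factory):
        model = GEPModel(printed_score_mode=True)
        assert classify_gep(record_factory(gep_h=0.5), model).label == NORMAL

    def test_undefined_score_conservative(self, record_factory):
        d = classify_gep(record_factory(correlation=-0.1), GEPModel())
        assert d.label == ABNORMAL and d.flagged


class TestEntropy:
    @pytest.mark.parametrize("counts, expected", [
        ((10, 0), 0.0),
        ((1, 1), 1.0),
        ((38, 8), 0.666649),      # cohort class split, bits
    ])
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            entropy((0, 0))


class TestInformationGain:
    def test_class_copy_attribute_gains_parent_entropy(self):
        y = np.array([0, 0, 1, 1, 1, 0])
        masks = [y == 0, y == 1]
        assert information_gain(y, masks) == pytest.approx(entropy((3, 3)))

    def test_independent_attribute_gains_nothing(self):
        y = np.array([0, 1, 0, 1])
        masks = [np.array([True, True, False, False]),
                 np.array([False, False, True, True])]
        assert information_gain(y, masks) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_toy_table(self):
        # 4-row table, threshold split on x at 2.5
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        le = x <= 2.5
        # brute force: H(2,2) - 0.5*H(2,0) - 0.5*H(0,2)
        expected = 1.0 - 0.5 * 0.0 - 0.5 * 0.0
        assert information_gain(y, [le, ~le]) == pytest.approx(expected)


class TestTreeInduction:
    def _toy(self):
        return pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "b": [5.0, 1.0, 4.0, 2.0, 6.0, 3.0],
            "input_class": [0, 0, 0, 1, 1, 1],
        })

    def test_perfect_separator_gives_depth_one_tree(self):
        df = self._toy()
        tree = train_c45(df, features=["a", "b"], min_leaf=1)
        assert tree.leaf_count == 2 and tree.node_count == 3
        preds = [tree.predict(r) for r in df.to_dict("records")]
        assert preds == df.input_class.tolist()

    def test_root_attribute_maximises_information_gain(self, cohort_df):
        features = ["age", "h_mean", "angle_1", "contrast"]
        cm = CostMatrix()
        y = cohort_df.input_class.to_numpy()
        w = cm.instance_weights(y)
        best = (-1.0, None)
        for attr in features:
            col = cohort_df[attr].to_numpy()
            for thr in threshold_candidates(col):
                g = information_gain(y, [col <= thr, col > thr], w)
                if g > best[0]:
                    best = (g, attr)
        tree = train_c45(cohort_df, features=features, cost_matrix=cm, min_leaf=2)
        assert tree.root.attr == best[1]

    def test_single_class_dataset_gives_single_leaf(self):
        df = self._toy().assign(input_class=0)
        tree = train_c45(df, features=["a"])
        assert tree.root.is_leaf and tree.leaf_count == 1

    def test_cost_reweighting_never_hurts_upweighted_recall(self, cohort_df):
        recalls = {}
        for costs in (((0, 1), (1, 0)), ((0, 1), (5, 0))):
            cm = CostMatrix(costs)
            tree = train_c45(cohort_df, cost_matrix=cm)
            preds = [tree.predict(r) for r in cohort_df.to_dict("records")]
            c = confusion(preds, cohort_df.input_class.tolist(),
                          positive_class=NORMAL)
            recalls[costs] = c.TP / (c.TP + c.FN)
        assert recalls[((0, 1), (5, 0))] >= recalls[((0, 1), (1, 0))]

    def test_deterministic_given_dataset_order(self, cohort_df):
        t1 = train_c45(cohort_df)
        t2 = train_c45(cohort_df)
        assert t1.to_json() == t2.to_json()

    def test_tree_rules_round_trip(self, cohort):
        # replaying the induced rules through the rule machinery
        # reproduces the tree's own predictions exactly
        tree = train_c45(cohort)
        ruleset = tree.to_ruleset()
        for rec in cohort:
            assert classify_rules(rec, ruleset).label == tree.predict(rec)

    def test_cost_matrix_validation(self):
        with pytest.raises(ValueError):
            CostMatrix(((1, 1), (5, 0)))
        with pytest.raises(ValueError):
            CostMatrix(((0, -1), (5, 0)))

    def test_upweighted_class_is_minority_normal(self):
        assert CostMatrix().upweighted_class == NORMAL


class TestModelResults:
    def test_fit_and_summary(self, cohort):
        res = CervicalPainTree(cohort).fit()
        text = res.summary()
        assert "Cost-sensitive decision tree" in text
        assert "nodes:" in text and "IF " in text

    def test_split_fit_reports_test_confusion(self, cohort):
        res = CervicalPainTree(cohort).fit(train_fraction=2 / 3, seed=0)
        assert res.test is not None and len(res.test) == 16
        assert "test" in res.summary()
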