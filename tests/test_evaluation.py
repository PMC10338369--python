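"""Precision-recall machinery, AUCPR_adj and curve averaging."""

import numpy as np
import pytest

import sirnaforest as sf
from sirnaforest.evaluation import (
    MetricError,
    RECALL_GRID,
    UndefinedMetricError,
    curve_frame,
)

Y4 = np.array([1, 0, 1, 0])
S4 = np.array([0.9, 0.8, 0.7, 0.6])


class TestContingencyTable:
    def test_direct_count(self):
        t = sf.contingency_table([1, 1, 0, 0], [1, 0, 1, 0])
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        t = sf.contingency_table([1, 0, 1], [1, 0, 1])
        assert t.fp == 0 and t.fn == 0

    def test_cells_partition_n(self):
        rng = np.random.default_rng(0)
        y, p = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert sf.contingency_table(y, p).n == 50


class TestPRCurve:
    def test_known_points_of_four_score_example(self):
        curve = sf.precision_recall_curve(Y4, S4)
        pts = set(zip(np.round(curve.recalls, 10), np.round(curve.precisions, 10)))
        assert (0.5, 1.0) in pts
        assert (1.0, round(2 / 3, 10)) in pts
        assert curve.recalls[-1] == 1.0

    def test_perfect_ranking_touches_precision_one_at_full_recall(self):
        curve = sf.precision_recall_curve([1, 1, 0], [0.9, 0.8, 0.1])
        pts = set(zip(curve.recalls, curve.precisions))
        assert (1.0, 1.0) in pts

    def test_all_equal_scores_single_informative_point(self):
        curve = sf.precision_recall_curve([1, 0, 0, 1], [0.3] * 4)
        # prepended zero-positive endpoint plus one real point
        assert curve.margins.size == 2
        assert curve.recalls[-1] == 1.0
        assert curve.precisions[-1] == 0.5

    def test_recalls_non_decreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(3, 25)
            y = rng.integers(0, 2, n)
            y[0] = 1
            curve = sf.precision_recall_curve(y, rng.random(n))
            assert np.all(np.diff(curve.recalls) >= 0)

    def test_no_positives_rejected(self):
        with pytest.raises(UndefinedMetricError):
            sf.precision_recall_curve([0, 0], [0.1, 0.2])

    def test_margin_point_matches_contingency(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.round(rng.random(n), 2)
            curve = sf.precision_recall_curve(y, s)
            t = sf.contingency_table(y, sf.classify(s, 0.5))
            recall, precision = curve.point_at_margin(0.5)
            if t.tp + t.fp == 0:
                assert (recall, precision) == (0.0, 1.0)
            else:
                assert recall == pytest.approx(t.tp / (t.tp + t.fn))
                assert precision == pytest.approx(t.tp / (t.tp + t.fp))


class TestAUCPR:
    def test_flat_curve_is_rectangle(self):
        # all-equal scores yield the flat no-skill curve at prevalence
        curve = sf.precision_recall_curve([1, 0, 0, 1], [0.3] * 4)
        assert sf.aucpr(curve) == pytest.approx(0.5)

    def test_perfect_ranker_reaches_one(self):
        curve = sf.precision_recall_curve([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert sf.aucpr(curve) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, pr_oracle):
        curve = sf.precision_recall_curve(Y4, S4)
        assert sf.aucpr(curve) == pytest.approx(pr_oracle(Y4, S4)["aucpr"], abs=1e-12)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            y = rng.integers(0, 2, n)
            y[0] = 1
            s = np.round(rng.random(n), 2)
            curve = sf.precision_recall_curve(y, s)
            assert sf.aucpr(curve) == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )


class TestAdjustedMetric:
    def test_prevalence_examples(self):
        assert sf.p_at_full_recall([1] * 25 + [0] * 75) == 0.25
        assert sf.p_at_full_recall([1, 1]) == 1.0
        assert sf.p_at_full_recall([1, 0]) == 0.5

    def test_no_discrimination_scores_give_exact_zero(self):
        y = [1, 0, 0, 1, 0]
        curve = sf.precision_recall_curve(y, [0.4] * 5)
        assert sf.aucpr_adj(curve, y) == 0.0

    def test_perfect_ranker_at_quarter_prevalence(self):
        y = [1] + [0] * 3
        curve = sf.precision_recall_curve(y, [0.9, 0.3, 0.2, 0.1])
        assert sf.aucpr_adj(curve, y) == pytest.approx(0.75)

    def test_equals_subtraction_of_terms(self, pr_oracle):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            y = rng.integers(0, 2, n)
            y[0] = 1
            s = rng.random(n)
            curve = sf.precision_recall_curve(y, s)
            assert sf.aucpr_adj(curve, y) == pytest.approx(
                sf.aucpr(curve) - sf.p_at_full_recall(y), abs=1e-15
            )
            assert sf.aucpr_adj(curve, y) == pytest.approx(
                pr_oracle(y, s)["aucpr_adj"], abs=1e-12
            )

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 25)
        y[0] = 1
        s = rng.random(25)
        base = sf.aucpr_adj(sf.precision_recall_curve(y, s), y)
        for f in (lambda v: v**3, np.exp, lambda v: 5 * v - 2):
            assert sf.aucpr_adj(sf.precision_recall_curve(y, f(s)), y) == pytest.approx(
                base, abs=1e-12
            )

    def test_invariant_under_record_permutation(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 30)
        y[0] = 1
        s = rng.random(30)
        perm = rng.permutation(30)
        a = sf.evaluate_predictions(y, s)
        b = sf.evaluate_predictions(y[perm], s[perm])
        for attr in ("aucpr", "p_r1", "aucpr_adj", "roc_auc"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-12)
        assert a.table == b.table


class TestROC:
    def test_examples(self, roc_oracle):
        assert sf.roc_auc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0
        assert sf.roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5
        assert sf.roc_auc(Y4, S4) == pytest.approx(0.75)
        assert sf.roc_auc(Y4, S4) == pytest.approx(roc_oracle(Y4, S4), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sf.roc_auc([1, 1], [0.2, 0.3])


class TestNormalizeScores:
    def test_examples(self):
        assert list(sf.normalize_scores([0.1, 0.5, 0.9])) == [0.0, 50.0, 100.0]
        assert list(sf.normalize_scores([-0.2, 0.8])) == [0.0, 100.0]
        assert list(sf.normalize_scores([0.3, 0.3, 0.3])) == [0.0, 0.0, 0.0]


class TestAveragePRCurves:
    def test_identical_curves_average_to_themselves(self):
        curve = sf.precision_recall_curve(Y4, S4)
        avg = sf.average_pr_curves([curve] * 5)
        single = sf.average_pr_curves([curve])
        assert np.allclose(avg.precisions, single.precisions)

    def test_two_flat_curves_average_midway(self):
        a = sf.precision_recall_curve([1, 0, 0, 1, 0], [0.3] * 5)  # flat at 0.4
        b = sf.precision_recall_curve([1, 1, 0, 1, 0], [0.3] * 5)  # flat at 0.6
        avg = sf.average_pr_curves([a, b])
        assert np.allclose(avg.precisions[1:], 0.5)  # grid point 0 is the (0,1) endpoint

    def test_output_on_shared_grid(self):
        curve = sf.precision_recall_curve(Y4, S4)
        avg = sf.average_pr_curves([curve])
        assert np.array_equal(avg.recalls, RECALL_GRID)

    def test_empty_input_rejected(self):
        with pytest.raises(MetricError):
            sf.average_pr_curves([])


def test_curve_frame_columns():
    frame = curve_frame(sf.precision_recall_curve(Y4, S4))
    assert list(frame.columns) == ["margin", "recall", "precision"]
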