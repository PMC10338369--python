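"""Proxy feature-weight extraction, normalization and the AU-GC trend."""

import numpy as np
import pytest

import sirnaforest as sf
from sirnaforest.attribution import (
    SIGN_CONVENTIONS,
    WeightMatrix,
    trend_frame,
)
from sirnaforest.classifiers import FamilyError


def groups_of(**kwargs):
    g = {"TP": [], "TN": [], "FP": [], "FN": []}
    g.update(kwargs)
    return g


class TestClassificationGroups:
    def test_partition_and_perfect_model(self):
        X = sf.encode_sequences(["A" * 20, "A" * 20, "U" * 20, "U" * 20])
        y = np.array([1, 1, 0, 0])
        model = sf.train_linear_freqdiff(X, y)
        groups = sf.classification_groups(model, X, y)
        assert groups["FP"].size == 0 and groups["FN"].size == 0
        sizes = sum(v.size for v in groups.values())
        assert sizes == 4

    def test_all_positive_predictions(self):
        X = sf.encode_sequences(["A" * 20, "C" * 20, "G" * 20, "U" * 20])
        y = np.array([1, 1, 0, 0])

        class AlwaysPositive(sf.TrainedClassifier):
            def predict_confidence(self, X):
                return np.ones(len(np.atleast_2d(X)))

        groups = sf.classification_groups(AlwaysPositive(family="forest"), X, y)
        assert groups["FP"].size == 2 and groups["FN"].size == 0
        assert groups["TP"].size == 2 and groups["TN"].size == 0


class TestProxyFeatureWeights:
    def test_class_signs_poly_a_tp_poly_u_tn(self):
        X = sf.encode_sequences(["A" * 20, "U" * 20])
        w = sf.proxy_feature_weights(groups_of(TP=[0], TN=[1]), X).values
        assert np.all(w[:, 0] == 1) and np.all(w[:, 1] == -1)
        assert np.all(w[:, 2:] == 0)

    def test_correctness_variant_matches_literal_sum(self):
        X = sf.encode_sequences(["A" * 20, "U" * 20])
        w = sf.proxy_feature_weights(
            groups_of(TP=[0], TN=[1]), X, convention="correctness"
        ).values
        assert np.all(w[:, 0] == 1) and np.all(w[:, 1] == 1)

    @pytest.mark.parametrize("convention", list(SIGN_CONVENTIONS))
    def test_lone_false_positive_negated(self, convention):
        X = sf.encode_sequences(["G" * 20])
        w = sf.proxy_feature_weights(groups_of(FP=[0]), X, convention=convention).values
        assert np.all(w[:, 3] == -1)
        assert np.all(w[:, :3] == 0)

    def test_empty_group_contributes_zero_not_error(self):
        X = sf.encode_sequences(["A" * 20, "C" * 20])
        w = sf.proxy_feature_weights(groups_of(TP=[0, 1]), X).values
        assert np.all(w[:, 0] == 0.5) and np.all(w[:, 2] == 0.5)

    def test_all_empty_rejected(self):
        X = sf.encode_sequences(["A" * 20])
        with pytest.raises(ValueError):
            sf.proxy_feature_weights(groups_of(), X)

    def test_unknown_convention_rejected(self):
        X = sf.encode_sequences(["A" * 20])
        with pytest.raises(ValueError):
            sf.proxy_feature_weights(groups_of(TP=[0]), X, convention="bogus")

    def test_error_free_model_reduces_to_group_mean_difference(self, seq_factory):
        """With empty FP/FN the proxy collapses to the class-mean contrast."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            n_tp, n_tn = rng.integers(1, 8, 2)
            X = sf.encode_sequences(seq_factory(rng, int(n_tp + n_tn)))
            groups = groups_of(TP=list(range(n_tp)), TN=list(range(n_tp, n_tp + n_tn)))
            # hand-written oracle: plain means over the two groups
            mean_tp = X[: n_tp].mean(axis=0).reshape(20, 4)
            mean_tn = X[n_tp:].mean(axis=0).reshape(20, 4)
            w_class = sf.proxy_feature_weights(groups, X).values
            assert np.allclose(w_class, mean_tp - mean_tn, atol=1e-12)
            w_corr = sf.proxy_feature_weights(groups, X, convention="correctness").values
            assert np.allclose(w_corr, mean_tp + mean_tn, atol=1e-12)


class TestNormalizeWeightMatrix:
    def test_scales_peak_to_100(self):
        raw = np.zeros((20, 4))
        raw[0, 0] = 0.5
        raw[1, 1] = -0.25
        norm = sf.normalize_weight_matrix(WeightMatrix(raw)).values
        assert norm[0, 0] == 100.0
        assert norm[1, 1] == -50.0

    def test_zero_band_applied_after_scaling(self):
        raw = np.zeros((20, 4))
        raw[0, :3] = [0.5, -1.0, 0.1]  # scaled to 50, -100, 10
        norm = sf.normalize_weight_matrix(WeightMatrix(raw)).values
        assert list(norm[0, :3]) == [50.0, -100.0, 0.0]

    def test_all_zero_matrix_unchanged(self):
        norm = sf.normalize_weight_matrix(WeightMatrix(np.zeros((20, 4))))
        assert norm.normalized and np.all(norm.values == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            w = WeightMatrix(rng.normal(size=(20, 4)))
            once = sf.normalize_weight_matrix(w)
            twice = sf.normalize_weight_matrix(once)
            assert np.allclose(once.values, twice.values)

    def test_band_invariant_holds(self):
        rng = np.random.default_rng(12)
        norm = sf.normalize_weight_matrix(WeightMatrix(rng.normal(size=(20, 4))))
        mags = np.abs(norm.values)
        assert not np.any((mags > 0) & (mags < 20))
        assert mags.max() <= 100

    def test_non_finite_rejected(self):
        raw = np.zeros((20, 4))
        raw[0, 0] = np.nan
        with pytest.raises(ValueError):
            sf.normalize_weight_matrix(WeightMatrix(raw))


class TestDirectLinearWeights:
    def test_poly_a_vs_poly_u_model(self):
        X = sf.encode_sequences(["A" * 20, "U" * 20])
        model = sf.train_linear_freqdiff(X, np.array([1, 0]))
        w = sf.direct_linear_weights(model).values
        assert np.all(w[:, 0] == 100) and np.all(w[:, 1] == -100)
        assert np.all(w[:, 2:] == 0)

    def test_zero_weight_model_gives_zero_matrix(self):
        X = sf.encode_sequences(["AUCG" * 5, "AUCG" * 5])
        model = sf.train_linear_freqdiff(X, np.array([1, 0]))
        assert np.all(sf.direct_linear_weights(model).values == 0)

    def test_forest_rejected(self, seq_factory):
        rng = np.random.default_rng(13)
        X = sf.encode_sequences(seq_factory(rng, 10))
        model = sf.train_random_forest(X, np.array([0, 1] * 5), sf.ForestConfig(seed=0))
        with pytest.raises(FamilyError):
            sf.direct_linear_weights(model)


class TestAUGCTrend:
    def test_printed_position_example(self):
        # a position with A=64, U=-100, C=94, G=0 has trend (64-100)-(0+94)
        raw = np.zeros((20, 4))
        raw[17] = [64.0, -100.0, 94.0, 0.0]  # columns A, U, C, G
        trend = sf.au_gc_trend(WeightMatrix(raw))
        assert trend[17] == pytest.approx(-130.0)
        assert trend[0] == 0.0

    def test_symmetric_weights_cancel(self):
        raw = np.full((20, 4), 7.5)
        assert np.allclose(sf.au_gc_trend(WeightMatrix(raw)), 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(14)
        w1, w2 = rng.normal(size=(2, 20, 4))
        a, b = 2.5, -1.25
        combo = sf.au_gc_trend(WeightMatrix(a * w1 + b * w2))
        parts = a * sf.au_gc_trend(WeightMatrix(w1)) + b * sf.au_gc_trend(WeightMatrix(w2))
        assert np.allclose(combo, parts)


def test_weight_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(15)
    w = sf.normalize_weight_matrix(WeightMatrix(rng.normal(size=(20, 4))))
    path = tmp_path / "weights.tsv"
    w.to_tsv(path)
    back = WeightMatrix.from_tsv(path, normalized=True)
    assert np.allclose(back.values, w.values)


def test_trend_frame_has_position_labels():
    frame = trend_frame(np.arange(20.0))
    assert frame["position"].iloc[0] == "t1"
    assert frame["position"].iloc[-1] == "t20"
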