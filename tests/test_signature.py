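import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsig import (
    SignatureModel,
    calibrate_threshold,
    classify,
    published_signature,
    score_samples,
    train_svm_rfe,
)

from .oracles import accuracy_at_threshold

MARKERS = ("hsa-let-7e-5p", "hsa-miR-106a-5p", "hsa-miR-28-3p", "hsa-miR-542-5p")


def _expr(values_by_sample):
    return pd.DataFrame(values_by_sample, index=list(MARKERS))


class TestPublishedModels:
    @pytest.mark.parametrize(
        "scale, weights, threshold",
        [
            ("tlda", (1.037, 0.9, 0.247, 0.903), 1.024),
            ("single_assay", (1.037, 0.9, 0.247, 0.903), 2.442),
            ("external_equal_weight", (1.0, 1.0, 1.0, 1.0), 19.14),
        ],
    )
    def test_constants(self, scale, weights, threshold):
        model = published_signature(scale)
        assert model.weights == weights
        assert model.threshold == threshold
        assert model.markers == MARKERS

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="unknown scale"):
            published_signature("tissue")

    def test_models_immutable(self):
        model = published_signature("tlda")
        with pytest.raises(dataclasses.FrozenInstanceError):
            model.threshold = 0.0

    def test_json_roundtrip(self, tmp_path):
        model = published_signature("single_assay")
        path = tmp_path / "model.json"
        model.to_json(path)
        assert SignatureModel.from_json(path) == model


class TestScoring:
    def test_zero_inputs_score_zero(self):
        scores = score_samples(_expr({"s1": [0.0] * 4}), published_signature("tlda"))
        assert scores["s1"] == 0.0

    def test_unit_inputs_sum_the_weights(self):
        scores = score_samples(_expr({"s1": [1.0] * 4}), published_signature("tlda"))
        assert scores["s1"] == pytest.approx(3.087)

    def test_single_marker_crosses_tlda_threshold(self):
        model = published_signature("tlda")
        scores = score_samples(_expr({"s1": [1.0, 0.0, 0.0, 0.0]}), model)
        assert scores["s1"] == pytest.approx(1.037)
        assert classify(scores, model)["s1"]  # 1.037 > 1.024

    def test_marker_matching_tolerates_case_and_prefix(self):
        expr = pd.DataFrame({"s1": [1.0, 1.0, 1.0, 1.0]},
                            index=["let-7e-5p", "MIR-106A-5P", "hsa-mir-28-3p",
                                   "miR-542-5p"])
        scores = score_samples(expr, published_signature("tlda"))
        assert scores["s1"] == pytest.approx(3.087)

    def test_missing_marker_listed_in_error(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["hsa-let-7e-5p"])
        with pytest.raises(ValueError, match="miR-106a-5p"):
            score_samples(expr, published_signature("tlda"))

    @given(st.floats(-5, 5), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_score_is_linear(self, alpha, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        y = rng.normal(size=(4, 3))
        model = published_signature("tlda")
        sx = score_samples(_expr(dict(zip("abc", x.T))), model)
        sy = score_samples(_expr(dict(zip("abc", y.T))), model)
        s_sum = score_samples(_expr(dict(zip("abc", (alpha * x + y).T))), model)
        assert np.allclose(s_sum, alpha * sx + sy, atol=1e-9)


class TestClassify:
    @pytest.mark.parametrize("scale", ["tlda", "single_assay", "external_equal_weight"])
    def test_strict_inequality_at_threshold(self, scale):
        model = published_signature(scale)
        t = model.threshold
        pred = classify([t, t + 1e-9, t - 1e-9], model)
        assert pred.tolist() == [False, True, False]

    def test_empty_scores_give_empty_predictions(self):
        assert classify([], published_signature("tlda")).tolist() == []


class TestCalibrateThreshold:
    def test_separable_toy(self):
        t = calibrate_threshold([3.0, 4.0, 1.0, 2.0], [True, True, False, False])
        assert t == pytest.approx(2.5)

    def test_interleaved_scores_fall_back_to_majority(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        labels = [True, False, True, False, True, False]
        t = calibrate_threshold(scores, labels)
        acc = accuracy_at_threshold(scores, labels, t)
        # a brute-force scan over every cut cannot beat chance plus one point
        best = max(accuracy_at_threshold(scores, labels, c)
                   for c in np.linspace(0, 7, 141))
        assert acc == pytest.approx(best)

    def test_all_equal_scores_predict_all_negative(self):
        t = calibrate_threshold([2.0, 2.0, 2.0], [True, False, False])
        assert not (np.array([2.0, 2.0, 2.0]) > t).any()

    @pytest.mark.parametrize("seed", range(5))
    def test_chosen_threshold_is_globally_optimal(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        t = calibrate_threshold(scores, labels)
        acc = accuracy_at_threshold(scores, labels, t)
        for c in np.concatenate([scores - 1e-9, scores + 1e-9, [scores.min() - 1]]):
            assert accuracy_at_threshold(scores, labels, c) <= acc + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            calibrate_threshold([1.0, 2.0], [True, True])


class TestSvmRfe:
    def _planted(self, rng, n=40, n_noise=4, sep=3.0):
        labels = np.array([True] * (n // 2) + [False] * (n // 2))
        informative = rng.normal(size=(2, n)) + sep * labels
        noise = rng.normal(size=(n_noise, n))
        expr = pd.DataFrame(np.vstack([informative, noise]),
                            index=[f"info-{i}" for i in range(2)]
                            + [f"noise-{i}" for i in range(n_noise)])
        return expr, labels

    def test_perfect_single_feature_scores_loocv_one(self):
        labels = np.array([True] * 6 + [False] * 6)
        expr = pd.DataFrame(
            [np.where(labels, 5.0, -5.0) + np.linspace(0, 0.1, 12)], index=["hero"]
        )
        result = train_svm_rfe(expr, labels, ["hero"], sizes=[1])
        assert result.loocv_accuracy[1] == 1.0

    def test_informative_features_survive_elimination(self):
        rng = np.random.default_rng(0)
        expr, labels = self._planted(rng)
        result = train_svm_rfe(expr, labels, list(expr.index), sizes=range(2, 7))
        for k in range(2, 7):
            assert {"info-0", "info-1"} <= set(result.markers_by_size[k])
            assert result.loocv_accuracy[k] >= 0.95

    def test_sizes_nested_and_accuracies_in_unit_interval(self):
        rng = np.random.default_rng(1)
        expr, labels = self._planted(rng, n=20)
        result = train_svm_rfe(expr, labels, list(expr.index), sizes=range(1, 7))
        for k in range(1, 6):
            assert set(result.markers_by_size[k]) < set(result.markers_by_size[k + 1])
        for k in result.sizes:
            assert 0.0 <= result.loocv_accuracy[k] <= 1.0
            assert 0.0 <= result.apparent_accuracy[k] <= 1.0

    def test_single_class_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 8)))
        with pytest.raises(ValueError, match="classes"):
            train_svm_rfe(expr, np.ones(8, dtype=bool), list(expr.index), sizes=[1])
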