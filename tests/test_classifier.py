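import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumibolus.classifier import (
    MetricsReport,
    TrainedModel,
    evaluate,
    kfold_validate,
    predict,
    predict_table,
    split_balanced,
    train,
)
from rumibolus.errors import InsufficientClassError, ValidationError


def cluster_table(n_rum=100, n_non=100, seed=0, rum=(45.0, -9.9), non=(25.0, -7.8),
                  spread=(2.0, 0.2)):
    """Two Gaussian clusters in (mean_ici, log_jvb) at the observed geometry."""
    rng = np.random.default_rng(seed)
    rows = []
    for n, (ici, jvb), lab in ((n_rum, rum, "rumination"), (n_non, non, "non_rumination")):
        for _ in range(n):
            rows.append(
                (0.0, rng.normal(ici, spread[0]), 0.0, rng.normal(jvb, spread[1]), lab)
            )
    df = pd.DataFrame(rows, columns=["block_start", "mean_ici", "mean_jvb", "log_jvb", "label"])
    df["mean_jvb"] = np.exp(df.log_jvb)
    return df


class TestSplit:
    def test_balanced_80_20_arithmetic(self):
        train_t, test_t = split_balanced(cluster_table(100, 100), seed=0)
        assert len(train_t) == 160 and len(test_t) == 40
        assert (train_t.label == "rumination").sum() == 80
        assert (test_t.label == "rumination").sum() == 20

    def test_majority_subsampled_before_split(self):
        train_t, test_t = split_balanced(cluster_table(150, 100), seed=0)
        assert len(train_t) + len(test_t) == 200
        assert (train_t.label == "rumination").sum() == 80

    def test_deterministic_given_seed(self):
        t = cluster_table()
        a1, b1 = split_balanced(t, seed=7)
        a2, b2 = split_balanced(t, seed=7)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        a3, _ = split_balanced(t, seed=8)
        assert not a1.equals(a3)

    def test_tiny_class_rejected(self):
        with pytest.raises(InsufficientClassError):
            split_balanced(cluster_table(4, 100), seed=0)


class TestTrainPredict:
    def test_separable_clouds_fit_perfectly(self):
        t = cluster_table()
        model = train(t)
        pred = predict_table(model, t)
        assert (pred == t.label.to_numpy()).all()

    def test_single_class_rejected(self):
        t = cluster_table(n_non=0)
        with pytest.raises(InsufficientClassError):
            train(t)

    def test_duplication_leaves_boundary_unchanged(self):
        t = cluster_table(50, 50)
        doubled = pd.concat([t, t], ignore_index=True)
        m1, m2 = train(t), train(doubled)
        assert m1.boundary_slope() == pytest.approx(m2.boundary_slope(), rel=1e-6)
        np.testing.assert_allclose(m1.weights, m2.weights, rtol=1e-6)

    def test_centroids_classified_as_own_class(self):
        model = train(cluster_table())
        assert predict(model, [[45.0, -9.9]])[0] == "rumination"
        assert predict(model, [[25.0, -7.8]])[0] == "non_rumination"

    def test_boundary_separates_cluster_centroids(self):
        for seed in range(10):
            model = train(cluster_table(seed=seed))
            d = model.decision(np.array([[45.0, -9.9], [25.0, -7.8]]))
            assert d[0] > 0 > d[1]

    def test_prediction_matches_explicit_affine_sign(self):
        model = train(cluster_table())
        rng = np.random.default_rng(3)
        X = np.c_[rng.uniform(15, 55, 50), rng.uniform(-11, -7, 50)]
        d = ((X - model.center) / model.scale) @ model.weights + model.bias
        np.testing.assert_array_equal(
            predict(model, X), np.where(d >= 0, "rumination", "non_rumination")
        )

    def test_boundary_tie_goes_to_rumination(self):
        model = TrainedModel(
            weights=np.array([1.0, 0.0]), bias=0.0,
            center=np.array([30.0, -9.0]), scale=np.array([1.0, 1.0]),
        )
        assert predict(model, [[30.0, -9.0]])[0] == "rumination"

    def test_persistence_roundtrip(self, tmp_path):
        model = train(cluster_table(), seed=5)
        path = tmp_path / "model.txt"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        np.testing.assert_array_equal(back.center, model.center)
        assert back.seed == 5


class TestMetrics:
    def test_all_correct_gives_ones(self):
        y = ["rumination"] * 3 + ["non_rumination"] * 4
        m = evaluate(y, y)
        for v in (m.precision, m.recall, m.specificity, m.npv, m.f1):
            assert v == pytest.approx(1.0)

    def test_zero_denominator_reported_missing(self):
        m = MetricsReport(tp=0, fp=0, fn=3, tn=5)
        assert m.precision is None
        assert m.recall == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [])

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 50) for _ in range(4)]))
    def test_f1_identity_and_label_swap_symmetry(self, counts):
        tp, fp, fn, tn = counts
        m = MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)
        if m.f1 is not None:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))
        # swapping the positive class swaps precision<->npv, recall<->specificity
        swapped = MetricsReport(tp=tn, fp=fn, fn=fp, tn=tp)
        assert swapped.precision == m.npv
        assert swapped.recall == m.specificity
        assert swapped.npv == m.precision
        assert swapped.specificity == m.recall

    def test_confusion_counts_sum_to_total(self):
        t = cluster_table(30, 30)
        model = train(t)
        m = evaluate(predict_table(model, t), t.label.to_numpy())
        assert m.total == len(t)


class TestKFold:
    def test_folds_partition_the_data(self):
        t = cluster_table(30, 30)
        report = kfold_validate(t, k=5, seed=0)
        assert len(report.f1) == 5

    def test_leave_one_out_limit(self):
        t = cluster_table(6, 6, spread=(0.5, 0.05))
        report = kfold_validate(t, k=6, seed=0)
        assert len(report.f1) == 6

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(InsufficientClassError):
            kfold_validate(cluster_table(8, 8), k=10, seed=0)

    def test_separable_data_has_stable_folds(self):
        """On well-separated clusters the fold F1s barely vary and the
        boundary orientation is consistent across folds."""
        for seed in range(10):
            t = cluster_table(60, 60, seed=seed)
            report = kfold_validate(t, k=10, seed=seed)
            assert report.f1_variance < 0.01
            slopes = np.abs(np.array(report.slopes))
            assert slopes.std() / slopes.mean() < 0.2


class TestPublishedConfusionTable:
    """Metric formulas applied to the published confusion fractions."""

    m = MetricsReport(tp=34.3, fp=6.9, fn=4.2, tn=54.6)

    def test_precision(self):
        assert self.m.precision == pytest.approx(0.832, abs=1e-3)

    def test_f1(self):
        assert round(self.m.f1, 3) == 0.861

    def test_total_is_hundred_percent(self):
        assert self.m.total == pytest.approx(100.0)
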