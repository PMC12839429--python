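import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hfsof.eval_metrics import (
    ConfusionMatrix,
    aggregate,
    confusion,
    evaluate_classifier,
    fit_final_svm,
    macro_f1_from_predictions,
    ovr_auc,
    per_class_metrics,
    predict_with_scores,
)

# per-class recalls (%), precisions (%) and supports of the reference
# 6-class study, used for aggregation-consistency checks
REFERENCE_RECALLS = np.array([85.0, 70.0, 49.0, 77.0, 78.0, 98.0]) / 100.0
REFERENCE_SUPPORTS = np.array([355, 198, 71, 418, 223, 1039])


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = confusion(y, y, 3)
        assert np.all(cm.counts == np.diag([2, 2, 1]))
        np.testing.assert_array_equal(cm.supports, [2, 2, 1])

    def test_indexing_convention(self):
        cm = confusion(np.array([0]), np.array([1]), 2)
        assert cm.counts[0, 1] == 1
        assert cm.total == 1

    def test_total_conservation(self, rng):
        y_true = rng.integers(0, 4, size=100)
        y_pred = rng.integers(0, 4, size=100)
        assert confusion(y_true, y_pred, 4).total == 100

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 5]), np.array([0, 1]), 2)


class TestPerClassMetrics:
    def test_worked_example(self):
        cm = ConfusionMatrix(counts=np.array([[8, 2], [1, 9]]))
        p, r, f1 = per_class_metrics(cm)
        assert p[0] == pytest.approx(8.0 / 9.0)
        assert r[0] == pytest.approx(0.8)
        assert f1[0] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))

    def test_never_predicted_class(self):
        cm = ConfusionMatrix(counts=np.array([[0, 3], [0, 5]]))
        p, r, f1 = per_class_metrics(cm)
        assert p[0] == 0.0 and r[0] == 0.0 and f1[0] == 0.0

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(counts=np.diag([4, 6, 2]))
        p, r, f1 = per_class_metrics(cm)
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(r, 1.0)
        np.testing.assert_allclose(f1, 1.0)

    def test_f1_between_min_and_max(self, rng):
        counts = rng.integers(0, 20, size=(4, 4))
        counts[np.diag_indices(4)] += 1
        p, r, f1 = per_class_metrics(ConfusionMatrix(counts=counts))
        assert np.all(f1 >= np.minimum(p, r) - 1e-12)
        assert np.all(f1 <= np.maximum(p, r) + 1e-12)


class TestAggregate:
    def test_reference_macro_recall(self):
        macro, _ = aggregate(REFERENCE_RECALLS, REFERENCE_SUPPORTS)
        assert macro * 100 == pytest.approx(76.1667, abs=1e-3)
        # consistent with the study's printed macro recall of 76.05%
        assert abs(macro * 100 - 76.05) < 0.5

    def test_reference_weighted_recall(self):
        _, weighted = aggregate(REFERENCE_RECALLS, REFERENCE_SUPPORTS)
        assert weighted * 100 == pytest.approx(86.3351, abs=1e-3)
        # consistent with the study's printed weighted recall of 86.20%
        assert abs(weighted * 100 - 86.20) < 0.5

    def test_equal_supports_collapse(self, rng):
        values = rng.uniform(size=5)
        macro, weighted = aggregate(values, np.full(5, 7))
        assert macro == pytest.approx(weighted)

    def test_naive_loop_oracle(self, rng):
        values = rng.uniform(size=6)
        supports = rng.integers(1, 50, size=6)
        macro, weighted = aggregate(values, supports)
        assert macro == pytest.approx(sum(values) / 6)
        assert weighted == pytest.approx(
            sum(v * n for v, n in zip(values, supports)) / supports.sum()
        )

    @given(
        arrays(np.int64, (5, 5), elements=st.integers(0, 50)).filter(
            lambda m: m.sum(axis=1).min() > 0
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_weighted_recall_equals_accuracy(self, counts):
        cm = ConfusionMatrix(counts=counts)
        _, recall, _ = per_class_metrics(cm)
        _, weighted_recall = aggregate(recall, cm.supports)
        accuracy = np.trace(cm.counts) / cm.total
        assert weighted_recall == pytest.approx(accuracy, abs=1e-12)


def mann_whitney_auc(labels, scores):
    """Brute-force pairwise-comparison oracle for binary AUC."""
    pos = [s for lab, s in zip(labels, scores) if lab == 1]
    neg = [s for lab, s in zip(labels, scores) if lab == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestOvrAuc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.full((6, 3), -1.0)
        scores[np.arange(6), y] = 1.0
        aucs, macro, weighted = ovr_auc(y, scores)
        np.testing.assert_allclose(aucs, 1.0)
        assert macro == pytest.approx(1.0)
        assert weighted == pytest.approx(1.0)

    def test_matches_mann_whitney_oracle(self, rng):
        y = rng.integers(0, 3, size=30)
        y[:3] = [0, 1, 2]
        scores = rng.normal(size=(30, 3))
        aucs, _, _ = ovr_auc(y, scores)
        for c in range(3):
            oracle = mann_whitney_auc((y == c).astype(int), scores[:, c])
            assert aucs[c] == pytest.approx(oracle, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        # permutation simulation: mean AUC over many trials concentrates at 0.5
        n = 60
        vals = []
        for _ in range(200):
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
            aucs, _, _ = ovr_auc(y, scores)
            vals.append(aucs[0])
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        scores = rng.normal(size=(40, 2))
        a1, _, _ = ovr_auc(y, scores)
        a2, _, _ = ovr_auc(y, np.exp(3.0 * scores) + 5.0)
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_absent_class_excluded(self, rng):
        y = np.array([0, 0, 1, 1])
        scores = rng.normal(size=(4, 3))
        aucs, macro, _ = ovr_auc(y, scores)
        assert np.isnan(aucs[2])
        assert np.isfinite(macro)


class TestSvm:
    def test_separable_two_class_zero_errors(self, two_class_dataset):
        ds = two_class_dataset
        clf = fit_final_svm(ds.X, ds.y)
        y_pred, scores = predict_with_scores(clf, ds.X)
        assert np.all(y_pred == ds.y)
        assert scores.shape == (ds.n_samples, 2)

    def test_prediction_is_argmax_of_scores(self, planted_small):
        ds, _ = planted_small
        clf = fit_final_svm(ds.X, ds.y)
        y_pred, scores = predict_with_scores(clf, ds.X)
        np.testing.assert_array_equal(y_pred, np.argmax(scores, axis=1))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_final_svm(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_full_report(self, two_class_dataset):
        ds = two_class_dataset
        clf = fit_final_svm(ds.X, ds.y)
        report = evaluate_classifier(clf, ds.X, ds.y, 2, ds.class_names)
        assert report.accuracy == pytest.approx(1.0)
        assert report.macro["f1"] == pytest.approx(1.0)
        assert report.weighted["recall"] == pytest.approx(report.accuracy)
        payload = report.to_dict()
        assert set(payload) == {"accuracy", "per_class", "macro", "weighted"}
        assert len(payload["per_class"]) == 2

    def test_macro_f1_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        y_true = rng.integers(0, 4, size=100)
        y_pred = rng.integers(0, 4, size=100)
        ours = macro_f1_from_predictions(y_true, y_pred, 4)
        theirs = f1_score(y_true, y_pred, average="macro", zero_division=0)
        assert ours == pytest.approx(theirs, abs=1e-12)
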