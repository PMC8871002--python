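import math

import numpy as np
import pytest

from oracles import (
    brute_bf_score,
    brute_binary_counts,
    brute_class_metrics,
    brute_confusion,
    brute_dataset_metrics,
)
from saxseg.metrics import (
    ConfusionMatrix,
    MetricAccumulator,
    bf_score,
    binary_counts,
    class_boundary,
    confusion_matrix,
    dataset_metrics,
    default_bf_tolerance,
    mean_bf_score,
    segmentation_metrics,
)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(0, 3, (8, 8))
        cm = confusion_matrix(truth, truth, 3)
        assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))
        assert np.trace(cm.counts) == 64

    def test_enumerated_2x2(self):
        truth = np.array([[0, 0], [1, 2]])
        pred = np.array([[0, 1], [1, 1]])
        cm = confusion_matrix(pred, truth, 3)
        want = np.zeros((3, 3), dtype=int)
        want[0, 0] = 1
        want[0, 1] = 1
        want[1, 1] = 1
        want[2, 1] = 1
        assert np.array_equal(cm.counts, want)

    def test_additivity(self, rng):
        p1, t1 = rng.integers(0, 3, (2, 6, 6))
        p2, t2 = rng.integers(0, 3, (2, 6, 6))
        lhs = confusion_matrix(p1, t1, 3) + confusion_matrix(p2, t2, 3)
        rhs = confusion_matrix(np.hstack([p1, p2]), np.hstack([t1, t2]), 3)
        assert np.array_equal(lhs.counts, rhs.counts)

    def test_matches_brute_force(self, rng):
        pred = rng.integers(0, 4, (9, 9))
        truth = rng.integers(0, 4, (9, 9))
        cm = confusion_matrix(pred, truth, 4)
        assert np.array_equal(cm.counts, brute_confusion(pred, truth, 4))

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.zeros((2, 2), int), np.zeros((3, 3), int), 3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            confusion_matrix(np.full((2, 2), 5), np.zeros((2, 2), int), 3)


class TestBinaryCounts:
    def test_diagonal_has_no_errors(self, rng):
        truth = rng.integers(0, 3, (8, 8))
        cm = confusion_matrix(truth, truth, 3)
        for c in range(3):
            tp, fp, fn, tn = binary_counts(cm, c)
            assert fp == 0 and fn == 0

    def test_enumerated_example_class1(self):
        truth = np.array([[0, 0], [1, 2]])
        pred = np.array([[0, 1], [1, 1]])
        cm = confusion_matrix(pred, truth, 3)
        assert binary_counts(cm, 1) == (1, 2, 0, 1)

    def test_partition(self, rng):
        pred = rng.integers(0, 3, (7, 7))
        truth = rng.integers(0, 3, (7, 7))
        cm = confusion_matrix(pred, truth, 3)
        for c in range(3):
            assert sum(binary_counts(cm, c)) == 49

    def test_matches_brute_force(self, rng):
        pred = rng.integers(0, 3, (6, 6))
        truth = rng.integers(0, 3, (6, 6))
        cm = confusion_matrix(pred, truth, 3)
        for c in range(3):
            assert binary_counts(cm, c) == brute_binary_counts(pred, truth, c)


class TestSegmentationMetrics:
    def test_hand_arithmetic(self):
        # TP=8, FP=1, FN=1 for class 1
        cm = ConfusionMatrix(np.array([[10, 1], [1, 8]]))
        rep = segmentation_metrics(cm)
        assert math.isclose(rep.per_class["dice"][1], 16 / 18)
        assert math.isclose(rep.per_class["jaccard"][1], 0.8)

    def test_perfect_prediction_all_ones(self, rng):
        truth = rng.integers(0, 3, (10, 10))
        rep = segmentation_metrics(confusion_matrix(truth, truth, 3))
        for vec in rep.per_class.values():
            assert np.allclose(vec, 1.0)
        assert rep.global_accuracy == 1.0 and rep.mean_iou == 1.0

    def test_disjoint_prediction_zeros(self):
        truth = np.ones((4, 4), dtype=int)
        pred = np.full((4, 4), 2)
        rep = segmentation_metrics(confusion_matrix(pred, truth, 3))
        for key in ("dice", "jaccard", "sensitivity", "ppv"):
            assert rep.per_class[key][1] == 0.0

    def test_dice_jaccard_identity(self, rng):
        # dice == 2j/(1+j) exactly, every class
        pred = rng.integers(0, 3, (12, 12))
        truth = rng.integers(0, 3, (12, 12))
        rep = segmentation_metrics(confusion_matrix(pred, truth, 3))
        d, j = rep.per_class["dice"], rep.per_class["jaccard"]
        assert np.allclose(d, 2 * j / (1 + j), atol=1e-12, rtol=0)
        assert (j <= d + 1e-15).all()

    def test_label_permutation_invariance(self, rng):
        pred = rng.integers(0, 3, (10, 10))
        truth = rng.integers(0, 3, (10, 10))
        perm = np.array([2, 0, 1])
        a = segmentation_metrics(confusion_matrix(pred, truth, 3))
        b = segmentation_metrics(confusion_matrix(perm[pred], perm[truth], 3))
        for key in a.per_class:
            assert np.allclose(sorted(a.per_class[key]), sorted(b.per_class[key]))
        assert math.isclose(a.global_accuracy, b.global_accuracy)

    def test_matches_brute_force(self, rng):
        pred = rng.integers(0, 3, (16, 16))
        truth = rng.integers(0, 3, (16, 16))
        rep = segmentation_metrics(confusion_matrix(pred, truth, 3))
        for c in range(3):
            want = brute_class_metrics(pred, truth, c)
            for key, val in want.items():
                assert math.isclose(rep.per_class[key][c], val, abs_tol=1e-12)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            segmentation_metrics(ConfusionMatrix(np.zeros((3, 3), int)))


class TestDatasetMetrics:
    def test_diagonal_all_ones(self):
        cm = ConfusionMatrix(np.diag([50, 30, 20]))
        assert dataset_metrics(cm) == (1.0, 1.0, 1.0, 1.0)

    def test_absent_class_with_false_alarms(self):
        cm = ConfusionMatrix(np.array([[90, 10], [0, 0]]))
        ga, ma, mi, wi = dataset_metrics(cm)
        assert math.isclose(ga, 0.9)
        assert math.isclose(mi, (0.9 + 0.0) / 2)  # IoU_0 = 90/100, class 1 absent-truth, predicted
        assert math.isclose(wi, 0.9)  # class 1 has zero truth share

    def test_weighted_equals_mean_for_equal_shares(self):
        cm = ConfusionMatrix(np.array([[40, 10], [10, 40]]))
        ga, ma, mi, wi = dataset_metrics(cm)
        assert math.isclose(mi, wi)

    def test_matches_brute_force(self, rng):
        pred = rng.integers(0, 3, (16, 16))
        truth = rng.integers(0, 3, (16, 16))
        got = dataset_metrics(confusion_matrix(pred, truth, 3))
        want = brute_dataset_metrics(pred, truth, 3)
        assert np.allclose(got, want, atol=1e-12)


class TestBFScore:
    def test_identical_masks_score_one(self, rng):
        mask = np.zeros((20, 20), dtype=int)
        mask[5:15, 6:14] = 1
        assert bf_score(mask, mask, 1) == 1.0

    def test_default_tolerance(self):
        assert default_bf_tolerance((256, 192)) == math.ceil(0.0075 * math.hypot(256, 192))

    def test_shifted_square_beyond_tolerance(self):
        tol = 2
        truth = np.zeros((24, 24), dtype=int)
        truth[2:12, 2:12] = 1
        pred = np.roll(truth, tol + 2, axis=1)
        got = bf_score(pred, truth, 1, tolerance=tol)
        want = brute_bf_score(pred, truth, 1, tol)
        assert got < 1.0
        assert math.isclose(got, want, abs_tol=1e-9)

    def test_one_pixel_shift_within_tolerance(self):
        truth = np.zeros((24, 24), dtype=int)
        truth[5:15, 5:15] = 1
        pred = np.roll(truth, 1, axis=0)
        assert bf_score(pred, truth, 1, tolerance=2) == 1.0

    def test_absent_class_conventions(self):
        empty = np.zeros((8, 8), dtype=int)
        square = empty.copy()
        square[2:5, 2:5] = 1
        assert bf_score(empty, empty, 1) == 1.0
        assert bf_score(square, empty, 1) == 0.0
        assert bf_score(empty, square, 1) == 0.0

    def test_symmetry(self, rng):
        a = rng.integers(0, 3, (16, 16))
        b = rng.integers(0, 3, (16, 16))
        for c in range(3):
            assert math.isclose(bf_score(a, b, c), bf_score(b, a, c), abs_tol=1e-12)

    def test_matches_brute_force_random(self, rng):
        for _ in range(5):
            a = rng.integers(0, 3, (12, 12))
            b = rng.integers(0, 3, (12, 12))
            for c in range(3):
                assert math.isclose(
                    bf_score(a, b, c, tolerance=2), brute_bf_score(a, b, c, 2), abs_tol=1e-9
                )

    def test_boundary_includes_image_edge(self):
        mask = np.ones((4, 4), dtype=int)
        boundary = class_boundary(mask, 1)
        assert boundary[0].all() and boundary[-1].all()
        assert not boundary[1:3, 1:3].any()

    def test_mean_bf_score(self, rng):
        masks = [rng.integers(0, 3, (10, 10)) for _ in range(3)]
        val = mean_bf_score(masks, masks, 3)
        assert val == 1.0


class TestMetricAccumulator:
    def test_accumulation_matches_pooled(self, rng):
        preds = [rng.integers(0, 3, (8, 8)) for _ in range(3)]
        truths = [rng.integers(0, 3, (8, 8)) for _ in range(3)]
        acc = MetricAccumulator(3)
        for p, t in zip(preds, truths):
            acc.add(p, t)
        pooled = confusion_matrix(np.hstack(preds), np.hstack(truths), 3)
        assert np.array_equal(acc.cm.counts, pooled.counts)
        rep = acc.report()
        assert rep.mean_bf_score is not None
        assert 0.0 <= rep.mean_bf_score <= 1.0

    def test_report_metrics_in_unit_interval(self, rng):
        acc = MetricAccumulator(3)
        acc.add(rng.integers(0, 3, (8, 8)), rng.integers(0, 3, (8, 8)))
        rep = acc.report()
        doc = rep.to_dict()
        for key, vec in doc["per_class"].items():
            assert all(0.0 <= v <= 1.0 for v in vec), key
        for key in ("global_accuracy", "mean_accuracy", "mean_iou", "weighted_iou"):
            assert 0.0 <= doc[key] <= 1.0
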