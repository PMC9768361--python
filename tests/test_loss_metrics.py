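"""Loss closed forms and metric oracles.

The soft-Jaccard and cross-entropy values are checked against hand-evaluated
closed forms; MIoU and Dice against a naive double-loop pixel-count oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mucomap.loss_metrics import (
    combined_loss,
    combined_loss_grad,
    cross_entropy_loss,
    dice,
    jaccard_distance_loss,
    miou,
    per_class_dice,
    per_class_iou,
)


def naive_iou_dice(pred, truth, num_classes):
    """Double-loop pixel-count oracle for IoU and Dice per class."""
    ious, dices = [], []
    for k in range(num_classes):
        inter = npred = ntruth = 0
        for i in range(pred.shape[0]):
            for j in range(pred.shape[1]):
                p, t = pred[i, j] == k, truth[i, j] == k
                inter += p and t
                npred += p
                ntruth += t
        union = npred + ntruth - inter
        ious.append(inter / union if union else np.nan)
        dices.append(2 * inter / (npred + ntruth) if npred + ntruth else np.nan)
    return np.array(ious), np.array(dices)


class TestJaccardDistance:
    def test_perfect_overlap_is_zero(self):
        p = y = np.ones(10)
        assert jaccard_distance_loss(p, y, smooth=0) == 0.0

    def test_disjoint_is_one(self):
        assert jaccard_distance_loss(np.ones(6), np.zeros(6), smooth=0) == 1.0

    def test_hand_evaluated_two_pixel_case(self):
        # terms: (1*1)/(1+1-1) = 1 and (0.5*0)/(0.5+0-0) = 0 -> 1 - 1/2
        val = jaccard_distance_loss([1.0, 0.5], [1.0, 0.0], smooth=0)
        assert val == pytest.approx(0.5, abs=1e-6)

    def test_empty_vs_empty_with_smoothing_is_perfect(self):
        assert jaccard_distance_loss(np.zeros(5), np.zeros(5), smooth=1.0) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            jaccard_distance_loss(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        hnp.arrays(np.float64, (12,), elements=st.floats(0, 1)),
        hnp.arrays(np.int8, (12,), elements=st.integers(0, 1)),
    )
    def test_bounded_and_symmetric(self, p, y):
        y = y.astype(np.float64)
        v = jaccard_distance_loss(p, y, smooth=0)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(jaccard_distance_loss(y, p, smooth=0), abs=1e-12)


class TestCrossEntropy:
    def test_one_hot_match_is_zero(self):
        y = np.eye(3)[[0, 1, 2]]
        assert cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_single_pixel_closed_form(self):
        p = np.array([[0.5, 0.25, 0.25]])
        y = np.array([[1.0, 0.0, 0.0]])
        assert cross_entropy_loss(p, y) == pytest.approx(np.log(2), abs=1e-6)

    def test_uniform_prediction_is_log3(self):
        p = np.full((7, 3), 1 / 3)
        y = np.eye(3)[np.arange(7) % 3]
        assert cross_entropy_loss(p, y) == pytest.approx(np.log(3), abs=1e-6)

    def test_hard_zero_prediction_stays_finite(self):
        p = np.array([[0.0, 1.0]])
        y = np.array([[1.0, 0.0]])
        assert np.isfinite(cross_entropy_loss(p, y))


class TestCombinedLoss:
    def test_perfect_prediction_zero(self):
        y = np.eye(3)[np.zeros((4, 4), dtype=int)]
        lv = combined_loss(y, y, smooth=0)
        assert lv.total == pytest.approx(0.0, abs=1e-6)

    def test_parts_sum_exactly(self, rng):
        p = rng.random((5, 5, 3))
        p /= p.sum(-1, keepdims=True)
        y = np.eye(3)[rng.integers(0, 3, (5, 5))]
        lv = combined_loss(p, y)
        assert lv.total == lv.jaccard_part + lv.ce_part  # bitwise additivity

    def test_single_class_case_sums_the_two_oracles(self):
        p, y = [1.0, 0.5], [1.0, 0.0]
        lv = combined_loss(p, y, smooth=0, channel_axis=None)
        jd = jaccard_distance_loss(p, y, smooth=0)
        ce = cross_entropy_loss(p, y, channel_axis=None)
        assert jd == pytest.approx(0.5, abs=1e-6)
        assert lv.total == pytest.approx(jd + ce, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.05, 0.95, size=(3, 4, 3))
        y = np.eye(3)[rng.integers(0, 3, (3, 4))]
        g = combined_loss_grad(p, y, smooth=1.0)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (2, 3, 2)]:
            pp = p.copy()
            pp[idx] += eps
            up = combined_loss(pp, y).total
            pp[idx] -= 2 * eps
            dn = combined_loss(pp, y).total
            assert g[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-4)


class TestMetrics:
    def test_identical_maps_score_one(self, rng):
        cm = rng.integers(0, 3, (10, 10))
        assert miou(cm, cm, 3) == 1.0
        assert dice(cm, cm, 3) == 1.0

    def test_binary_count_example(self):
        # truth 4 px, pred 6 px, overlap 3 -> IoU 3/7, Dice 6/10
        truth = np.zeros((4, 4), dtype=int)
        truth[0, :4] = 1
        pred = np.zeros((4, 4), dtype=int)
        pred[0, :3] = 1
        pred[1, :3] = 1
        assert per_class_iou(pred, truth, 2)[1] == pytest.approx(3 / 7)
        assert per_class_dice(pred, truth, 2)[1] == pytest.approx(6 / 10)

    def test_two_by_two_enumeration(self):
        truth = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        assert miou(pred, truth, 2) == pytest.approx(7 / 12)

    def test_absent_class_excluded_from_mean(self):
        truth = np.zeros((3, 3), dtype=int)
        pred = np.zeros((3, 3), dtype=int)
        assert miou(pred, truth, 3) == 1.0  # classes 1, 2 absent everywhere

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            miou(np.zeros((2, 2), int), np.zeros((3, 3), int), 3)

    def test_label_permutation_invariance(self, rng):
        pred = rng.integers(0, 3, (12, 12))
        truth = rng.integers(0, 3, (12, 12))
        perm = np.array([2, 0, 1])
        assert miou(pred, truth, 3) == pytest.approx(miou(perm[pred], perm[truth], 3))
        assert dice(pred, truth, 3) == pytest.approx(dice(perm[pred], perm[truth], 3))

    def test_against_double_loop_oracle(self, rng):
        for _ in range(25):
            pred = rng.integers(0, 3, (16, 16))
            truth = rng.integers(0, 3, (16, 16))
            oi, od = naive_iou_dice(pred, truth, 3)
            np.testing.assert_allclose(per_class_iou(pred, truth, 3), oi, atol=1e-12)
            np.testing.assert_allclose(per_class_dice(pred, truth, 3), od, atol=1e-12)

    def test_dice_iou_identity(self, rng):
        for _ in range(25):
            pred = rng.integers(0, 2, (8, 8))
            truth = rng.integers(0, 2, (8, 8))
            ious = per_class_iou(pred, truth, 2)
            dices = per_class_dice(pred, truth, 2)
            mask = ~np.isnan(ious)
            np.testing.assert_allclose(
                dices[mask], 2 * ious[mask] / (1 + ious[mask]), atol=1e-12
            )
            assert (dices[mask] >= ious[mask] - 1e-12).all()
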