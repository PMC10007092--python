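"""Dice loss family, confusion metrics, MSE and PSNR."""
import math
from fractions import Fraction

import numpy as np
import pytest

from sswan.autodiff import Tensor
from sswan.losses import (
    ConfusionCounts,
    classification_metrics,
    confusion,
    dice_coefficient,
    dice_loss,
    mse,
    psnr,
    total_loss,
    weighted_dice_loss,
)

from oracles import confusion_oracle, dice_loss_oracle


def hard_probs(labels, num_classes):
    return np.eye(num_classes)[labels]


class TestDiceLoss:
    def test_perfect_hard_masks_score_zero(self):
        labels = (np.arange(36).reshape(6, 6) % 2)
        p = hard_probs(labels, 2)
        assert dice_loss(p, p) < 1e-6

    def test_disjoint_hard_masks_score_one(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.ones((4, 4), dtype=int)
        # both class channels are fully disjoint between prediction and truth
        assert dice_loss(hard_probs(a, 2), hard_probs(b, 2)) == pytest.approx(1.0)

    def test_two_by_two_worked_example(self):
        """Hand-summed arithmetic: fg dice 2/3, bg dice 4/5, uniform weights."""
        probs = np.zeros((2, 2, 2))
        probs[..., 1] = [[1, 0], [0, 0]]
        probs[..., 0] = 1 - probs[..., 1]
        truth = np.zeros((2, 2, 2))
        truth[..., 1] = [[1, 1], [0, 0]]
        truth[..., 0] = 1 - truth[..., 1]
        expected = 1 - 0.5 * (2 * 1 / (1 + 2)) - 0.5 * (2 * 2 / (3 + 2))
        assert dice_loss(probs, truth, eps=0.0) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(size=(5, 4, 3))
        probs = raw / raw.sum(axis=2, keepdims=True)
        truth = hard_probs(rng.integers(0, 3, size=(5, 4)), 3)
        w = rng.uniform(size=3)
        w /= w.sum()
        assert dice_loss(probs, truth, weights=w) == pytest.approx(
            dice_loss_oracle(probs, truth, w), abs=1e-12)

    def test_bounded_and_monotone_toward_truth(self):
        """On a one-pixel toy the loss falls strictly as the foreground
        probability approaches the true label."""
        truth = np.zeros((1, 1, 2))
        truth[0, 0, 1] = 1.0
        losses = []
        for p in np.linspace(0.05, 0.95, 10):
            probs = np.array([[[1 - p, p]]])
            val = dice_loss(probs, truth)
            assert 0.0 <= val <= 1.0
            losses.append(val)
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_tensor_input_is_differentiable(self):
        probs = Tensor(np.full((2, 2, 2), 0.5), requires_grad=True)
        truth = hard_probs(np.array([[0, 1], [1, 0]]), 2)
        loss = dice_loss(probs, truth)
        loss.backward()
        assert probs.grad is not None and np.any(probs.grad != 0)

    def test_bad_weights_rejected(self):
        p = np.full((2, 2, 2), 0.5)
        with pytest.raises(ValueError):
            dice_loss(p, p, weights=[0.9, 0.9])
        with pytest.raises(ValueError):
            dice_loss(p, p, weights=[1.5, -0.5])


class TestWeightedDiceLoss:
    def test_perfect_prediction_scores_zero(self):
        m = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        assert weighted_dice_loss(m, m) < 1e-6

    def test_disjoint_masks_score_one(self):
        a = np.zeros((4, 4))
        a[0, 0] = 1.0
        b = np.zeros((4, 4))
        b[3, 3] = 1.0
        assert weighted_dice_loss(a, b) == pytest.approx(1.0)

    def test_half_overlap_hand_arithmetic(self):
        """pred covers 2 px, truth covers 2 px, 1 shared:
        1 - 4*1 / (2 + 3*2) = 1/2 under the 1:3 denominator convention."""
        pred = np.zeros((1, 4))
        pred[0, :2] = 1.0
        truth = np.zeros((1, 4))
        truth[0, 1:3] = 1.0
        assert weighted_dice_loss(pred, truth) == pytest.approx(0.5, abs=1e-6)

    def test_under_coverage_costs_more_than_plain_dice(self):
        truth = np.zeros((6, 6))
        truth[1:5, 1:5] = 1.0
        pred = np.zeros((6, 6))
        pred[2:4, 2:4] = 1.0          # strictly inside the truth
        plain = dice_loss(
            np.stack([1 - pred, pred], axis=-1),
            np.stack([1 - truth, truth], axis=-1),
            weights=[0.0, 1.0])
        assert weighted_dice_loss(pred, truth) > plain

    def test_non_binary_truth_rejected(self):
        with pytest.raises(ValueError):
            weighted_dice_loss(np.zeros((2, 2)), np.full((2, 2), 0.5))


class TestTotalLoss:
    def test_lambda_zero_is_identity(self):
        assert total_loss(0.37, [np.ones((3, 3))], lam=0.0) == 0.37

    def test_zero_parameters_add_nothing(self):
        assert total_loss(0.2, [np.zeros((4, 4))], lam=0.1) == pytest.approx(0.2)

    def test_single_weight_arithmetic(self):
        assert total_loss(0.3, [np.array([2.0])], lam=0.1) == pytest.approx(0.7)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(0.1, [], lam=-1e-3)


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self, rng):
        labels = rng.integers(0, 3, size=(10, 10))
        c = confusion(labels, labels, positive_class=1)
        assert c.fp == 0 and c.fn == 0
        assert c.total == 100

    def test_inverted_binary_maps(self):
        truth = (np.arange(16).reshape(4, 4) % 2)
        c = confusion(1 - truth, truth, positive_class=1)
        assert c.tp == 0 and c.tn == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 2, size=(10, 10))
        truth = rng.integers(0, 2, size=(10, 10))
        c = confusion(pred, truth, positive_class=1)
        assert (c.tp, c.fp, c.tn, c.fn) == confusion_oracle(pred, truth, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((3, 3)), np.zeros((3, 4)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestClassificationMetrics:
    def test_worked_case(self):
        r = classification_metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert r.accuracy == pytest.approx(0.85)
        assert r.precision == pytest.approx(0.9)
        assert r.recall == pytest.approx(9 / 11)
        assert r.sensitivity == pytest.approx(9 / 11)
        assert r.specificity == pytest.approx(8 / 9)

    def test_paper_exact_variant_uses_printed_denominators(self):
        r = classification_metrics(ConfusionCounts(tp=9, fp=1, tn=8, fn=2),
                                   paper_exact=True)
        assert r.sensitivity == pytest.approx(0.9)       # TP/(TP+FP)
        assert r.specificity == pytest.approx(0.8)       # TN/(TP+FP)

    def test_error_free_counts_give_unit_rates(self):
        r = classification_metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        assert (r.accuracy, r.precision, r.recall, r.specificity) == (1, 1, 1, 1)

    def test_undefined_metrics_are_nan_not_zero(self):
        r = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert math.isnan(r.precision)
        assert not math.isnan(r.accuracy)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_rational_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fp + tn + fn == 0:
                continue
            r = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert r.accuracy == pytest.approx(
                float(Fraction(tp + tn, tp + fp + tn + fn)), abs=1e-15)
            if tp + fn:
                assert r.recall == pytest.approx(
                    float(Fraction(tp, tp + fn)), abs=1e-15)
            if tn + fp:
                assert r.specificity == pytest.approx(
                    float(Fraction(tn, tn + fp)), abs=1e-15)


class TestMSEandPSNR:
    def test_mse_cases(self, rng):
        x = rng.normal(size=(8, 8))
        assert mse(x, x) == 0.0
        assert mse(x + 1, x) == pytest.approx(1.0)
        assert mse(np.array([[1.0, 0.0], [2.0, 4.0]]),
                   np.array([[0.0, 1.0], [0.0, 4.0]])) == pytest.approx(1.5)

    def test_psnr_closed_forms(self, rng):
        x = rng.normal(size=(8, 8))
        assert psnr(x, x) == math.inf
        noisy = x + math.sqrt(0.01)
        assert psnr(noisy, x, peak=1.0) == pytest.approx(20.0)
        assert psnr(x + 1.0, x, peak=1.0) == pytest.approx(0.0)

    def test_psnr_decreases_with_noise(self, rng):
        x = rng.normal(size=(32, 32))
        vals = [psnr(x + rng.normal(0, s, size=x.shape), x, peak=4.0)
                for s in (0.01, 0.03, 0.1, 0.3, 1.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2)), np.zeros((2, 2)), peak=0.0)


def test_dice_coefficient_hard_overlap():
    a = np.array([[1, 1, 0, 0]])
    b = np.array([[0, 1, 1, 0]])
    assert dice_coefficient(a, b) == pytest.approx(0.5)
    assert dice_coefficient(np.zeros((2, 2)), np.zeros((2, 2))) == 1.0


class TestDiceBoundsProperty:
    """Property: the soft Dice loss stays in [0, 1] for any probability field."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 4))
    def test_loss_bounded(self, seed, L):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(size=(6, 6, L))
        probs = raw / raw.sum(axis=2, keepdims=True)
        truth = np.eye(L)[rng.integers(0, L, size=(6, 6))]
        val = dice_loss(probs, truth)
        assert 0.0 <= val <= 1.0
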