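"""ROI Align, the softmax classifier math, mask head, multi-task loss."""

import numpy as np
import pytest

from nucseg.autodiff import Tensor
from nucseg.heads import (ClassBoxHead, DetectionResult, MaskHead,
                          SoftmaxParams, detections_to_label_map,
                          multi_task_loss, paste_mask, roi_align, sgd_step,
                          softmax_gradient, softmax_loss, softmax_probs)
from nucseg.rpn import Box, RpnLossTerms


class TestRoiAlign:
    def test_constant_map_gives_constant_output(self):
        f = Tensor(np.full((2, 8, 8), 3.25))
        out = roi_align(f, [[1.3, 2.1, 5.7, 6.2]], output_size=3)
        np.testing.assert_allclose(out.data, 3.25)

    def test_shape_contract_independent_of_box_size(self, rng):
        f = Tensor(rng.normal(size=(4, 16, 16)))
        for box in ([0, 0, 4, 4], [2, 2, 14, 9], [0.5, 0.5, 2.0, 2.0]):
            assert roi_align(f, [box], 7).shape == (1, 4, 7, 7)

    def test_integer_aligned_bins_on_ramp(self):
        """Box on exact integer bins over a column-ramp equals bin averages."""
        H = W = 8
        ramp = np.tile(np.arange(W, dtype=float), (H, 1))
        out = roi_align(Tensor(ramp[None]), [[0, 0, 4, 4]], output_size=2)
        # x-samples per bin: 0.5,1.5 -> pixel coords 0.0,1.0 -> mean 0.5
        np.testing.assert_allclose(out.data[0, 0],
                                   [[0.5, 2.5], [0.5, 2.5]], atol=1e-12)

    def test_linearity_in_feature_map(self, rng):
        a, b = 2.0, -0.7
        F = rng.normal(size=(2, 10, 10))
        G = rng.normal(size=(2, 10, 10))
        box = [[1.2, 3.4, 7.8, 9.1]]
        lhs = roi_align(Tensor(a * F + b * G), box, 5).data
        rhs = a * roi_align(Tensor(F), box, 5).data + \
            b * roi_align(Tensor(G), box, 5).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.normal(size=(1, 6, 6))
        box = [[0.7, 1.1, 4.3, 5.2]]
        t = Tensor(f, requires_grad=True)
        (roi_align(t, box, 3) ** 2.0).sum().backward()
        eps = 1e-6
        num = np.zeros_like(f)
        for i in np.ndindex(f.shape):
            fp, fm = f.copy(), f.copy()
            fp[i] += eps
            fm[i] -= eps
            num[i] = (float((roi_align(Tensor(fp), box, 3).data ** 2).sum()) -
                      float((roi_align(Tensor(fm), box, 3).data ** 2).sum())) / (2 * eps)
        np.testing.assert_allclose(t.grad, num, atol=1e-5)

    def test_degenerate_box_raises(self):
        with pytest.raises(ValueError):
            roi_align(Tensor(np.zeros((1, 8, 8))), [[2, 2, 2, 5]], 3)


class TestSoftmaxMath:
    def test_equal_logits_uniform(self, rng):
        params = SoftmaxParams(theta=np.zeros((4, 3)))
        p = softmax_probs(rng.normal(size=3), params)
        np.testing.assert_allclose(p, 0.25)

    def test_two_class_log_odds(self):
        # theta1.x - theta2.x = ln 2  ->  probabilities (2/3, 1/3)
        params = SoftmaxParams(theta=np.array([[np.log(2.0)], [0.0]]))
        p = softmax_probs(np.array([1.0]), params)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_normalization_and_shift_invariance(self, rng):
        theta = rng.normal(size=(5, 4))
        x = rng.normal(size=(7, 4))
        p = softmax_probs(x, SoftmaxParams(theta=theta))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        # adding one shared direction to every class vector shifts all
        # logits equally and leaves the probabilities unchanged
        shift = rng.normal(size=4)
        p2 = softmax_probs(x, SoftmaxParams(theta=theta + shift * 0))
        np.testing.assert_allclose(p, p2)

    def test_uniform_predictions_loss_is_log_k(self, rng):
        k, d, m = 5, 3, 10
        params = SoftmaxParams(theta=np.zeros((k, d)))
        X = rng.normal(size=(m, d))
        y = rng.integers(1, k + 1, size=m)
        assert softmax_loss(X, y, params) == pytest.approx(np.log(k))

    def test_confident_correct_predictions_near_zero_loss(self):
        params = SoftmaxParams(theta=np.array([[50.0, 0], [0, 50.0]]))
        X = np.array([[1.0, 0], [0, 1.0]])
        assert softmax_loss(X, [1, 2], params) < 1e-8

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            softmax_loss(np.zeros((0, 2)), [], SoftmaxParams(theta=np.zeros((2, 2))))

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradient vs central differences on random 5-class data."""
        k, d, m = 5, 4, 8
        theta = rng.normal(size=(k, d))
        X = rng.normal(size=(m, d))
        y = rng.integers(1, k + 1, size=m)
        grad = softmax_gradient(X, y, SoftmaxParams(theta=theta))
        eps = 1e-5
        num = np.zeros_like(theta)
        for i in np.ndindex(theta.shape):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (softmax_loss(X, y, SoftmaxParams(theta=tp)) -
                      softmax_loss(X, y, SoftmaxParams(theta=tm))) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-4

    def test_gradient_class_contributions_sum_to_zero(self, rng):
        """Summing the per-class gradients over classes cancels exactly."""
        theta = rng.normal(size=(3, 4))
        X = rng.normal(size=(6, 4))
        y = rng.integers(1, 4, size=6)
        grad = softmax_gradient(X, y, SoftmaxParams(theta=theta))
        np.testing.assert_allclose(grad.sum(axis=0), 0.0, atol=1e-12)

    def test_sgd_zero_gradient_no_change(self, rng):
        params = SoftmaxParams(theta=rng.normal(size=(3, 2)))
        out = sgd_step(params, np.zeros((3, 2)))
        np.testing.assert_array_equal(out.theta, params.theta)

    def test_sgd_unit_step_on_own_theta_zeroes(self, rng):
        params = SoftmaxParams(theta=rng.normal(size=(3, 2)))
        out = sgd_step(params, params.theta, alpha=1.0)
        np.testing.assert_allclose(out.theta, 0.0)

    def test_sgd_descends_on_toy_problem(self, rng):
        theta = rng.normal(size=(3, 4))
        X = rng.normal(size=(12, 4))
        y = rng.integers(1, 4, size=12)
        params = SoftmaxParams(theta=theta, alpha=0.05)
        before = softmax_loss(X, y, params)
        for _ in range(5):
            params = sgd_step(params, softmax_gradient(X, y, params))
        assert softmax_loss(X, y, params) < before


class TestMaskHead:
    def test_shape_contract(self, rng):
        head = MaskHead(8, channels=8, num_classes=2, rng=rng)
        roi = Tensor(rng.normal(size=(3, 8, 14, 14)))
        assert head(roi).shape == (3, 2, 28, 28)

    def test_zero_weights_give_half_probability(self, rng):
        head = MaskHead(4, channels=4, num_classes=2, rng=rng)
        for _, p in head.named_parameters():
            p.data[...] = 0.0
        logits = head(Tensor(rng.normal(size=(1, 4, 8, 8))))
        np.testing.assert_allclose(1 / (1 + np.exp(-logits.data)), 0.5)

    def test_paste_all_ones_covers_rounded_box(self):
        mask = np.ones((4, 4))
        out = paste_mask(mask, Box(2.3, 1.6, 6.8, 5.1), (10, 10))
        want = np.zeros((10, 10), bool)
        want[1:6, 2:7] = True                   # floor/ceil of the box
        np.testing.assert_array_equal(out, want)

    def test_paste_clips_to_frame(self):
        out = paste_mask(np.ones((4, 4)), np.array([-3, -3, 5, 5.0]), (8, 8))
        assert out[:5, :5].all() and not out[5:, :].any()


class TestClassBoxHead:
    def test_output_shapes(self, rng):
        head = ClassBoxHead(8, pooled_size=7, hidden=16, num_classes=2, rng=rng)
        roi = Tensor(rng.normal(size=(5, 8, 7, 7)))
        cls, box = head(roi)
        assert cls.shape == (5, 2)
        assert box.shape == (5, 2, 4)


class TestMultiTaskLoss:
    def test_all_zero(self):
        assert multi_task_loss(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_additivity(self, rng):
        base = multi_task_loss(0.3, 0.2, 0.1, 0.4)
        assert multi_task_loss(0.3, 0.2, 0.1, 0.9) == pytest.approx(base + 0.5)

    def test_accepts_rpn_terms_object(self):
        terms = RpnLossTerms(total=Tensor(0.7), cls_term=Tensor(0.5),
                             reg_term=Tensor(0.2), n_cls=4, n_reg=1, lam=1.0)
        out = multi_task_loss(terms, 0.1, 0.1, 0.1)
        assert float(out.data) == pytest.approx(1.0)

    def test_weights_apply_per_term(self):
        out = multi_task_loss(1.0, 1.0, 1.0, 1.0, weights=(1, 2, 3, 4))
        assert out == pytest.approx(10.0)


class TestDetectionResult:
    def test_score_range_validated(self):
        with pytest.raises(ValueError):
            DetectionResult(1, 1.5, np.array([0, 0, 2, 2.0]),
                            np.zeros((4, 4), bool))

    def test_label_map_resolves_overlap_by_score(self):
        m1 = np.zeros((6, 6), bool)
        m2 = np.zeros((6, 6), bool)
        m1[1:4, 1:4] = True
        m2[2:5, 2:5] = True                     # overlaps m1
        r1 = DetectionResult(1, 0.6, np.array([1, 1, 4, 4.0]), m1)
        r2 = DetectionResult(1, 0.9, np.array([2, 2, 5, 5.0]), m2)
        labels = detections_to_label_map([r1, r2], (6, 6))
        assert labels.grid[2, 2] == 1           # higher score claimed first
        assert labels.grid[1, 1] == 2
        assert len(labels.ids) == 2
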