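"""Anchors, box codec, smooth-L1, anchor assignment, RPN loss, NMS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucseg import rpn as R
from nucseg.autodiff import Tensor


class TestAnchors:
    def test_nine_anchors_per_location(self):
        a = R.generate_anchors((1, 2, 4), (0.5, 1.0, 2.0), [(0, 0)], stride=16)
        assert a.shape == (9, 4)

    def test_grid_product_count(self):
        a = R.generate_anchors((1, 2, 4), (0.5, 1.0, 2.0), (2, 2), stride=16)
        assert a.shape == (36, 4)

    def test_unit_ratio_gives_square(self):
        a = R.generate_anchors((2.0,), (1.0,), [(0, 0)], stride=8, base_size=16)
        w = a[0, 2] - a[0, 0]
        h = a[0, 3] - a[0, 1]
        assert w == h == pytest.approx(32.0)

    def test_area_invariant_under_ratio(self):
        a = R.generate_anchors((1.5,), (0.5, 1.0, 2.0), [(0, 0)], stride=8)
        areas = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
        np.testing.assert_allclose(areas, areas[0])

    def test_centering_on_mapped_location(self):
        a = R.generate_anchors((1.0,), (1.0,), [(3, 5)], stride=4)
        cx = (a[0, 0] + a[0, 2]) / 2
        cy = (a[0, 1] + a[0, 3]) / 2
        assert (cx, cy) == (5.5 * 4 / 4 * 4 / 4 * 4, 3.5 * 4) or \
            (cx, cy) == ((5 + 0.5) * 4, (3 + 0.5) * 4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            R.generate_anchors((), (1.0,), (1, 1), 16)
        with pytest.raises(ValueError):
            R.generate_anchors((1.0,), (-1.0,), (1, 1), 16)


class TestBoxCodec:
    def test_identity(self):
        b = R.Box(4, 4, 10, 12)
        d = R.encode_box(b, b)
        assert d == R.BoxDelta(0.0, 0.0, 0.0, 0.0)

    def test_hand_example(self):
        anchor = R.Box(8, 8, 12, 12)       # center (10,10), size (4,4)
        box = R.Box(8, 8, 16, 12)          # center (12,10), size (8,4)
        d = R.encode_box(box, anchor)
        assert d.tx == pytest.approx(0.5)
        assert d.ty == pytest.approx(0.0)
        assert d.tw == pytest.approx(np.log(2))
        assert d.th == pytest.approx(0.0)

    def test_hand_example_inverse(self):
        anchor = R.Box(8, 8, 12, 12)
        out = R.decode_box(R.BoxDelta(0.5, 0.0, np.log(2), 0.0), anchor)
        assert out.x == pytest.approx(12) and out.y == pytest.approx(10)
        assert out.w == pytest.approx(8) and out.h == pytest.approx(4)

    def test_round_trip_1000_random_pairs(self):
        rng = np.random.default_rng(42)
        anchors = np.zeros((1000, 4))
        anchors[:, 0] = rng.uniform(0, 200, 1000)
        anchors[:, 1] = rng.uniform(0, 200, 1000)
        aw = rng.uniform(4, 50, 1000)
        ah = rng.uniform(4, 50, 1000)
        anchors[:, 2] = anchors[:, 0] + aw
        anchors[:, 3] = anchors[:, 1] + ah
        # boxes in the regression regime of their anchors
        boxes = anchors.copy()
        boxes[:, 0] += rng.uniform(-0.5, 0.5, 1000) * aw
        boxes[:, 1] += rng.uniform(-0.5, 0.5, 1000) * ah
        boxes[:, 2] = boxes[:, 0] + aw * rng.uniform(0.5, 2.0, 1000)
        boxes[:, 3] = boxes[:, 1] + ah * rng.uniform(0.5, 2.0, 1000)
        back = R.decode_box(R.encode_box(boxes, anchors), anchors)
        assert np.abs(back - boxes).max() < 1e-5

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(1.0, 100.0), st.floats(1.0, 100.0),
                     st.floats(0.25, 4.0), st.floats(0.25, 4.0),
                     st.floats(1.0, 100.0), st.floats(1.0, 100.0),
                     st.floats(4.0, 50.0), st.floats(4.0, 50.0)))
    def test_round_trip_property(self, vals):
        bx, by, fw, fh, ax, ay, aw, ah = vals
        bw, bh = aw * fw, ah * fh
        box = R.Box(bx, by, bx + bw, by + bh)
        anchor = R.Box(ax, ay, ax + aw, ay + ah)
        back = R.decode_box(R.encode_box(box, anchor), anchor)
        assert abs(back.x1 - box.x1) < 1e-6 * max(1, bw)
        assert abs(back.y2 - box.y2) < 1e-6 * max(1, bh)

    def test_degenerate_anchor_raises(self):
        with pytest.raises(ValueError):
            R.encode_box(np.array([0, 0, 4, 4.0]), np.array([0, 0, 0, 4.0]))

    def test_overflow_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = R.decode_box(R.BoxDelta(0, 0, 50.0, 0), R.Box(0, 0, 4, 4))
        assert np.isfinite(out.as_array()).all()


class TestSmoothL1:
    @pytest.mark.parametrize("x,want", [(0.0, 0.0), (1.0, 0.5), (-3.0, 2.5),
                                        (0.5, 0.125), (2.0, 1.5)])
    def test_hand_values(self, x, want):
        assert R.smooth_l1(x) == pytest.approx(want)

    def test_continuity_at_unit(self):
        eps = 1e-9
        assert abs(R.smooth_l1(1 - eps) - R.smooth_l1(1 + eps)) < 1e-8
        assert abs(R.smooth_l1(-1 + eps) - R.smooth_l1(-1 - eps)) < 1e-8

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-50, 50))
    def test_nonnegative_and_quadratic_inside(self, x):
        v = R.smooth_l1(x)
        assert v >= 0
        if abs(x) <= 1:
            assert v == pytest.approx(0.5 * x * x)

    def test_tensor_version_matches_numpy(self, rng):
        x = rng.normal(scale=2.0, size=(5, 4))
        t = R._smooth_l1_t(Tensor(x, requires_grad=True))
        np.testing.assert_allclose(t.data, R.smooth_l1(x))


class TestAssignment:
    def test_exact_anchor_is_positive(self):
        gt = np.array([[10, 10, 20, 20.0]])
        anchors = np.array([[10, 10, 20, 20.0], [100, 100, 110, 110.0]])
        a = R.assign_anchors(anchors, gt)
        assert a.labels[0] == 1 and a.matched_gt[0] == 0
        assert a.labels[1] == 0

    def test_no_ground_truth_all_negative(self):
        anchors = np.array([[0, 0, 4, 4.0], [8, 8, 12, 12.0]])
        a = R.assign_anchors(anchors, np.zeros((0, 4)))
        assert (a.labels == 0).all()

    def test_between_thresholds_is_ignored(self):
        # IoU = 8/24 + ... construct IoU exactly 0.5: boxes 4x4 overlapping 2x4
        gt = np.array([[0, 0, 4, 4.0]])
        anchors = np.array([[2, 0, 6, 4.0],     # inter 8, union 24 -> 1/3 ... rescue
                            [0, 0, 4, 4.0],     # IoU 1 -> positive, takes the rescue
                            [3, 0, 7, 4.0]])    # inter 4, union 28 -> 1/7 < 0.3 -> neg
        a = R.assign_anchors(anchors, gt, iou_hi=0.7, iou_lo=0.3)
        assert a.labels[1] == 1
        assert a.labels[0] == -1                # 1/3 sits between the thresholds
        assert a.labels[2] == 0

    def test_argmax_rescue_guarantees_positive_per_gt(self, rng):
        gt = np.array([[5, 5, 9, 9.0]])
        anchors = np.array([[4, 4, 8, 8.0], [20, 20, 30, 30.0]])  # best IoU < 0.7
        a = R.assign_anchors(anchors, gt)
        assert a.labels[0] == 1                 # rescued argmax anchor

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            R.assign_anchors(np.zeros((1, 4)), np.zeros((0, 4)),
                             iou_hi=0.3, iou_lo=0.7)


class TestRpnLoss:
    def _setup(self):
        anchors = np.array([[0, 0, 8, 8.0], [10, 10, 18, 18.0],
                            [30, 30, 38, 38.0]])
        labels = np.array([1, 0, -1], dtype=np.int8)
        assignment = R.AnchorAssignment(labels, np.array([0, -1, -1]),
                                        np.array([1.0, 0.0, 0.0]))
        targets = np.zeros((3, 4))
        return anchors, assignment, targets

    def test_perfect_predictions_near_zero(self):
        _, assignment, targets = self._setup()
        probs = np.array([1.0, 0.0, 0.5])
        deltas = targets.copy()
        terms = R.rpn_loss(probs, deltas, assignment, targets)
        assert float(terms.total.data) < 1e-5

    def test_single_positive_regression_half(self):
        """One positive anchor with t - t* = (1,0,0,0): smooth-L1 gives 0.5."""
        _, assignment, targets = self._setup()
        probs = np.array([1.0, 0.0, 0.5])
        deltas = targets.copy()
        deltas[0, 0] = 1.0
        terms = R.rpn_loss(probs, deltas, assignment, targets,
                           lam=1.0, n_reg=1)
        assert float(terms.reg_term.data) == pytest.approx(0.5, abs=1e-9)

    def test_lambda_scales_only_regression(self):
        _, assignment, targets = self._setup()
        probs = np.array([0.8, 0.3, 0.5])
        deltas = targets + 0.7
        t1 = R.rpn_loss(probs, deltas, assignment, targets, lam=1.0)
        t2 = R.rpn_loss(probs, deltas, assignment, targets, lam=2.0)
        assert float(t2.reg_term.data) == pytest.approx(2 * float(t1.reg_term.data))
        assert float(t2.cls_term.data) == pytest.approx(float(t1.cls_term.data))

    def test_ignored_anchors_leave_loss_fixed(self):
        _, assignment, targets = self._setup()
        probs = np.array([0.9, 0.1, 0.5])
        deltas = targets + 0.2
        base = float(R.rpn_loss(probs, deltas, assignment, targets).total.data)
        probs2 = probs.copy()
        probs2[2] = 0.99                       # perturb the ignored anchor
        deltas2 = deltas.copy()
        deltas2[2] += 5.0
        moved = float(R.rpn_loss(probs2, deltas2, assignment, targets).total.data)
        assert moved == pytest.approx(base, abs=1e-12)

    def test_no_positives_regression_zero(self):
        assignment = R.AnchorAssignment(np.array([0, 0], dtype=np.int8),
                                        np.array([-1, -1]), np.zeros(2))
        terms = R.rpn_loss(np.array([0.1, 0.2]), np.zeros((2, 4)),
                           assignment, np.zeros((2, 4)))
        assert float(terms.reg_term.data) == 0.0
        assert terms.n_reg == 1


class TestNms:
    def test_duplicate_boxes_keep_higher_score(self):
        boxes = np.array([[0, 0, 10, 10.0], [0, 0, 10, 10.0]])
        kept_boxes, kept_scores, _ = R.select_proposals(
            boxes, np.array([0.8, 0.9]), nms_iou=0.5)
        assert len(kept_boxes) == 1
        assert kept_scores[0] == 0.9

    def test_disjoint_boxes_all_survive(self):
        boxes = np.array([[0, 0, 4, 4.0], [10, 10, 14, 14.0], [20, 0, 24, 4.0]])
        kept, _, _ = R.select_proposals(boxes, np.array([0.5, 0.6, 0.7]),
                                        nms_iou=0.5)
        assert len(kept) == 3

    def test_output_subset_and_pairwise_below_threshold(self, rng):
        boxes = np.zeros((40, 4))
        boxes[:, 0] = rng.uniform(0, 50, 40)
        boxes[:, 1] = rng.uniform(0, 50, 40)
        boxes[:, 2] = boxes[:, 0] + rng.uniform(4, 20, 40)
        boxes[:, 3] = boxes[:, 1] + rng.uniform(4, 20, 40)
        scores = rng.uniform(size=40)
        kept, _, idx = R.select_proposals(boxes, scores, nms_iou=0.4)
        iou = R.box_iou_matrix(kept, kept)
        np.fill_diagonal(iou, 0.0)
        assert iou.max() <= 0.4 + 1e-12
        np.testing.assert_array_equal(kept, boxes[idx])

    def test_agrees_with_bruteforce_oracle(self):
        """Greedy NMS matches a naive O(n^2) reference on 100 random sets."""
        def nms_oracle(boxes, scores, thresh):
            order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
            kept = []
            for i in order:
                ok = True
                for j in kept:
                    if R.box_iou_matrix(boxes[i][None], boxes[j][None])[0, 0] > thresh:
                        ok = False
                        break
                if ok:
                    kept.append(i)
            return kept

        for trial in range(100):
            rng = np.random.default_rng(trial)
            n = 50
            boxes = np.zeros((n, 4))
            boxes[:, 0] = rng.uniform(0, 60, n)
            boxes[:, 1] = rng.uniform(0, 60, n)
            boxes[:, 2] = boxes[:, 0] + rng.uniform(2, 25, n)
            boxes[:, 3] = boxes[:, 1] + rng.uniform(2, 25, n)
            scores = np.round(rng.uniform(size=n), 2)   # induce ties
            _, _, kept = R.select_proposals(boxes, scores, pre_nms_top_k=n,
                                            nms_iou=0.5, post_nms_top_k=n)
            assert list(kept) == nms_oracle(boxes, scores, 0.5), f"trial {trial}"


class TestProposalIO:
    def test_text_round_trip(self, tmp_path, rng):
        boxes = rng.uniform(0, 50, size=(5, 2))
        boxes = np.hstack([boxes, boxes + rng.uniform(1, 10, size=(5, 2))])
        scores = rng.uniform(size=5)
        path = tmp_path / "proposals.txt"
        R.write_proposals(path, boxes, scores)
        b2, s2 = R.read_proposals(path)
        np.testing.assert_allclose(b2, boxes, atol=1e-4)
        np.testing.assert_allclose(s2, scores, atol=1e-6)
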