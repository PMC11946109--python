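"""Loss-formula oracles: Wise-IoU v1/v3, gradient gain, class-aware weights,
BCE and distribution-focal terms, and the composite objective."""

import numpy as np
import pytest

from reefdet.autograd import Tensor
from reefdet.boxes import Box, DegenerateBoxError
from reefdet.losses import (
    ClassDistribution, LossConfig, WIoUState, box_iou, ciou_loss_t,
    class_aware_weight, classification_loss, composite_loss,
    distribution_focal_loss, gradient_gain, iou_t, outlier_degree,
    wiou_v1_loss, wiou_v1_t, wiou_v3_loss, wiou_v3_t,
)


def unit_square(cx=0.5, cy=0.5, side=1.0):
    return Box(cx, cy, side, side, "corner_px")


class TestWIoUv1:
    def test_identical_boxes_zero(self):
        b = Box.from_corners(0, 0, 2, 1)
        assert wiou_v1_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_concentric_quarter_iou(self):
        # concentric: exponential factor is exactly 1, loss = 1 - IoU
        outer = Box(0, 0, 2, 2, "corner_px")
        inner = Box(0, 0, 1, 1, "corner_px")
        assert box_iou(outer, inner) == pytest.approx(0.25)
        assert wiou_v1_loss(inner, outer) == pytest.approx(0.75)

    def test_off_center_componentwise_oracle(self):
        pred = Box.from_corners(0.0, 0.0, 2.0, 2.0)
        gt = Box.from_corners(1.0, 0.5, 3.0, 2.5)
        # step-by-step recomputation with independent arithmetic
        inter = (2.0 - 1.0) * (2.0 - 0.5)
        union = 4.0 + 4.0 - inter
        iou = inter / union
        d2 = (1.0 - 2.0) ** 2 + (1.0 - 1.5) ** 2
        cw, ch = 3.0 - 0.0, 2.5 - 0.0  # smallest enclosing box
        expected = (1 - iou) * np.exp(d2 / (cw**2 + ch**2))
        assert wiou_v1_loss(pred, gt) == pytest.approx(expected, rel=1e-12)
        # literal predicted-box normalizer variant
        expected_pred = (1 - iou) * np.exp(d2 / (2.0**2 + 2.0**2))
        assert wiou_v1_loss(pred, gt, use_enclosing_normalizer=False) == \
            pytest.approx(expected_pred, rel=1e-12)

    def test_lower_bound_is_iou_loss(self, rng):
        """exp factor >= 1, with equality iff the centers coincide."""
        for _ in range(200):
            p = rng.uniform(0, 1, 4)
            g = rng.uniform(0, 1, 4)
            pred = Box(p[0], p[1], 0.1 + p[2], 0.1 + p[3], "corner_px")
            gt = Box(g[0], g[1], 0.1 + g[2], 0.1 + g[3], "corner_px")
            assert wiou_v1_loss(pred, gt) >= (1 - box_iou(pred, gt)) - 1e-12

    def test_zero_normalizer_rejected(self):
        degenerate = Box(0.0, 0.0, 0.0, 0.0, "corner_px")
        gt = Box.from_corners(1, 1, 2, 2)
        with pytest.raises(DegenerateBoxError):
            wiou_v1_loss(degenerate, degenerate)
        assert wiou_v1_loss(degenerate, gt) > 0  # enclosing box saves pred-degenerate


class TestOutlierDegreeAndGain:
    def test_ratio_identity(self):
        st = WIoUState(running_iou_loss_mean=0.4)
        assert outlier_degree(0.4, st) == pytest.approx(1.0)
        assert outlier_degree(0.0, st) == 0.0

    def test_fixed_mode_reports_constant(self):
        st = WIoUState(theta_mode="fixed", theta_fixed=2.0)
        assert outlier_degree(123.0, st) == 2.0

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            WIoUState(running_iou_loss_mean=0.0)
        with pytest.raises(ValueError):
            WIoUState(beta=-1.0)

    def test_gain_exponent_zero_case(self):
        st = WIoUState(beta=2.5, tau=3.0)
        assert gradient_gain(3.0, st) == pytest.approx(1.0)
        assert gradient_gain(0.0, st) == 0.0

    def test_gain_at_published_constants(self):
        """kappa(theta=2) with beta=1.8, tau=3 equals 2 * 1.8 / 3 = 1.2 exactly."""
        st = WIoUState(beta=1.8, tau=3.0)
        assert gradient_gain(2.0, st) == pytest.approx(2 * 1.8 / 3, rel=1e-15)

    def test_gain_is_non_monotonic_single_interior_max(self):
        st = WIoUState(beta=1.8, tau=3.0)
        theta = np.linspace(1e-3, 10, 4000)
        k = gradient_gain(theta, st)
        d = np.diff(k)
        # one sign change: rises then falls
        assert d[0] > 0 and d[-1] < 0
        assert np.sum((d[:-1] > 0) & (d[1:] <= 0)) == 1
        # stationary point at theta* = 1/ln(beta)
        assert theta[np.argmax(k)] == pytest.approx(1 / np.log(1.8), abs=0.01)

    def test_running_mean_converges_geometrically(self):
        st = WIoUState(momentum=0.9)
        c = 0.37
        errs = []
        for _ in range(30):
            st.update(c)
            errs.append(abs(st.running_iou_loss_mean - c))
        ratios = [e2 / e1 for e1, e2 in zip(errs, errs[1:]) if e1 > 1e-14]
        assert all(r == pytest.approx(0.9, rel=1e-6) for r in ratios)


class TestWIoUv3:
    def test_identical_boxes_zero_any_state(self):
        b = Box.from_corners(0, 0, 3, 2)
        for st in (WIoUState(), WIoUState(theta_mode="fixed"),
                   WIoUState(running_iou_loss_mean=0.01)):
            loss, iou_loss = wiou_v3_loss(b, b, st)
            assert loss == pytest.approx(0.0, abs=1e-12)
            assert iou_loss == pytest.approx(0.0, abs=1e-12)

    def test_fixed_theta_product_of_oracles(self):
        # concentric boxes with IoU 0.5 -> v1 loss 0.5; kappa(2) = 1.2
        outer = Box(0, 0, 2, 2, "corner_px")
        inner = Box(0, 0, 2, 1, "corner_px")
        assert box_iou(outer, inner) == pytest.approx(0.5)
        st = WIoUState(theta_mode="fixed", theta_fixed=2.0, beta=1.8, tau=3.0)
        loss, iou_loss = wiou_v3_loss(inner, outer, st)
        assert loss == pytest.approx(1.2 * 0.5, rel=1e-12)
        assert iou_loss == pytest.approx(0.5)

    def test_dynamic_mode_at_running_mean_uses_theta_one(self):
        outer = Box(0, 0, 2, 2, "corner_px")
        inner = Box(0, 0, 2, 1, "corner_px")
        st = WIoUState(theta_mode="dynamic", running_iou_loss_mean=0.5,
                       beta=1.8, tau=3.0)
        loss, _ = wiou_v3_loss(inner, outer, st)
        expected = gradient_gain(1.0, st) * wiou_v1_loss(inner, outer)
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_batched_matches_scalar(self, rng):
        st = WIoUState(running_iou_loss_mean=0.3)
        preds, gts = [], []
        for _ in range(16):
            p = rng.uniform(0, 1, 4)
            g = rng.uniform(0, 1, 4)
            preds.append([p[0], p[1], p[0] + 0.2 + p[2], p[1] + 0.2 + p[3]])
            gts.append([g[0], g[1], g[0] + 0.2 + g[2], g[1] + 0.2 + g[3]])
        preds, gts = np.array(preds), np.array(gts)
        batched, detached = wiou_v3_t(Tensor(preds), Tensor(gts), st)
        for i in range(16):
            loss_i, iou_i = wiou_v3_loss(Box.from_corners(*preds[i]),
                                         Box.from_corners(*gts[i]), st)
            assert batched.data[i] == pytest.approx(loss_i, rel=1e-5)
            assert detached[i] == pytest.approx(iou_i, rel=1e-5)

    def test_normalizer_is_detached(self, rng):
        """Analytic gradients must match finite differences of a function in
        which the enclosing-box normalizer is frozen at its nominal value."""
        pred0 = np.array([[0.1, 0.2, 0.8, 0.7]])
        gt = np.array([[0.3, 0.3, 0.9, 0.9]])
        t = Tensor(pred0, requires_grad=True)
        wiou_v1_t(t, Tensor(gt)).sum().backward()
        analytic = t.grad.copy()

        cw = max(pred0[0, 2], gt[0, 2]) - min(pred0[0, 0], gt[0, 0])
        ch = max(pred0[0, 3], gt[0, 3]) - min(pred0[0, 1], gt[0, 1])
        norm = cw**2 + ch**2 + 1e-9

        def frozen(p):
            pb = Box.from_corners(*p[0])
            gb = Box.from_corners(*gt[0])
            d2 = (pb.cx - gb.cx) ** 2 + (pb.cy - gb.cy) ** 2
            return (1 - box_iou(pb, gb)) * np.exp(d2 / norm)

        eps = 1e-6
        numeric = np.zeros_like(pred0)
        for j in range(4):
            up, dn = pred0.copy(), pred0.copy()
            up[0, j] += eps
            dn[0, j] -= eps
            numeric[0, j] = (frozen(up) - frozen(dn)) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-7)


class TestClassAwareWeight:
    def test_eta_one_is_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10000))
            ns = int(rng.integers(0, n))
            assert class_aware_weight(ns, n, 1.0) == 1.0

    def test_rare_class_limit_is_one(self):
        assert class_aware_weight(0, 10**6, 8.0) == pytest.approx(1.0)
        assert class_aware_weight(1, 10**8, 8.0) == pytest.approx(1.0, abs=1e-6)

    def test_half_frequency_example(self):
        assert class_aware_weight(1, 2, 8.0) == pytest.approx(0.5 / (1 - 0.5**8), rel=1e-9)
        assert class_aware_weight(1, 2, 8.0) == pytest.approx(0.501961, abs=1e-6)

    def test_abundant_class_limit_is_inverse_eta(self):
        w = class_aware_weight(10**9 - 1, 10**9, 8.0)
        assert w == pytest.approx(1 / 8, rel=1e-6)

    def test_bounds_on_random_triples(self, rng):
        for _ in range(10000):
            n = int(rng.integers(2, 100000))
            ns = int(rng.integers(0, n))
            eta = float(rng.uniform(1.0, 16.0))
            w = class_aware_weight(ns, n, eta)
            assert 1.0 / eta < w <= 1.0 + 1e-12

    def test_strictly_decreasing_in_frequency(self):
        n = 1000
        w = [class_aware_weight(ns, n, 8.0) for ns in range(0, n, 10)]
        assert all(a > b for a, b in zip(w, w[1:]) if a != 1.0 or b != 1.0) or \
            all(a >= b for a, b in zip(w, w[1:]))
        assert w == sorted(w, reverse=True)
        assert w[0] == pytest.approx(1.0)

    def test_degenerate_full_ownership(self):
        assert class_aware_weight(5, 5, 8.0, num_classes=1) == 1.0
        with pytest.raises(ValueError):
            class_aware_weight(5, 5, 8.0, num_classes=3)
        with pytest.raises(ValueError):
            class_aware_weight(6, 5, 8.0)

    def test_distribution_invariants(self):
        with pytest.raises(ValueError):
            ClassDistribution(np.array([1, -1]))
        with pytest.raises(ValueError):
            ClassDistribution(np.array([0, 0]))
        d = ClassDistribution(np.array([70, 20, 10]))
        assert d.n == 100
        w = d.weights(8.0)
        assert w[0] < w[1] < w[2] <= 1.0


class TestClassificationLoss:
    def test_perfect_prediction_near_zero(self):
        logits = np.array([[20.0, -20.0], [-20.0, 20.0]])
        targets = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert classification_loss(Tensor(logits), targets).item() < 1e-6

    def test_uniform_scores_closed_form(self):
        logits = np.zeros((1, 4))  # sigmoid = 0.5 everywhere
        targets = np.array([[1.0, 0.0, 0.0, 0.0]])
        out = classification_loss(Tensor(logits), targets, reduction="none")
        np.testing.assert_allclose(out.data, np.full((1, 4), np.log(2.0)), rtol=1e-12)

    def test_random_case_matches_elementwise_oracle(self, rng):
        logits = rng.normal(size=(3, 5))
        targets = rng.uniform(0, 1, size=(3, 5))
        p = 1 / (1 + np.exp(-logits))
        oracle = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum()
        got = classification_loss(Tensor(logits), targets).item()
        assert got == pytest.approx(oracle, rel=1e-9)
        got_p = classification_loss(Tensor(p), targets, from_logits=False).item()
        assert got_p == pytest.approx(oracle, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(Tensor(np.zeros((2, 3))), np.zeros((3, 2)))


class TestDistributionFocalLoss:
    def test_concentrated_on_integer_target(self):
        logits = np.full((1, 17), -30.0)
        logits[0, 5] = 30.0
        out = distribution_focal_loss(Tensor(logits), np.array([5.0]))
        assert out.data[0] < 1e-6

    def test_uniform_distribution_log_k(self):
        k = 17
        logits = np.zeros((1, k))
        out = distribution_focal_loss(Tensor(logits), np.array([5.0]))
        assert out.data[0] == pytest.approx(np.log(k), rel=1e-9)

    def test_mid_bin_interpolated_oracle(self, rng):
        logits = rng.normal(size=(1, 17))
        t = 5.3
        logp = logits - np.log(np.exp(logits - logits.max()).sum()) - logits.max()
        expected = -(0.7 * logp[0, 5] + 0.3 * logp[0, 6])
        out = distribution_focal_loss(Tensor(logits), np.array([t]))
        assert out.data[0] == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            distribution_focal_loss(Tensor(np.zeros((1, 17))), np.array([16.5]))


def _toy_batch(rng, num_classes=4, n_anchors=12):
    """A miniature prediction/assignment pair for composite-loss checks."""
    from reefdet.assigner import AssignmentResult

    cls_logits = Tensor(rng.normal(size=(1, n_anchors, num_classes)), requires_grad=True)
    box_logits = Tensor(rng.normal(size=(1, n_anchors, 4, 17)), requires_grad=True)
    anchors = np.stack([np.arange(n_anchors) * 8 + 4.0,
                        np.full(n_anchors, 4.0)], axis=-1)
    strides = np.full(n_anchors, 8.0)
    pred_boxes = Tensor(np.concatenate([anchors - 6.0, anchors + 6.0], axis=-1)[None],
                        requires_grad=True)
    fg = np.zeros((1, n_anchors), dtype=bool)
    fg[0, [2, 7]] = True
    t_cls = np.zeros((1, n_anchors), dtype=np.int64)
    t_cls[0, 2], t_cls[0, 7] = 1, 3
    t_box = np.zeros((1, n_anchors, 4))
    t_box[0, 2] = anchors[2].tolist() + anchors[2].tolist()
    t_box[0, 2] += np.array([-8, -4, 8, 4.0])
    t_box[0, 7] = anchors[7].tolist() + anchors[7].tolist()
    t_box[0, 7] += np.array([-5, -5, 5, 5.0])
    t_sc = np.zeros((1, n_anchors, num_classes))
    t_sc[0, 2, 1] = 0.8
    t_sc[0, 7, 3] = 0.6
    assigned = AssignmentResult(fg, t_cls, t_box, t_sc)
    preds = {"cls_logits": cls_logits, "box_logits": box_logits,
             "pred_boxes": pred_boxes, "anchors": anchors, "strides": strides}
    return preds, assigned


class TestCompositeLoss:
    def test_eta_one_equals_class_aware_off(self, rng):
        preds, assigned = _toy_batch(rng)
        dist = ClassDistribution(np.array([40, 30, 20, 10]))
        on = composite_loss(preds, assigned, dist,
                            LossConfig(eta=1.0, use_class_aware=True))
        off = composite_loss(preds, assigned, None,
                             LossConfig(use_class_aware=False))
        for k, v in on.floats().items():
            assert v == pytest.approx(off.floats()[k], rel=1e-12)

    def test_all_flags_off_reduces_to_plain_weighted_sum(self, rng):
        """alpha1*BCE + alpha2*DFL + alpha3*CIoU, reconstructed independently."""
        preds, assigned = _toy_batch(rng)
        cfg = LossConfig(use_class_aware=False, use_wiou_v3=False)
        got = composite_loss(preds, assigned, None, cfg)

        tss = assigned.target_scores.sum()
        bce = classification_loss(preds["cls_logits"], assigned.target_scores).item() / tss
        fg = assigned.fg_mask
        w = assigned.target_scores[fg].sum(axis=-1)
        pb = Tensor(preds["pred_boxes"].data[fg])
        ciou = float((ciou_loss_t(pb, Tensor(assigned.target_boxes[fg])).data * w).sum() / tss)
        from reefdet.losses import _encode_ltrb
        nidx = np.nonzero(fg)[1]
        ltrb = _encode_ltrb(assigned.target_boxes[fg], preds["anchors"][nidx],
                            preds["strides"][nidx], cfg.reg_max)
        dfl = distribution_focal_loss(Tensor(preds["box_logits"].data[fg]), ltrb)
        dfl = float((dfl.data.mean(axis=-1) * w).sum() / tss)

        expected = cfg.alpha1 * bce + cfg.alpha2 * dfl + cfg.alpha3 * ciou
        assert got.total.item() == pytest.approx(expected, rel=1e-6)
        assert got.l_cls.item() == pytest.approx(bce, rel=1e-6)
        assert got.l_dfl.item() == pytest.approx(dfl, rel=1e-6)
        assert got.l_box.item() == pytest.approx(ciou, rel=1e-6)

    def test_total_is_configured_combination(self, rng):
        preds, assigned = _toy_batch(rng)
        dist = ClassDistribution(np.array([40, 30, 20, 10]))
        cfg = LossConfig()
        bd = composite_loss(preds, assigned, dist, cfg)
        assert bd.total.item() == pytest.approx(
            cfg.alpha1 * bd.l_cls.item() + cfg.alpha2 * bd.l_dfl.item()
            + cfg.alpha3 * bd.l_box.item(), rel=1e-6)
        assert all(v >= 0 for v in bd.floats().values())

    def test_box_and_dfl_scale_with_class_weight(self, rng):
        """A single assigned target of class s scales box/DFL terms by w(ns)."""
        from reefdet.assigner import AssignmentResult

        preds, assigned = _toy_batch(rng)
        fg = np.zeros_like(assigned.fg_mask)
        fg[0, 7] = True
        single = AssignmentResult(fg, assigned.target_classes,
                                  assigned.target_boxes, assigned.target_scores * fg[..., None])
        counts = np.array([40, 30, 20, 10])
        dist = ClassDistribution(counts)
        lo = composite_loss(preds, single, dist, LossConfig(eta=1.0))
        hi = composite_loss(preds, single, dist, LossConfig(eta=8.0))
        w = class_aware_weight(10, counts.sum(), 8.0)  # class 3 weight
        assert hi.l_box.item() == pytest.approx(w * lo.l_box.item(), rel=1e-9)
        assert hi.l_dfl.item() == pytest.approx(w * lo.l_dfl.item(), rel=1e-9)

    def test_empty_assignment_gives_background_only_loss(self, rng):
        from reefdet.assigner import AssignmentResult

        preds, _ = _toy_batch(rng)
        n = preds["cls_logits"].shape[1]
        empty = AssignmentResult(np.zeros((1, n), dtype=bool),
                                 np.zeros((1, n), dtype=np.int64),
                                 np.zeros((1, n, 4)), np.zeros((1, n, 4)))
        bd = composite_loss(preds, empty, None, LossConfig(use_class_aware=False))
        assert bd.l_box.item() == 0.0
        assert bd.l_dfl.item() == 0.0
        assert bd.l_cls.item() > 0.0

    def test_missing_class_in_distribution_rejected(self, rng):
        preds, assigned = _toy_batch(rng)
        with pytest.raises(ValueError):
            composite_loss(preds, assigned, ClassDistribution(np.array([5, 5])),
                           LossConfig())
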