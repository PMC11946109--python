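"""Detection matching, average precision and mAP summaries against
independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from reefdet.metrics import (
    Detection, GroundTruth, IOU_THRESHOLDS, average_precision,
    map_summary, match_detections, nms,
)


def det(img, cls, box, score):
    return Detection(img, cls, tuple(float(v) for v in box), float(score))


def gt(img, cls, box):
    return GroundTruth(img, cls, tuple(float(v) for v in box))


def reference_ap(scores, tp_flags, n_gt):
    """Independent PR integration: explicit loop over PR points, monotone
    envelope built right-to-left, rectangle-rule integration."""
    if n_gt == 0:
        return None if len(scores) == 0 else 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    points = []
    tp = fp = 0
    for i in order:
        if tp_flags[i]:
            tp += 1
        else:
            fp += 1
        points.append((tp / n_gt, tp / (tp + fp)))
    env = []
    best = 0.0
    for r, p in reversed(points):
        best = max(best, p)
        env.append((r, best))
    env.reverse()
    ap = 0.0
    prev_r = 0.0
    for r, p in env:
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestMatching:
    def test_tp_at_half_fp_at_three_quarters(self):
        g = [gt(0, 0, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 7), 0.9)]  # IoU = 0.7
        assert match_detections(d, g, 0.5).tp.tolist() == [True]
        assert match_detections(d, g, 0.75).tp.tolist() == [False]

    def test_each_gt_matched_at_most_once(self):
        g = [gt(0, 0, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 10), 0.9), det(0, 0, (0, 0, 10, 9), 0.8)]
        m = match_detections(d, g, 0.5)
        assert m.tp.tolist() == [True, False]

    def test_constructed_case_matches_greedy_oracle(self):
        """3 detections, 2 GTs: flags equal an exhaustive greedy reference."""
        g = [gt(0, 0, (0, 0, 10, 10)), gt(0, 0, (20, 0, 30, 10))]
        d = [det(0, 0, (1, 0, 11, 10), 0.95),
             det(0, 0, (0, 0, 10, 10), 0.90),
             det(0, 0, (19, 0, 29, 10), 0.85)]
        m = match_detections(d, g, 0.5)

        # oracle: greedy in confidence order, best unmatched GT by IoU
        def iou(a, b):
            ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
            iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
            inter = ix * iy
            ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
            return inter / ua

        taken = set()
        expected = []
        for dd in sorted(d, key=lambda x: -x.score):
            cands = [(iou(dd.box, gg.box), j) for j, gg in enumerate(g)
                     if j not in taken and iou(dd.box, gg.box) >= 0.5]
            if cands:
                best = max(cands, key=lambda t: (t[0], -t[1]))
                taken.add(best[1])
                expected.append(True)
            else:
                expected.append(False)
        assert m.tp.tolist() == expected

    def test_equal_confidence_tie_break_is_stable(self):
        g = [gt(0, 0, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 9), 0.5), det(0, 0, (0, 0, 10, 10), 0.5)]
        m = match_detections(d, g, 0.5)
        # stable sort keeps original order: first detection wins the GT
        assert m.tp.tolist() == [True, False]


class TestAveragePrecision:
    def test_perfect_detection_ap_one(self):
        g = [gt(0, 0, (0, 0, 10, 10)), gt(1, 0, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 10), 0.9), det(1, 0, (0, 0, 10, 10), 0.8)]
        assert average_precision(match_detections(d, g, 0.5)) == pytest.approx(1.0)

    def test_two_gt_one_tp_one_fp_gives_half(self):
        g = [gt(0, 0, (0, 0, 10, 10)), gt(0, 0, (50, 50, 60, 60))]
        d = [det(0, 0, (0, 0, 10, 10), 0.9), det(0, 0, (100, 100, 110, 110), 0.8)]
        assert average_precision(match_detections(d, g, 0.5)) == pytest.approx(0.5)

    def test_no_detections_zero_ap(self):
        g = [gt(0, 0, (0, 0, 10, 10))]
        assert average_precision(match_detections([], g, 0.5)) == 0.0

    def test_no_gt_no_det_excluded(self):
        assert average_precision(match_detections([], [], 0.5)) is None
        d = [det(0, 0, (0, 0, 10, 10), 0.9)]
        assert average_precision(match_detections(d, [], 0.5)) == 0.0

    def test_invariant_to_order_preserving_confidence_rescale(self, rng):
        g = [gt(0, 0, (i * 20, 0, i * 20 + 10, 10)) for i in range(5)]
        d = [det(0, 0, (i * 20 + rng.uniform(-3, 3), 0, i * 20 + 10, 10),
                 rng.uniform(0.1, 0.9)) for i in range(8)]
        ap1 = average_precision(match_detections(d, g, 0.5))
        rescaled = [Detection(x.image_id, x.class_id, x.box, 0.05 + 0.9 * x.score)
                    for x in d]
        ap2 = average_precision(match_detections(rescaled, g, 0.5))
        assert ap1 == pytest.approx(ap2, abs=1e-12)

    def test_fifty_random_cases_match_reference_integration(self, rng):
        """Implementation vs independent PR-curve integration, 50 random sets."""
        for _ in range(50):
            n_gt = int(rng.integers(1, 10))
            n_det = int(rng.integers(0, 15))
            scores = rng.uniform(0, 1, n_det)
            tp = np.zeros(n_det, dtype=bool)
            n_tp = min(int(rng.integers(0, n_gt + 1)), n_det)
            tp[rng.choice(n_det, size=n_tp, replace=False)] = True if n_det else 0
            from reefdet.metrics import MatchResult
            order = np.argsort(-scores, kind="stable")
            m = MatchResult(scores=scores[order], tp=tp[order], n_gt=n_gt)
            got = average_precision(m)
            want = reference_ap(scores, tp, n_gt)
            assert got == pytest.approx(want, abs=1e-6)


class TestMapSummary:
    def test_single_class_perfect(self):
        g = [gt(0, 0, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 10), 0.9)]
        s = map_summary(d, g, num_classes=1)
        assert s["map50"] == pytest.approx(1.0)
        assert s["map50_95"] == pytest.approx(1.0)

    def test_two_class_hand_average(self):
        g = [gt(0, 0, (0, 0, 10, 10)), gt(0, 1, (20, 20, 30, 30)),
             gt(1, 1, (0, 0, 10, 10))]
        d = [det(0, 0, (0, 0, 10, 10), 0.9),        # class 0: AP 1
             det(0, 1, (20, 20, 30, 30), 0.9),       # class 1: one of two GTs
             det(1, 1, (40, 40, 50, 50), 0.8)]       # class 1 FP
        s = map_summary(d, g, num_classes=2)
        ap0 = 1.0
        ap1 = 0.5  # TP at rank 1 (P=1, R=0.5), FP at rank 2
        assert s["map50"] == pytest.approx((ap0 + ap1) / 2)

    def test_map50_dominates_full_range(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = [gt(0, 0, (i * 30, 0, i * 30 + 20, 20)) for i in range(4)]
            d = [det(0, 0, (i * 30 + r.uniform(0, 8), r.uniform(0, 8),
                            i * 30 + 20 + r.uniform(-4, 4), 20 + r.uniform(-4, 4)),
                     r.uniform(0.2, 1.0)) for i in range(6)]
            s = map_summary(d, g, num_classes=1)
            assert s["map50"] >= s["map50_95"] - 1e-12

    def test_frequency_terciles(self):
        gts, dets = [], []
        # class 0: 6 instances (head), class 1: 3 (middle), class 2: 1 (tail)
        counts = {0: 6, 1: 3, 2: 1}
        for c, k in counts.items():
            for i in range(k):
                box = (i * 20, c * 20, i * 20 + 10, c * 20 + 10)
                gts.append(gt(0, c, box))
                if c != 2:  # tail class goes undetected
                    dets.append(det(0, c, box, 0.9))
        s = map_summary(dets, gts, num_classes=3)
        assert s["stratified"]["head"] == pytest.approx(1.0)
        assert s["stratified"]["middle"] == pytest.approx(1.0)
        assert s["stratified"]["tail"] == pytest.approx(0.0)

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            map_summary([], [], num_classes=0)


class TestNMS:
    def test_suppresses_overlapping_lower_scores(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]])
        scores = np.array([0.9, 0.8, 0.7])
        keep = nms(boxes, scores, iou_threshold=0.5)
        assert keep.tolist() == [0, 2]

    def test_max_det_cap(self):
        boxes = np.array([[i * 30, 0, i * 30 + 10, 10] for i in range(10)])
        scores = np.linspace(0.9, 0.1, 10)
        assert len(nms(boxes, scores, max_det=4)) == 4
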