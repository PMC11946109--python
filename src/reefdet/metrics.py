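"""COCO-style detection metrics.

Detections are matched to ground truths greedily in descending confidence;
a detection becomes a true positive when its best unmatched same-class,
same-image ground truth reaches the IoU threshold (ties on IoU go to the
lowest ground-truth index; equal confidences keep their original order).
Average precision integrates the monotone (all-points interpolated)
precision-recall envelope.  ``map_summary`` reports mAP at IoU 0.5, the
0.50:0.05:0.95 average, a per-class table, and head/middle/tail AP means
over class-frequency terciles — the stratification that exposes
class-imbalance effects in long-tailed species data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import pairwise_iou_xyxy

__all__ = ["Detection", "GroundTruth", "MatchResult", "match_detections",
           "average_precision", "map_summary", "nms", "IOU_THRESHOLDS"]

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    """A scored predicted box (xyxy pixels) on one image."""
    image_id: int
    class_id: int
    box: tuple[float, float, float, float]
    score: float


@dataclass(frozen=True)
class GroundTruth:
    """An annotated box (xyxy pixels) on one image."""
    image_id: int
    class_id: int
    box: tuple[float, float, float, float]


@dataclass
class MatchResult:
    """TP/FP flags for detections of one class at one IoU threshold, ordered
    by descending confidence (stable in the original detection order)."""
    scores: np.ndarray        # (D,) confidences, descending
    tp: np.ndarray            # (D,) bool
    n_gt: int
    gt_matched: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def match_detections(dets: list[Detection], gts: list[GroundTruth],
                     iou_threshold: float) -> MatchResult:
    """Greedy confidence-ordered matching of same-class detections to GTs."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    scores = np.array([dets[i].score for i in order], dtype=np.float64)
    gt_by_img: dict[int, list[int]] = {}
    for j, g in enumerate(gts):
        gt_by_img.setdefault(g.image_id, []).append(j)
    for rank, i in enumerate(order):
        d = dets[i]
        best_iou, best_j = -1.0, -1
        for j in gt_by_img.get(d.image_id, ()):
            if matched[j] or gts[j].class_id != d.class_id:
                continue
            iou = float(pairwise_iou_xyxy([d.box], [gts[j].box])[0, 0])
            if iou >= iou_threshold and iou > best_iou:  # ties keep lowest GT index
                best_iou, best_j = iou, j
        if best_j >= 0:
            matched[best_j] = True
            tp[rank] = True
    return MatchResult(scores=scores, tp=tp, n_gt=len(gts), gt_matched=matched)


def average_precision(match: MatchResult) -> float | None:
    """Area under the monotone all-points-interpolated PR curve.

    Returns ``None`` (class excluded from the mean) when the class has no
    ground truths and no detections; 0.0 when detections exist but no GTs.
    """
    if match.n_gt == 0:
        return None if len(match.scores) == 0 else 0.0
    if len(match.scores) == 0:
        return 0.0
    tp = match.tp.astype(np.float64)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / match.n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone envelope, integrated over recall (all-points interpolation)
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def _per_class_ap(dets, gts, class_ids, thresholds):
    ap = {}
    for c in class_ids:
        dc = [d for d in dets if d.class_id == c]
        gc = [g for g in gts if g.class_id == c]
        ap[c] = {t: average_precision(match_detections(dc, gc, t)) for t in thresholds}
    return ap


def map_summary(dets: list[Detection], gts: list[GroundTruth], num_classes: int,
                thresholds=IOU_THRESHOLDS) -> dict:
    """mAP_0.5, mAP_0.5:0.95, per-class AP table and frequency-stratified AP.

    Classes with no ground truths and no detections are excluded from means;
    terciles (head/middle/tail) are formed on ground-truth frequency among
    classes that have ground truths.
    """
    if num_classes < 1:
        raise ValueError("need at least one class")
    class_ids = list(range(num_classes))
    ap = _per_class_ap(dets, gts, class_ids, thresholds)
    t50 = thresholds[0]

    def class_mean(cids, t):
        vals = [ap[c][t] for c in cids if ap[c][t] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def class_mean_all(cids):
        vals = []
        for c in cids:
            per_t = [ap[c][t] for t in thresholds if ap[c][t] is not None]
            if per_t:
                vals.append(np.mean(per_t))
        return float(np.mean(vals)) if vals else float("nan")

    counts = np.zeros(num_classes, dtype=np.int64)
    for g in gts:
        counts[g.class_id] += 1
    present = [c for c in class_ids if counts[c] > 0]
    strata: dict[str, list[int]] = {"head": [], "middle": [], "tail": []}
    if present:
        order = sorted(present, key=lambda c: (-counts[c], c))
        k = len(order)
        cut1, cut2 = int(np.ceil(k / 3)), int(np.ceil(2 * k / 3))
        strata["head"] = order[:cut1]
        strata["middle"] = order[cut1:cut2]
        strata["tail"] = order[cut2:]

    per_class = {
        c: {
            "n_gt": int(counts[c]),
            "ap50": ap[c][t50],
            "ap": (float(np.mean([ap[c][t] for t in thresholds]))
                   if all(ap[c][t] is not None for t in thresholds) else None),
        }
        for c in class_ids
    }
    return {
        "map50": class_mean(class_ids, t50),
        "map50_95": class_mean_all(class_ids),
        "per_class": per_class,
        "stratified": {name: class_mean(cids, t50) if cids else float("nan")
                       for name, cids in strata.items()},
        "stratified_50_95": {name: class_mean_all(cids) if cids else float("nan")
                             for name, cids in strata.items()},
    }


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float = 0.7,
        max_det: int = 300) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores)))
    keep: list[int] = []
    while order.size and len(keep) < max_det:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        iou = pairwise_iou_xyxy(boxes[[i]], boxes[rest])[0]
        order = rest[iou <= iou_threshold]
    return np.array(keep, dtype=np.int64)
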