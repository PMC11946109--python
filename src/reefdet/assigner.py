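"""Task-aligned assignment of prediction locations to ground-truth boxes.

Each ground truth selects its top-k candidate locations (grid centers lying
inside the box) by the alignment metric ``score^alpha * IoU^beta``; a
location claimed by several ground truths goes to the one with the highest
IoU, ties broken by the lowest ground-truth index, so assignment is
deterministic.  Classification targets are the alignment metric normalised
per ground truth to peak at its best IoU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import pairwise_iou_xyxy

__all__ = ["AssignmentResult", "assign_targets", "encode_box_targets",
           "decode_box_targets"]


@dataclass
class AssignmentResult:
    """Per-location assignment for a batch.

    ``fg_mask`` (B, N) marks foreground locations; each maps to exactly one
    ground truth, whose class/box fill ``target_classes``/``target_boxes``.
    ``target_scores`` (B, N, C) are soft classification targets, zero on
    background locations.
    """

    fg_mask: np.ndarray
    target_classes: np.ndarray
    target_boxes: np.ndarray
    target_scores: np.ndarray

    @property
    def num_foreground(self) -> int:
        return int(self.fg_mask.sum())


def _assign_single(scores: np.ndarray, pred_boxes: np.ndarray, anchors: np.ndarray,
                   gt_boxes: np.ndarray, gt_classes: np.ndarray,
                   topk: int, alpha: float, beta: float):
    """One image; returns (fg, cls, boxes (N,4), scores (N,C))."""
    n, c = scores.shape
    fg = np.zeros(n, dtype=bool)
    t_cls = np.zeros(n, dtype=np.int64)
    t_box = np.zeros((n, 4))
    t_sc = np.zeros((n, c))
    m = len(gt_boxes)
    if m == 0:
        return fg, t_cls, t_box, t_sc

    iou = pairwise_iou_xyxy(gt_boxes, pred_boxes)          # (M, N)
    inside = (
        (anchors[:, 0] >= gt_boxes[:, None, 0]) & (anchors[:, 0] < gt_boxes[:, None, 2])
        & (anchors[:, 1] >= gt_boxes[:, None, 1]) & (anchors[:, 1] < gt_boxes[:, None, 3])
    )                                                       # (M, N)
    cls_score = scores[:, gt_classes].T                     # (M, N)
    align = np.clip(cls_score, 1e-9, None) ** alpha * np.clip(iou, 0, None) ** beta
    align = np.where(inside, align, 0.0)

    candidate = np.zeros_like(inside)
    for g in range(m):
        # stable top-k: sort by (-align, index)
        order = np.lexsort((np.arange(n), -align[g]))[:topk]
        order = order[align[g, order] > 0]
        candidate[g, order] = True

    # resolve locations claimed by multiple ground truths
    claimed = candidate.sum(axis=0)
    if (claimed > 1).any():
        contested = np.nonzero(claimed > 1)[0]
        for j in contested:
            gs = np.nonzero(candidate[:, j])[0]
            best = gs[np.lexsort((gs, -iou[gs, j]))[0]]
            candidate[:, j] = False
            candidate[best, j] = True

    gt_of = candidate.argmax(axis=0)
    fg = candidate.any(axis=0)
    idx = np.nonzero(fg)[0]
    gi = gt_of[idx]
    t_cls[idx] = gt_classes[gi]
    t_box[idx] = gt_boxes[gi]

    # normalised soft targets: align scaled so each GT's best candidate
    # carries its best candidate IoU
    pos_align = np.where(candidate, align, 0.0)
    pos_iou = np.where(candidate, iou, 0.0)
    amax = pos_align.max(axis=1, keepdims=True)
    imax = pos_iou.max(axis=1, keepdims=True)
    norm = pos_align * imax / np.clip(amax, 1e-9, None)
    t_sc[idx, gt_classes[gi]] = norm[gi, idx]
    return fg, t_cls, t_box, t_sc


def assign_targets(scores: np.ndarray, pred_boxes: np.ndarray, anchors: np.ndarray,
                   gt_boxes_list, gt_classes_list, topk: int = 10,
                   alpha: float = 0.5, beta: float = 6.0) -> AssignmentResult:
    """Batched task-aligned assignment (all inputs detached numpy).

    ``scores`` (B, N, C) sigmoid class scores, ``pred_boxes`` (B, N, 4) xyxy
    pixels, ``anchors`` (N, 2) grid centers; ground truths are per-image
    lists of (Mi, 4) xyxy arrays and (Mi,) class vectors.  An image with zero
    ground truths yields an empty foreground set.
    """
    b, n, c = scores.shape
    fg = np.zeros((b, n), dtype=bool)
    t_cls = np.zeros((b, n), dtype=np.int64)
    t_box = np.zeros((b, n, 4))
    t_sc = np.zeros((b, n, c))
    for i in range(b):
        gtb = np.asarray(gt_boxes_list[i], dtype=np.float64).reshape(-1, 4)
        gtc = np.asarray(gt_classes_list[i], dtype=np.int64).reshape(-1)
        fg[i], t_cls[i], t_box[i], t_sc[i] = _assign_single(
            scores[i], pred_boxes[i], anchors, gtb, gtc, topk, alpha, beta
        )
    return AssignmentResult(fg, t_cls, t_box, t_sc)


def encode_box_targets(gt_xyxy: np.ndarray, location: np.ndarray, stride: float,
                       reg_max: int) -> np.ndarray:
    """Left/top/right/bottom distances of ``location`` to the box sides, in
    stride units, clamped to [0, reg_max - 0.01].  The location must lie
    inside the box."""
    gt = np.asarray(gt_xyxy, dtype=np.float64)
    loc = np.asarray(location, dtype=np.float64)
    if not (gt[..., 0] <= loc[..., 0]).all() or not (loc[..., 0] <= gt[..., 2]).all() \
       or not (gt[..., 1] <= loc[..., 1]).all() or not (loc[..., 1] <= gt[..., 3]).all():
        raise ValueError("location lies outside the ground-truth box")
    ltrb = np.stack([
        loc[..., 0] - gt[..., 0], loc[..., 1] - gt[..., 1],
        gt[..., 2] - loc[..., 0], gt[..., 3] - loc[..., 1],
    ], axis=-1) / stride
    return np.clip(ltrb, 0.0, reg_max - 0.01)


def decode_box_targets(ltrb: np.ndarray, location: np.ndarray, stride: float) -> np.ndarray:
    """Inverse of :func:`encode_box_targets` up to clamping."""
    ltrb = np.asarray(ltrb, dtype=np.float64) * stride
    loc = np.asarray(location, dtype=np.float64)
    return np.stack([
        loc[..., 0] - ltrb[..., 0], loc[..., 1] - ltrb[..., 1],
        loc[..., 0] + ltrb[..., 2], loc[..., 1] + ltrb[..., 3],
    ], axis=-1)
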