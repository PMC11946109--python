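"""Detection loss functions: Wise-IoU v1/v3, class-aware reweighting, BCE and
distribution-focal terms, and their composition into the training objective.

The total objective is

    L = alpha1 * L_cls + alpha2 * L_dfl + alpha3 * L_box

where ``L_box`` is either the complete-IoU (CIoU) baseline or the Wise-IoU v3
loss.  Wise-IoU v1 scales the IoU loss by an exponential penalty on the
squared center distance, normalised by the squared diagonal of the smallest
enclosing box (treated as a constant under differentiation):

    L_WIoUv1 = (1 - IoU) * exp(d^2 / (W^2 + H^2)*)

Wise-IoU v3 additionally multiplies by a non-monotonic gradient gain

    kappa = theta / (tau * beta**(theta - tau)),

where the outlier degree ``theta`` is the (detached) IoU loss of the
prediction divided by an exponential running mean of IoU losses over
training.  Boxes of average quality (theta near tau-dependent optimum) get
the largest gain; very good and very bad boxes are both down-weighted.

Class-aware reweighting multiplies each loss contribution by

    w(ns) = (1 - ns/n) / (1 - (ns/n)^eta),

a strictly decreasing function of the class frequency ns/n with w == 1 at
eta == 1 and limit 1/eta as ns/n -> 1: rare species keep full weight while
abundant ones are down-weighted by up to a factor eta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_tensor
from .boxes import Box, DegenerateBoxError, iou_xyxy

__all__ = [
    "WIoUState", "LossConfig", "LossBreakdown", "ClassDistribution",
    "box_iou", "wiou_v1_loss", "wiou_v3_loss", "outlier_degree", "gradient_gain",
    "class_aware_weight", "classification_loss", "distribution_focal_loss",
    "composite_loss", "iou_t", "ciou_loss_t", "wiou_v1_t", "wiou_v3_t",
]


# ---------------------------------------------------------------------------
# class distribution and class-aware weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassDistribution:
    """Per-class training-instance counts ``ns`` and their total ``n``."""

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a 1-D vector with at least one class")
        if (counts < 0).any():
            raise ValueError("class counts must be nonnegative")
        if counts.sum() < 1:
            raise ValueError("total instance count must be >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def num_classes(self) -> int:
        return int(self.counts.size)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def weights(self, eta: float) -> np.ndarray:
        """Class-aware weight vector w(ns, n, eta) for every class."""
        return np.array(
            [class_aware_weight(int(ns), self.n, eta, num_classes=self.num_classes)
             for ns in self.counts]
        )


def class_aware_weight(ns: int, n: int, eta: float, num_classes: int | None = None) -> float:
    """Weight (1 - ns/n) / (1 - (ns/n)^eta) for a class with ns of n instances.

    Decreasing in ns/n for eta > 1, identically 1 for eta == 1, and bounded in
    (1/eta, 1].  A class owning *all* instances is only meaningful for a
    single-class dataset, where the weight is defined as 1; with more than one
    class it violates the distribution invariant and is rejected.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    if ns < 0 or n < 1 or ns > n:
        raise ValueError(f"need 0 <= ns <= n with n >= 1, got ns={ns}, n={n}")
    if ns == n:
        if num_classes is not None and num_classes > 1:
            raise ValueError("ns == n is degenerate for a multi-class dataset")
        return 1.0
    if eta == 1:
        return 1.0
    r = ns / n
    if r == 0.0:
        return 1.0
    # near r = 1 the ratio tends to 1/eta (L'Hopital); the direct formula is
    # already stable for r <= 1 - 1e-12 in double precision
    return float((1.0 - r) / (1.0 - r**eta))


# ---------------------------------------------------------------------------
# Wise-IoU machinery
# ---------------------------------------------------------------------------

@dataclass
class WIoUState:
    """Hyperparameters and running statistics of the Wise-IoU v3 loss.

    ``running_iou_loss_mean`` is an exponential running mean of the detached
    per-box IoU losses, updated once per batch by the trainer; ``momentum`` is
    the retention factor (mean <- m * mean + (1 - m) * batch value).
    """

    beta: float = 1.8
    tau: float = 3.0
    momentum: float = 0.99
    theta_mode: str = "dynamic"  # "dynamic" | "fixed"
    theta_fixed: float = 2.0
    running_iou_loss_mean: float = 1.0
    use_enclosing_normalizer: bool = True

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.tau == 0:
            raise ValueError("tau must be nonzero")
        if not 0 < self.momentum < 1:
            raise ValueError("momentum must lie in (0, 1)")
        if self.theta_mode not in ("dynamic", "fixed"):
            raise ValueError("theta_mode must be 'dynamic' or 'fixed'")
        if self.running_iou_loss_mean <= 0:
            raise ValueError("running_iou_loss_mean must be positive")

    def update(self, batch_iou_loss_mean: float) -> None:
        """Fold one batch's mean detached IoU loss into the running mean."""
        v = float(batch_iou_loss_mean)
        if np.isfinite(v):
            self.running_iou_loss_mean = (
                self.momentum * self.running_iou_loss_mean + (1 - self.momentum) * v
            )


def outlier_degree(iou_loss, state: WIoUState):
    """Abnormality degree theta of a prediction given its (detached) IoU loss."""
    if state.running_iou_loss_mean <= 0:
        raise ValueError("running IoU-loss mean must be positive")
    if state.theta_mode == "fixed":
        return np.broadcast_to(state.theta_fixed, np.shape(iou_loss)).copy() \
            if np.ndim(iou_loss) else state.theta_fixed
    return np.asarray(iou_loss) / state.running_iou_loss_mean if np.ndim(iou_loss) \
        else float(iou_loss) / state.running_iou_loss_mean


def gradient_gain(theta, state: WIoUState):
    """Non-monotonic gain kappa = theta / (tau * beta**(theta - tau))."""
    if state.beta <= 0:
        raise ValueError("beta must be > 0")
    theta = np.asarray(theta, dtype=np.float64)
    kappa = theta / (state.tau * state.beta ** (theta - state.tau))
    return float(kappa) if kappa.ndim == 0 else kappa


# ---------------------------------------------------------------------------
# scalar (Box) API — the formula surface used by oracles and diagnostics
# ---------------------------------------------------------------------------

def box_iou(a: Box, b: Box, img_size: tuple[float, float] | None = None) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    if a.rep is not b.rep:
        if img_size is None:
            raise ValueError("mixed representations require img_size for conversion")
        w, h = img_size
        a, b = a.to_corner_px(w, h), b.to_corner_px(w, h)
    if a.area == 0 and b.area == 0:
        raise DegenerateBoxError("IoU undefined: both boxes have zero area")
    return float(iou_xyxy(a.xyxy(), b.xyxy()))


def wiou_v1_loss(pred: Box, gt: Box, use_enclosing_normalizer: bool = True) -> float:
    """Wise-IoU v1: (1 - IoU) * exp(center_dist^2 / normalizer*).

    The normalizer is the squared diagonal of the smallest box enclosing the
    pair (default) or of the predicted box; either way it is a detached
    constant — no gradient sensitivity flows through it.
    """
    iou = box_iou(pred, gt)
    d2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    if use_enclosing_normalizer:
        px1, py1, px2, py2 = pred.corners()
        gx1, gy1, gx2, gy2 = gt.corners()
        cw = max(px2, gx2) - min(px1, gx1)
        ch = max(py2, gy2) - min(py1, gy1)
    else:
        cw, ch = pred.w, pred.h
    norm = cw**2 + ch**2
    if norm == 0:
        raise DegenerateBoxError("zero normalizer: both box dimensions are zero")
    return float((1.0 - iou) * np.exp(d2 / norm))


def wiou_v3_loss(pred: Box, gt: Box, state: WIoUState) -> tuple[float, float]:
    """Wise-IoU v3 = kappa(theta) * WIoUv1.

    Returns ``(loss, iou_loss)`` where ``iou_loss = 1 - IoU`` is the detached
    quantity the caller folds into the state's running mean (once per batch).
    """
    iou_loss = 1.0 - box_iou(pred, gt)
    theta = outlier_degree(iou_loss, state)
    kappa = gradient_gain(theta, state)
    v1 = wiou_v1_loss(pred, gt, state.use_enclosing_normalizer)
    return float(kappa * v1), float(iou_loss)


# ---------------------------------------------------------------------------
# tensor box losses (batched, differentiable)
# ---------------------------------------------------------------------------

def iou_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Elementwise IoU of (N, 4) xyxy tensors, differentiable w.r.t. pred."""
    gt = as_tensor(gt)
    ix = pred[:, 2].minimum(gt[:, 2]) - pred[:, 0].maximum(gt[:, 0])
    iy = pred[:, 3].minimum(gt[:, 3]) - pred[:, 1].maximum(gt[:, 1])
    inter = ix.clamp(0, None) * iy.clamp(0, None)
    area_p = (pred[:, 2] - pred[:, 0]) * (pred[:, 3] - pred[:, 1])
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = area_p + area_g - inter + 1e-9
    return inter / union


def ciou_loss_t(pred: Tensor, gt: Tensor) -> Tensor:
    """Complete-IoU loss 1 - IoU + d^2/c^2 + alpha*v on (N, 4) xyxy tensors."""
    gt = as_tensor(gt)
    iou = iou_t(pred, gt)
    cw = pred[:, 2].maximum(gt[:, 2]) - pred[:, 0].minimum(gt[:, 0])
    ch = pred[:, 3].maximum(gt[:, 3]) - pred[:, 1].minimum(gt[:, 1])
    c2 = cw**2 + ch**2 + 1e-9
    d2 = ((pred[:, 0] + pred[:, 2] - gt[:, 0] - gt[:, 2]) ** 2
          + (pred[:, 1] + pred[:, 3] - gt[:, 1] - gt[:, 3]) ** 2) * 0.25
    wp = pred[:, 2] - pred[:, 0]
    hp = (pred[:, 3] - pred[:, 1]) + 1e-9
    wg = gt[:, 2] - gt[:, 0]
    hg = (gt[:, 3] - gt[:, 1]) + 1e-9
    v = (4.0 / np.pi**2) * ((wg / hg).arctan() - (wp / hp).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou.data + v.data + 1e-9))  # detached, per CIoU
    return 1.0 - iou + d2 / c2 + alpha * v


def wiou_v1_t(pred: Tensor, gt: Tensor, use_enclosing_normalizer: bool = True) -> Tensor:
    gt = as_tensor(gt)
    iou = iou_t(pred, gt)
    dx = (pred[:, 0] + pred[:, 2] - gt[:, 0] - gt[:, 2]) * 0.5
    dy = (pred[:, 1] + pred[:, 3] - gt[:, 1] - gt[:, 3]) * 0.5
    d2 = dx**2 + dy**2
    if use_enclosing_normalizer:
        cw = np.maximum(pred.data[:, 2], gt.data[:, 2]) - np.minimum(pred.data[:, 0], gt.data[:, 0])
        ch = np.maximum(pred.data[:, 3], gt.data[:, 3]) - np.minimum(pred.data[:, 1], gt.data[:, 1])
    else:
        cw = pred.data[:, 2] - pred.data[:, 0]
        ch = pred.data[:, 3] - pred.data[:, 1]
    norm = Tensor(cw**2 + ch**2 + 1e-9)  # detached normalizer
    return (1.0 - iou) * (d2 / norm).exp()


def wiou_v3_t(pred: Tensor, gt: Tensor, state: WIoUState) -> tuple[Tensor, np.ndarray]:
    """Batched Wise-IoU v3; returns (per-box loss, detached per-box IoU loss)."""
    iou_loss_detached = 1.0 - iou_t(pred, gt).data
    theta = outlier_degree(iou_loss_detached, state)
    kappa = gradient_gain(theta, state)
    v1 = wiou_v1_t(pred, gt, state.use_enclosing_normalizer)
    return Tensor(np.asarray(kappa)) * v1, iou_loss_detached


# ---------------------------------------------------------------------------
# classification and distribution-focal terms
# ---------------------------------------------------------------------------

def classification_loss(scores, targets, from_logits: bool = True,
                        reduction: str = "sum", weights=None):
    """Binary cross-entropy over per-anchor, per-class activations.

    ``weights`` optionally scales each element (broadcastable), which is how
    the class-aware column weights enter.
    """
    scores = as_tensor(scores)
    targets = np.asarray(targets if not isinstance(targets, Tensor) else targets.data)
    if scores.shape != targets.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs targets {targets.shape}")
    if (targets < 0).any() or (targets > 1).any():
        raise ValueError("targets must lie in [0, 1]")
    t = Tensor(targets)
    if from_logits:
        # softplus(x) - x * t, the stable form of -[t log s + (1-t) log(1-s)]
        elem = scores.softplus() - scores * t
    else:
        p = scores.clamp(1e-12, 1 - 1e-12)
        elem = -(t * p.log() + (1.0 - t) * (1.0 - p).log())
    if weights is not None:
        elem = elem * as_tensor(weights)
    if reduction == "none":
        return elem
    if reduction == "mean":
        return elem.mean()
    return elem.sum()


def distribution_focal_loss(pred_bin_logits, target_offset, reduction: str = "none",
                            weights=None):
    """Interpolated cross-entropy on the two bins bracketing a continuous target.

    ``pred_bin_logits``: (..., reg_max + 1) logits over integer distance bins;
    ``target_offset``: (...) continuous values in [0, reg_max].
    """
    logits = as_tensor(pred_bin_logits)
    t = np.asarray(target_offset if not isinstance(target_offset, Tensor)
                   else target_offset.data, dtype=np.float64)
    nbins = logits.shape[-1]
    reg_max = nbins - 1
    if (t < 0).any() or (t > reg_max).any():
        raise ValueError(f"target offsets must lie in [0, {reg_max}]")
    flat = logits.reshape(-1, nbins)
    tf = t.reshape(-1)
    lo = np.clip(np.floor(tf), 0, reg_max - 1).astype(np.int64)
    hi = lo + 1
    w_hi = tf - lo
    w_lo = 1.0 - w_hi
    logp = flat.log_softmax(axis=-1)
    rows = np.arange(tf.size)
    elem = -(Tensor(w_lo) * logp[rows, lo] + Tensor(w_hi) * logp[rows, hi])
    elem = elem.reshape(t.shape)
    if weights is not None:
        elem = elem * as_tensor(weights)
    if reduction == "none":
        return elem
    if reduction == "mean":
        return elem.mean()
    return elem.sum()


# ---------------------------------------------------------------------------
# composite objective
# ---------------------------------------------------------------------------

@dataclass
class LossConfig:
    """Gains and variant flags of the training objective.

    The four ablation combinations are expressed by ``use_class_aware`` /
    ``use_wiou_v3`` (the depth/transformer flags live in the model config).
    """

    alpha1: float = 0.5
    alpha2: float = 1.5
    alpha3: float = 7.5
    eta: float = 8.0
    use_class_aware: bool = True
    use_wiou_v3: bool = True
    reg_max: int = 16
    wiou: WIoUState = field(default_factory=WIoUState)

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.alpha3) <= 0:
            raise ValueError("loss gains must be positive")
        if self.eta < 1:
            raise ValueError("eta must be >= 1")


@dataclass
class LossBreakdown:
    """Per-term values of one composite-loss evaluation (scalar tensors)."""

    l_cls: Tensor
    l_dfl: Tensor
    l_box: Tensor
    total: Tensor
    iou_loss_mean: float | None = None  # detached batch mean for WIoU state update

    def floats(self) -> dict[str, float]:
        return {"l_cls": self.l_cls.item(), "l_dfl": self.l_dfl.item(),
                "l_box": self.l_box.item(), "total": self.total.item()}


def _encode_ltrb(boxes: np.ndarray, anchors: np.ndarray, strides: np.ndarray,
                 reg_max: int) -> np.ndarray:
    """Side distances (left, top, right, bottom) in stride units, clamped."""
    ltrb = np.stack([
        anchors[:, 0] - boxes[:, 0],
        anchors[:, 1] - boxes[:, 1],
        boxes[:, 2] - anchors[:, 0],
        boxes[:, 3] - anchors[:, 1],
    ], axis=-1) / strides[:, None]
    return np.clip(ltrb, 0.0, reg_max - 0.01)


def composite_loss(predictions: dict, assigned, dist: ClassDistribution | None,
                   cfg: LossConfig, state: WIoUState | None = None) -> LossBreakdown:
    """Assemble the weighted objective from raw head outputs and assignments.

    ``predictions`` carries ``cls_logits`` (B, N, C), ``box_logits``
    (B, N, 4, reg_max + 1), decoded ``pred_boxes`` (B, N, 4) xyxy in pixels,
    plus constant ``anchors`` (N, 2) and ``strides`` (N,).  ``assigned`` is an
    :class:`~reefdet.assigner.AssignmentResult`.  Terms are normalised by the
    total assigned target-score mass.
    """
    state = state if state is not None else cfg.wiou
    cls_logits: Tensor = predictions["cls_logits"]
    box_logits: Tensor = predictions["box_logits"]
    pred_boxes: Tensor = predictions["pred_boxes"]
    anchors = np.asarray(predictions["anchors"])
    strides = np.asarray(predictions["strides"])

    num_classes = cls_logits.shape[-1]
    if cfg.use_class_aware:
        if dist is None:
            raise ValueError("class-aware loss requires a ClassDistribution")
        if dist.num_classes != num_classes:
            raise ValueError("distribution does not cover the model's classes")
        cw = dist.weights(cfg.eta)
    else:
        cw = np.ones(num_classes)

    target_scores = assigned.target_scores  # (B, N, C) ndarray
    tss = max(float(target_scores.sum()), 1.0)

    l_cls = classification_loss(
        cls_logits, target_scores, from_logits=True, reduction="sum",
        weights=cw[None, None, :],
    ) * (1.0 / tss)

    fg = assigned.fg_mask  # (B, N) bool
    iou_loss_mean = None
    if fg.any():
        bidx, nidx = np.nonzero(fg)
        tgt_boxes = assigned.target_boxes[bidx, nidx]          # (M, 4)
        tgt_cls = assigned.target_classes[bidx, nidx]          # (M,)
        score_w = target_scores[bidx, nidx].sum(axis=-1)       # (M,)
        w = score_w * cw[tgt_cls]

        pb = pred_boxes[fg]                                    # (M, 4) tensor
        if cfg.use_wiou_v3:
            per_box, iou_loss_det = wiou_v3_t(pb, Tensor(tgt_boxes), state)
            iou_loss_mean = float(iou_loss_det.mean())
        else:
            per_box = ciou_loss_t(pb, Tensor(tgt_boxes))
        l_box = (per_box * Tensor(w)).sum() * (1.0 / tss)

        ltrb = _encode_ltrb(tgt_boxes, anchors[nidx], strides[nidx], cfg.reg_max)
        bl = box_logits[fg]                                    # (M, 4, R+1)
        dfl_elem = distribution_focal_loss(bl, ltrb, reduction="none")
        l_dfl = (dfl_elem.mean(axis=-1) * Tensor(w)).sum() * (1.0 / tss)
    else:
        l_box = Tensor(0.0)
        l_dfl = Tensor(0.0)

    total = cfg.alpha1 * l_cls + cfg.alpha2 * l_dfl + cfg.alpha3 * l_box
    return LossBreakdown(l_cls=l_cls, l_dfl=l_dfl, l_box=l_box, total=total,
                         iou_loss_mean=iou_loss_mean)
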