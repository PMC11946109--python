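"""Seedable SGD training loop for the detector.

One integer seed controls weight initialisation and data order, so repeated
runs in deterministic mode produce identical losses.  The loop follows the
conventional recipe for this detector family: SGD with momentum 0.937 and
weight decay 5e-4 (on convolution/linear weights only), linear warmup into a
cosine learning-rate decay, and the Wise-IoU running mean updated once per
batch from detached IoU losses.  No pretrained weights are used anywhere.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import DetectionModel
from .assigner import assign_targets
from .autograd import Tensor
from .losses import ClassDistribution, LossConfig, composite_loss
from .metrics import Detection, GroundTruth, map_summary, nms

__all__ = ["TrainConfig", "Trainer", "SGD", "predict", "evaluate_model",
           "save_checkpoint", "load_checkpoint", "NonFiniteLossError"]


class NonFiniteLossError(RuntimeError):
    """Raised when a batch produces a NaN/Inf loss; carries a diagnostic dump."""

    def __init__(self, message: str, batch_info: dict):
        super().__init__(message)
        self.batch_info = batch_info


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    lr0: float = 0.02
    lrf: float = 0.01            # final LR as a fraction of lr0
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    grad_clip_norm: float = 10.0
    seed: int = 0
    deterministic: bool = True
    eval_interval: int = 0       # 0 = evaluate only after the final epoch
    conf_threshold: float = 0.001
    nms_iou: float = 0.7
    max_det: int = 300


class SGD:
    """Momentum SGD; weight decay applies to convolution/linear weights only
    (batch-norm scales and all biases are left undecayed)."""

    def __init__(self, named_params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.params = list(named_params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for _, p in self.params]

    def _decayed(self, name: str, p) -> bool:
        return name.endswith("weight") and p.data.ndim > 1

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for (name, p), v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay and self._decayed(name, p):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - lr * v

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()


def cosine_lr(step: int, total_steps: int, warmup_steps: int, lr0: float,
              lrf: float) -> float:
    if warmup_steps > 0 and step < warmup_steps:
        return lr0 * (step + 1) / warmup_steps
    t = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    return lr0 * (lrf + (1 - lrf) * 0.5 * (1 + math.cos(math.pi * min(t, 1.0))))


def _clip_grad_norm(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Trainer:
    """Runs the composite objective over an in-memory dataset.

    ``images``: (N, 3, H, W) float32 in [0, 1]; ``boxes``/``classes``:
    per-image (Mi, 4) xyxy pixel arrays and (Mi,) class vectors.
    """

    def __init__(self, model: DetectionModel, loss_cfg: LossConfig,
                 dist: ClassDistribution | None, cfg: TrainConfig):
        self.model = model
        self.loss_cfg = loss_cfg
        self.dist = dist
        self.cfg = cfg
        self.optimizer = SGD(model.named_parameters(), cfg.lr0, cfg.momentum,
                             cfg.weight_decay)
        self.history: list[dict] = []

    def _epoch_batches(self, n: int, rng: np.random.Generator):
        order = rng.permutation(n)
        bs = self.cfg.batch_size
        for i in range(0, n, bs):
            yield order[i : i + bs]

    def train_step(self, imgs: np.ndarray, boxes_list, classes_list, lr: float) -> dict:
        model, cfg = self.model, self.cfg
        out = model.outputs(Tensor(imgs))
        scores = 1.0 / (1.0 + np.exp(-out["cls_logits"].data))
        assigned = assign_targets(scores, out["pred_boxes"].data, out["anchors"],
                                  boxes_list, classes_list)
        breakdown = composite_loss(out, assigned, self.dist, self.loss_cfg)
        vals = breakdown.floats()
        if not all(np.isfinite(v) for v in vals.values()):
            raise NonFiniteLossError(
                f"non-finite loss {vals}",
                {"losses": vals, "n_fg": assigned.num_foreground,
                 "boxes": [np.asarray(b).tolist() for b in boxes_list]},
            )
        self.optimizer.zero_grad()
        breakdown.total.backward()
        _clip_grad_norm([p for _, p in self.optimizer.params], cfg.grad_clip_norm)
        self.optimizer.step(lr)
        if breakdown.iou_loss_mean is not None:
            self.loss_cfg.wiou.update(breakdown.iou_loss_mean)
        vals["n_fg"] = assigned.num_foreground
        return vals

    def run(self, images: np.ndarray, boxes_list, classes_list,
            val: tuple | None = None, log_path=None, epochs: int | None = None,
            stop_map50: float | None = None) -> list[dict]:
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        n = len(images)
        rng = np.random.default_rng(cfg.seed)
        steps_per_epoch = math.ceil(n / cfg.batch_size)
        total_steps = epochs * steps_per_epoch
        warmup = int(cfg.warmup_epochs * steps_per_epoch)
        step = 0
        writer = None
        if log_path is not None:
            fh = open(log_path, "w", newline="")
            writer = csv.writer(fh)
            writer.writerow(["epoch", "l_cls", "l_dfl", "l_box", "total",
                             "map50", "map50_95"])
        try:
            for epoch in range(epochs):
                self.model.train()
                sums = {"l_cls": 0.0, "l_dfl": 0.0, "l_box": 0.0, "total": 0.0}
                nb = 0
                for batch in self._epoch_batches(n, rng):
                    lr = cosine_lr(step, total_steps, warmup, cfg.lr0, cfg.lrf)
                    vals = self.train_step(
                        images[batch],
                        [boxes_list[i] for i in batch],
                        [classes_list[i] for i in batch],
                        lr,
                    )
                    for k in sums:
                        sums[k] += vals[k]
                    nb += 1
                    step += 1
                row = {k: v / nb for k, v in sums.items()}
                row["epoch"] = epoch
                evaluate_now = (
                    val is not None
                    and (epoch == epochs - 1
                         or (cfg.eval_interval and (epoch + 1) % cfg.eval_interval == 0))
                )
                if evaluate_now:
                    summary = evaluate_model(self.model, *val,
                                             conf=cfg.conf_threshold,
                                             nms_iou=cfg.nms_iou, max_det=cfg.max_det)
                    row["map50"] = summary["map50"]
                    row["map50_95"] = summary["map50_95"]
                    row["summary"] = summary
                self.history.append(row)
                if writer is not None:
                    writer.writerow([epoch, row["l_cls"], row["l_dfl"], row["l_box"],
                                     row["total"], row.get("map50", ""),
                                     row.get("map50_95", "")])
                if stop_map50 is not None and row.get("map50", 0.0) >= stop_map50:
                    break
        finally:
            if writer is not None:
                fh.close()
        return self.history


# ---------------------------------------------------------------------------
# inference and evaluation helpers
# ---------------------------------------------------------------------------

def predict(model: DetectionModel, images: np.ndarray, conf: float = 0.25,
            nms_iou: float = 0.7, max_det: int = 300) -> list[list[Detection]]:
    """Decode, threshold and per-class NMS; returns detections per image."""
    model.eval()
    out = model.outputs(Tensor(np.asarray(images, dtype=np.float32)))
    scores = 1.0 / (1.0 + np.exp(-out["cls_logits"].data))   # (B, N, C)
    boxes = out["pred_boxes"].data                            # (B, N, 4)
    results = []
    big = 1e5
    for i in range(len(images)):
        ns, cs = np.nonzero(scores[i] >= conf)
        if ns.size == 0:
            results.append([])
            continue
        bx = boxes[i, ns]
        sc = scores[i, ns, cs]
        offset_boxes = bx + cs[:, None] * big                 # class-separated NMS
        keep = nms(offset_boxes, sc, iou_threshold=nms_iou, max_det=max_det)
        results.append([
            Detection(image_id=i, class_id=int(cs[k]),
                      box=tuple(np.asarray(bx[k], dtype=float)), score=float(sc[k]))
            for k in keep
        ])
    return results


def evaluate_model(model: DetectionModel, images, boxes_list, classes_list,
                   num_classes: int | None = None, conf: float = 0.001,
                   nms_iou: float = 0.7, max_det: int = 300) -> dict:
    num_classes = num_classes if num_classes is not None else model.cfg.num_classes
    dets_nested = predict(model, images, conf=conf, nms_iou=nms_iou, max_det=max_det)
    dets = [d for per_img in dets_nested for d in per_img]
    gts = [GroundTruth(image_id=i, class_id=int(c), box=tuple(np.asarray(b, dtype=float)))
           for i, (bb, cc) in enumerate(zip(boxes_list, classes_list))
           for b, c in zip(bb, cc)]
    return map_summary(dets, gts, num_classes)


def save_checkpoint(model: DetectionModel, path, extra: dict | None = None) -> None:
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    if extra:
        for k, v in extra.items():
            state[f"meta::{k}"] = np.asarray(v)
    np.savez(path, **state)


def load_checkpoint(model: DetectionModel, path) -> dict:
    data = np.load(path, allow_pickle=False)
    params = {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("param::")}
    model.load_state_dict(params)
    return {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("meta::")}
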