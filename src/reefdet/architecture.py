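"""Detector architecture: CSP (C2f) backbone with optional transformer final
stage, PAN-FPN neck with C2f or transformer fusion blocks, and a decoupled
anchor-free head with a distribution-bin box branch.

The graph is fully determined by :class:`ModelConfig`, so trainable-parameter
counts are exact and reproducible.  Named presets cover the standard
small/medium/large baselines (stage depths 1-2-2-1 / 2-4-4-2 / 3-6-6-3 at
widths 0.50 / 0.75 / 1.00) and the depth-rescaled 6-12-12-6 variants with and
without transformer blocks, whose width and transformer constants were
calibrated once against the published parameter budgets and committed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .autograd import Tensor, concat

__all__ = [
    "ModelConfig", "DetectionModel", "C2f", "SPPF", "TransformerBlock",
    "TransformerStack", "ConvBlock", "count_parameters", "get_preset",
    "PRESET_NAMES", "make_divisible", "make_anchors",
]


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclass(frozen=True)
class ModelConfig:
    """Everything that determines the detector graph (and its parameter count).

    ``stage_depths`` are the bottleneck counts of the four backbone C2f stages
    (the final entry becomes the transformer-stack depth when
    ``use_transformer`` is set); ``neck_depth`` is the bottleneck count of
    each of the four neck fusion blocks.
    """

    num_classes: int = 80
    stage_depths: tuple[int, int, int, int] = (1, 2, 2, 1)
    neck_depth: int = 1
    width_multiple: float = 0.5
    max_channels: int = 1024
    use_transformer: bool = False
    neck_trans_depth: int = 2
    trans_heads: int = 4
    trans_ffn_ratio: float = 2.0
    reg_max: int = 16
    use_sppf: bool = True
    input_size: int = 640

    def __post_init__(self):
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if any(d < 1 for d in self.stage_depths) or self.neck_depth < 1:
            raise ValueError("stage and neck depths must be positive")
        if self.width_multiple <= 0:
            raise ValueError("width_multiple must be positive")

    def channels(self) -> tuple[int, ...]:
        """Scaled channel widths of the five backbone levels."""
        base = (64, 128, 256, 512, 1024)
        ch = tuple(
            make_divisible(min(c, self.max_channels) * self.width_multiple)
            for c in base
        )
        if any(c <= 0 for c in ch):
            raise ValueError("channel scaling produced a non-positive width")
        return ch


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ConvBlock(nn.Module):
    """Conv2d (no bias) + BatchNorm + SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, bias=False)
        self.bn = nn.BatchNorm2d(c2)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(nn.Module):
    def __init__(self, c: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = ConvBlock(c, c, 3)
        self.cv2 = ConvBlock(c, c, 3)
        self.add = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Split-transform-concat block with ``n`` serial bottlenecks.

    The input projection is split in two; one half passes through the serial
    bottleneck chain, and every intermediate output joins the final
    concatenation, widening the gradient path at small parameter cost.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False):
        super().__init__()
        if n < 1:
            raise ValueError("C2f requires at least one bottleneck")
        if c1 < 1 or c2 < 1:
            raise ValueError("channel counts must be positive")
        self.c = c2 // 2
        self.cv1 = ConvBlock(c1, 2 * self.c, 1)
        self.cv2 = ConvBlock((2 + n) * self.c, c2, 1)
        self.m = nn.ModuleList([Bottleneck(self.c, shortcut) for _ in range(n)])

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        ys = [y[:, : self.c], y[:, self.c :]]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three serial k=5 max-pools, concatenated."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBlock(c1, c_, 1)
        self.cv2 = ConvBlock(c_ * 4, c2, 1)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x: Tensor) -> Tensor:
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concat([y0, y1, y2, y3], axis=1))


class TransformerBlock(nn.Module):
    """Pre-norm multi-head self-attention block over flattened feature maps.

    Tokens are the h*w spatial positions of an NCHW feature map (d = channel
    count).  A learnable 1-D positional embedding, produced by a linear layer
    from the normalised token index, is added before attention; both the
    attention and feed-forward sublayers use residual element-wise summation.
    Output shape equals input shape.
    """

    def __init__(self, d: int, heads: int = 4, ffn_ratio: float = 2.0):
        super().__init__()
        if d % heads != 0:
            raise ValueError(f"channel count {d} not divisible by heads {heads}")
        self.d, self.heads = d, heads
        self.pos = nn.Linear(1, d)
        self.ln1 = nn.LayerNorm(d)
        self.qkv = nn.Linear(d, 3 * d)
        self.proj = nn.Linear(d, d)
        self.ln2 = nn.LayerNorm(d)
        f = max(8, make_divisible(d * ffn_ratio, 8))
        self.fc1 = nn.Linear(d, f)
        self.fc2 = nn.Linear(f, d)

    def attend(self, t: Tensor) -> Tensor:
        b, n, d = t.shape
        h, dh = self.heads, d // self.heads
        qkv = self.qkv(t).reshape(b, n, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (b, h, n, dh)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w = x.shape
        t = x.reshape(b, d, h * w).transpose(0, 2, 1)  # (b, n, d)
        idx = (np.arange(h * w, dtype=np.float32) / max(h * w - 1, 1)).reshape(-1, 1)
        # positional embedding feeds the attention path; the residual stream
        # stays untouched, so zeroed sublayers leave the block an identity
        t = t + self.attend(self.ln1(t + self.pos(Tensor(idx))))
        t = t + self.fc2(self.fc1(self.ln2(t)).silu())
        return t.transpose(0, 2, 1).reshape(b, d, h, w)


class TransformerStack(nn.Module):
    def __init__(self, d: int, depth: int, heads: int = 4, ffn_ratio: float = 2.0):
        super().__init__()
        self.blocks = nn.ModuleList(
            [TransformerBlock(d, heads, ffn_ratio) for _ in range(depth)]
        )

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


class TransFuse(nn.Module):
    """Neck fusion block for the transformer variant: 1x1 projection of the
    concatenated inputs followed by a transformer stack."""

    def __init__(self, c1: int, c2: int, depth: int, heads: int, ffn_ratio: float):
        super().__init__()
        self.proj = ConvBlock(c1, c2, 1)
        self.trans = TransformerStack(c2, depth, heads, ffn_ratio)

    def forward(self, x: Tensor) -> Tensor:
        return self.trans(self.proj(x))


# ---------------------------------------------------------------------------
# backbone / neck / head
# ---------------------------------------------------------------------------

class Backbone(nn.Module):
    """Stem + four stride-2 stages; emits features at strides 8, 16, 32."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c1, c2, c3, c4, c5 = cfg.channels()
        d = cfg.stage_depths
        self.stem = ConvBlock(3, c1, 3, 2)
        self.down1 = ConvBlock(c1, c2, 3, 2)
        self.stage1 = C2f(c2, c2, d[0], shortcut=True)
        self.down2 = ConvBlock(c2, c3, 3, 2)
        self.stage2 = C2f(c3, c3, d[1], shortcut=True)
        self.down3 = ConvBlock(c3, c4, 3, 2)
        self.stage3 = C2f(c4, c4, d[2], shortcut=True)
        self.down4 = ConvBlock(c4, c5, 3, 2)
        if cfg.use_transformer:
            self.stage4: nn.Module = TransformerStack(
                c5, d[3], cfg.trans_heads, cfg.trans_ffn_ratio
            )
        else:
            self.stage4 = C2f(c5, c5, d[3], shortcut=True)
        self.sppf = SPPF(c5, c5) if cfg.use_sppf else nn.Identity()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stage1(self.down1(self.stem(x)))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        return p3, p4, p5

    def stage_types(self) -> list[str]:
        return [type(m).__name__ for m in
                (self.stage1, self.stage2, self.stage3, self.stage4)]


class Neck(nn.Module):
    """PAN-FPN: top-down merge then bottom-up aggregation, four fusion blocks."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        _, _, c3, c4, c5 = cfg.channels()
        self.up = nn.Upsample(2)

        def fuse(cin: int, cout: int) -> nn.Module:
            if cfg.use_transformer:
                return TransFuse(cin, cout, cfg.neck_trans_depth,
                                 cfg.trans_heads, cfg.trans_ffn_ratio)
            return C2f(cin, cout, cfg.neck_depth, shortcut=False)

        self.fuse_td1 = fuse(c5 + c4, c4)   # top-down to P4
        self.fuse_td2 = fuse(c4 + c3, c3)   # top-down to P3
        self.down1 = ConvBlock(c3, c3, 3, 2)
        self.fuse_bu1 = fuse(c3 + c4, c4)   # bottom-up to P4
        self.down2 = ConvBlock(c4, c4, 3, 2)
        self.fuse_bu2 = fuse(c4 + c5, c5)   # bottom-up to P5

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor):
        t4 = self.fuse_td1(concat([self.up(p5), p4], axis=1))
        n3 = self.fuse_td2(concat([self.up(t4), p3], axis=1))
        n4 = self.fuse_bu1(concat([self.down1(n3), t4], axis=1))
        n5 = self.fuse_bu2(concat([self.down2(n4), p5], axis=1))
        return n3, n4, n5


class DetectHead(nn.Module):
    """Decoupled anchor-free head: per scale, a class branch (C channels) and
    a box-distribution branch (4 * (reg_max + 1) channels)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        _, _, c3, c4, c5 = cfg.channels()
        chans = (c3, c4, c5)
        nb = 4 * (cfg.reg_max + 1)
        mid_box = max(16, c3 // 4, nb)
        mid_cls = max(c3, min(cfg.num_classes, 100))
        self.nc, self.reg_max = cfg.num_classes, cfg.reg_max
        self.box_branches = nn.ModuleList([
            nn.Sequential(ConvBlock(ch, mid_box, 3), ConvBlock(mid_box, mid_box, 3),
                          nn.Conv2d(mid_box, nb, 1))
            for ch in chans
        ])
        self.cls_branches = nn.ModuleList([
            nn.Sequential(ConvBlock(ch, mid_cls, 3), ConvBlock(mid_cls, mid_cls, 3),
                          nn.Conv2d(mid_cls, cfg.num_classes, 1))
            for ch in chans
        ])
        # bias priors: rare-positive classification, unit box distances
        for br in self.cls_branches:
            br[2].bias.data[:] = -math.log((1 - 0.01) / 0.01)
        for br in self.box_branches:
            br[2].bias.data[:] = 1.0

    def forward(self, feats):
        out = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            out.append((cb(f), bb(f)))
        return out


STRIDES = (8, 16, 32)


def make_anchors(feat_shapes, strides=STRIDES, offset: float = 0.5):
    """Grid-cell center points (pixels) and per-point strides, concatenated
    across scales in P3, P4, P5 order."""
    pts, strs = [], []
    for (h, w), s in zip(feat_shapes, strides):
        xs = (np.arange(w) + offset) * s
        ys = (np.arange(h) + offset) * s
        gx, gy = np.meshgrid(xs, ys)
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(pts, axis=0), np.concatenate(strs, axis=0)


class DetectionModel(nn.Module):
    """Full detector; ``forward`` returns per-scale raw maps, ``outputs``
    returns the flattened tensors the loss and the decoder consume."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        with nn.init_rng(seed):
            self.backbone = Backbone(cfg)
            self.neck = Neck(cfg)
            self.head = DetectHead(cfg)
        self.strides = STRIDES

    def forward(self, x: Tensor):
        p3, p4, p5 = self.backbone(x)
        n3, n4, n5 = self.neck(p3, p4, p5)
        return self.head((n3, n4, n5))

    def outputs(self, x: Tensor) -> dict:
        """Flattened head outputs plus decoded boxes (pixels, xyxy)."""
        raw = self.forward(x)
        b = x.shape[0]
        nc, r1 = self.cfg.num_classes, self.cfg.reg_max + 1
        cls_list, box_list, shapes = [], [], []
        for cls_map, box_map in raw:
            _, _, h, w = cls_map.shape
            shapes.append((h, w))
            cls_list.append(cls_map.reshape(b, nc, h * w).transpose(0, 2, 1))
            box_list.append(box_map.reshape(b, 4, r1, h * w).transpose(0, 3, 1, 2))
        cls_logits = concat(cls_list, axis=1)              # (B, N, C)
        box_logits = concat(box_list, axis=1)              # (B, N, 4, R+1)
        anchors, strides = make_anchors(shapes, self.strides)
        dist = box_logits.softmax(axis=-1) @ Tensor(
            np.arange(r1, dtype=np.float32).reshape(r1, 1)
        )                                                   # (B, N, 4, 1)
        dist = dist[:, :, :, 0] * Tensor(strides.reshape(1, -1, 1).astype(np.float32))
        ax = Tensor(anchors[None, :, 0].astype(np.float32))
        ay = Tensor(anchors[None, :, 1].astype(np.float32))
        from .autograd import stack as t_stack
        pred_boxes = t_stack([
            ax - dist[:, :, 0], ay - dist[:, :, 1],
            ax + dist[:, :, 2], ay + dist[:, :, 3],
        ], axis=-1)
        return {
            "cls_logits": cls_logits,
            "box_logits": box_logits,
            "pred_boxes": pred_boxes,
            "anchors": anchors,
            "strides": strides,
            "feat_shapes": shapes,
        }


# ---------------------------------------------------------------------------
# presets and parameter counting
# ---------------------------------------------------------------------------

# Calibrated constants for the depth-rescaled 6-12-12-6 variants: the width
# and the transformer feed-forward ratio were fitted once to the published
# parameter budgets (26.87 M without transformer, 30.56 M with) and committed.
_PRESETS: dict[str, dict] = {
    "v8n": dict(stage_depths=(1, 2, 2, 1), neck_depth=1, width_multiple=0.25,
                max_channels=1024),
    "v8s": dict(stage_depths=(1, 2, 2, 1), neck_depth=1, width_multiple=0.50,
                max_channels=1024),
    "v8m": dict(stage_depths=(2, 4, 4, 2), neck_depth=2, width_multiple=0.75,
                max_channels=768),
    "v8l": dict(stage_depths=(3, 6, 6, 3), neck_depth=3, width_multiple=1.00,
                max_channels=512),
    "tf-depth-only": dict(stage_depths=(6, 12, 12, 6), neck_depth=6,
                          width_multiple=0.60, max_channels=512),
    "tf-full": dict(stage_depths=(6, 12, 12, 6), neck_depth=6,
                    width_multiple=0.60, max_channels=512,
                    use_transformer=True, neck_trans_depth=3, trans_heads=4,
                    trans_ffn_ratio=3.4),
    "micro": dict(stage_depths=(1, 1, 1, 1), neck_depth=1, width_multiple=0.25,
                  max_channels=256, input_size=64),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str, num_classes: int = 80, **overrides) -> ModelConfig:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kwargs = dict(_PRESETS[name])
    kwargs.update(overrides)
    return ModelConfig(num_classes=num_classes, **kwargs)


def count_parameters(cfg: ModelConfig) -> int:
    """Exact trainable-parameter count of the configured detector."""
    return DetectionModel(cfg, seed=0).count_parameters()
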