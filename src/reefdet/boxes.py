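"""Axis-aligned bounding boxes and plain-numpy box geometry.

Two representations are used throughout the package:

* ``center_norm`` — (cx, cy, w, h) normalised to [0, 1] by the image size,
  the convention of YOLO-style label files;
* ``corner_px`` — the same geometry carried as center/size in pixel units,
  with corners derived as (cx - w/2, ...).

Vectorised helpers operate on ``(..., 4)`` arrays in corner ("xyxy") layout;
the :class:`Box` dataclass is the scalar API used by the loss formulas and
their unit oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["BoxRep", "Box", "DegenerateBoxError", "iou_xyxy", "pairwise_iou_xyxy"]


class DegenerateBoxError(ValueError):
    """Raised when an operation is undefined for zero-area input boxes."""


class BoxRep(str, Enum):
    CENTER_NORM = "center_norm"
    CORNER_PX = "corner_px"


@dataclass(frozen=True)
class Box:
    cx: float
    cy: float
    w: float
    h: float
    rep: BoxRep = BoxRep.CENTER_NORM

    def __post_init__(self):
        if self.w < 0 or self.h < 0:
            raise ValueError(f"box sides must be nonnegative, got w={self.w}, h={self.h}")
        object.__setattr__(self, "rep", BoxRep(self.rep))

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) in the box's own units; x1 <= x2 and y1 <= y2."""
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float,
                     rep: BoxRep = BoxRep.CORNER_PX) -> "Box":
        if x2 < x1 or y2 < y1:
            raise ValueError("corner box requires x1 <= x2 and y1 <= y2")
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1, rep)

    def to_corner_px(self, img_w: float, img_h: float) -> "Box":
        if self.rep is BoxRep.CORNER_PX:
            return self
        return Box(self.cx * img_w, self.cy * img_h, self.w * img_w, self.h * img_h,
                   BoxRep.CORNER_PX)

    def to_center_norm(self, img_w: float, img_h: float) -> "Box":
        if self.rep is BoxRep.CENTER_NORM:
            return self
        return Box(self.cx / img_w, self.cy / img_h, self.w / img_w, self.h / img_h,
                   BoxRep.CENTER_NORM)

    def xyxy(self) -> np.ndarray:
        return np.array(self.corners(), dtype=np.float64)


def _coerce_pair(a: Box, b: Box, img_size: tuple[float, float] | None) -> tuple[Box, Box]:
    if a.rep is b.rep:
        return a, b
    if img_size is None:
        raise ValueError(
            "boxes use different representations; pass img_size=(w, h) to convert"
        )
    w, h = img_size
    return a.to_corner_px(w, h), b.to_corner_px(w, h)


def iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise IoU of corner-layout box arrays with matching shape (..., 4)."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    ix = np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0])
    iy = np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1])
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def pairwise_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs IoU: a (M, 4) x b (N, 4) -> (M, N)."""
    return iou_xyxy(np.asarray(a)[:, None, :], np.asarray(b)[None, :, :])
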