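"""Procedural long-tailed underwater detection scenes.

A stand-in for real reef-fish survey imagery with its key difficulties
controllable: a power-law class-frequency distribution (few abundant
"head" species, many rare "tail" species), small fish-like objects
(ellipse body + triangular tail, class-specific hue/aspect/striping)
composited at low contrast onto a blue-green gradient background with
smooth turbidity noise, optional blur, and bright suspended particles
("marine snow").  Everything derives from a single integer seed, and
identical (spec, seed) pairs produce byte-identical label files.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxes import Box, BoxRep, pairwise_iou_xyxy
from .losses import ClassDistribution

__all__ = ["SyntheticDatasetSpec", "SyntheticDataset", "LabelRecord",
           "sample_class_counts", "render_scene", "generate_dataset"]


@dataclass(frozen=True)
class LabelRecord:
    """One annotated instance: class id plus a normalised center-size box."""
    class_id: int
    box: Box


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Generation parameters; defaults emulate a small long-tailed survey.

    ``powerlaw_exponent`` (gamma) controls class imbalance: class k is drawn
    with probability proportional to (k + 1)^-gamma, so gamma = 0 is uniform
    and gamma around 1.5 gives a max/min count ratio above an order of
    magnitude at realistic totals.
    """

    num_classes: int = 12
    total_images: int = 100
    instances_per_image: tuple[int, int] = (1, 4)
    powerlaw_exponent: float = 1.5
    image_size: int = 64
    blur_sigma: float = 0.8
    particle_density: float = 4e-4   # particles per pixel
    contrast: float = 0.45           # object/background blend in (0, 1]
    max_occlusion_iou: float = 0.3
    min_scale: float = 0.18          # body length relative to image side
    max_scale: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 1 or self.total_images < 1:
            raise ValueError("need at least one class and one image")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")


def sample_class_counts(num_classes: int, gamma: float, total_instances: int,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Multinomial class counts with probabilities ~ rank^(-gamma), adjusted
    so every class keeps at least one instance; sums to ``total_instances``."""
    if num_classes < 1 or gamma < 0:
        raise ValueError("need num_classes >= 1 and gamma >= 0")
    if total_instances < num_classes:
        raise ValueError("total_instances must be >= num_classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = (np.arange(1, num_classes + 1, dtype=np.float64)) ** (-gamma)
    p /= p.sum()
    counts = rng.multinomial(total_instances, p)
    # guarantee >= 1 everywhere by borrowing from the currently largest class
    while (counts == 0).any():
        counts[int(np.argmax(counts == 0))] += 1
        counts[int(np.argmax(counts))] -= 1
    return counts


# ---------------------------------------------------------------------------
# appearance model
# ---------------------------------------------------------------------------

def _class_style(class_id: int, num_classes: int) -> dict:
    """Deterministic per-class appearance: hue, aspect ratio, striping."""
    hue = (class_id / max(num_classes, 1)) % 1.0
    rgb = colorsys.hsv_to_rgb(hue, 0.65, 0.85)
    aspect = 2.0 + 1.2 * ((class_id * 5) % max(num_classes, 1)) / max(num_classes, 1)
    return {"color": np.array(rgb), "aspect": aspect, "stripes": class_id % 3 == 0}


def _fish_mask(size: int, cx: float, cy: float, length: float, aspect: float,
               angle: float) -> np.ndarray:
    """Boolean mask of an ellipse body with a triangular tail."""
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa       # along body axis
    v = -(xx - cx) * sa + (yy - cy) * ca      # across body axis
    a = length / 2.0
    b = a / aspect
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tail: triangle widening from the rear tip of the body
    tail_len = 0.45 * a
    rear = -a
    t = (u - rear) / -tail_len                # 0 at body rear, 1 at tail end
    tail = (t >= 0) & (t <= 1.0) & (np.abs(v) <= b * (0.15 + 0.85 * t))
    return body | tail


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    top = np.array([0.10, 0.36, 0.42])
    bottom = np.array([0.03, 0.15, 0.22])
    g = np.linspace(0.0, 1.0, size)[:, None, None]
    img = top * (1 - g) + bottom * g
    img = np.broadcast_to(img, (size, size, 3)).copy()
    noise = gaussian_filter(rng.normal(0, 1.0, (size, size)), sigma=size / 8.0)
    img += 0.05 * noise[..., None]
    return np.clip(img, 0.0, 1.0)


def render_scene(spec: SyntheticDatasetSpec, instance_classes, rng: np.random.Generator,
                 return_masks: bool = False):
    """Composite the requested instances into one scene.

    Returns ``(image, records)`` — image (H, W, 3) float in [0, 1], records a
    list of :class:`LabelRecord` with tight normalised boxes — plus the
    per-instance boolean masks when ``return_masks`` is set.  Placements that
    would exceed the occlusion cap are retried a bounded number of times;
    instances that cannot be placed are dropped.
    """
    size = spec.image_size
    img = _background(size, rng)
    records: list[LabelRecord] = []
    masks: list[np.ndarray] = []
    placed_boxes: list[np.ndarray] = []
    for cls in instance_classes:
        style = _class_style(int(cls), spec.num_classes)
        for _ in range(20):  # bounded placement retries
            length = rng.uniform(spec.min_scale, spec.max_scale) * size
            angle = rng.uniform(0, 2 * np.pi)
            cx = rng.uniform(0.15 * size, 0.85 * size)
            cy = rng.uniform(0.15 * size, 0.85 * size)
            mask = _fish_mask(size, cx, cy, length, style["aspect"], angle)
            if mask.sum() < 4:
                continue
            ys, xs = np.nonzero(mask)
            box = np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=np.float64)
            if placed_boxes:
                ious = pairwise_iou_xyxy([box], np.stack(placed_boxes))[0]
                if (ious > spec.max_occlusion_iou).any():
                    continue
            color = style["color"].copy()
            shade = np.ones(mask.sum())
            if style["stripes"]:
                yy, xx = np.nonzero(mask)
                ca, sa = np.cos(angle), np.sin(angle)
                u = (xx + 0.5 - cx) * ca + (yy + 0.5 - cy) * sa
                shade = 0.75 + 0.25 * np.sign(np.sin(u * 2 * np.pi / max(length / 3, 1e-6)))
            c = spec.contrast
            img[mask] = (1 - c) * img[mask] + c * (color[None, :] * shade[:, None])
            placed_boxes.append(box)
            masks.append(mask)
            records.append(LabelRecord(int(cls), Box(
                (box[0] + box[2]) / 2 / size, (box[1] + box[3]) / 2 / size,
                (box[2] - box[0]) / size, (box[3] - box[1]) / size,
                BoxRep.CENTER_NORM,
            )))
            break
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    n_particles = rng.poisson(spec.particle_density * size * size)
    for _ in range(n_particles):
        px, py = rng.uniform(0, size, 2)
        r = rng.uniform(0.5, 1.5)
        yy, xx = np.mgrid[0:size, 0:size] + 0.5
        bump = np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * r * r))
        img = img + 0.6 * bump[..., None]
    img = np.clip(img, 0.0, 1.0)
    if return_masks:
        return img, records, masks
    return img, records


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """An in-memory generated dataset with 70/15/15 train/val/test splits."""

    spec: SyntheticDatasetSpec
    images: list
    labels: list
    splits: dict[str, list[int]] = field(default_factory=dict)

    @property
    def class_names(self) -> list[str]:
        return [f"species_{i:03d}" for i in range(self.spec.num_classes)]

    def class_distribution(self, split: str = "train") -> ClassDistribution:
        counts = np.zeros(self.spec.num_classes, dtype=np.int64)
        for i in self.splits[split]:
            for rec in self.labels[i]:
                counts[rec.class_id] += 1
        return ClassDistribution(counts)

    def arrays(self, split: str):
        """(images (N, 3, H, W) float32, per-image xyxy pixel boxes, classes)."""
        idx = self.splits[split]
        size = self.spec.image_size
        imgs = np.stack([self.images[i].transpose(2, 0, 1) for i in idx]).astype(np.float32)
        boxes, classes = [], []
        for i in idx:
            bb, cc = [], []
            for rec in self.labels[i]:
                b = rec.box.to_corner_px(size, size)
                bb.append(b.corners())
                cc.append(rec.class_id)
            boxes.append(np.array(bb, dtype=np.float64).reshape(-1, 4))
            classes.append(np.array(cc, dtype=np.int64))
        return imgs, boxes, classes


def _make_splits(labels, num_classes: int, rng: np.random.Generator) -> dict[str, list[int]]:
    """70/15/15 split by image, adjusted so every class with any instances
    appears in the training split."""
    n = len(labels)
    order = rng.permutation(n).tolist()
    n_train = int(round(0.70 * n))
    n_val = int(round(0.15 * n))
    splits = {"train": order[:n_train],
              "val": order[n_train:n_train + n_val],
              "test": order[n_train + n_val:]}
    present = set()
    for i in splits["train"]:
        present.update(rec.class_id for rec in labels[i])
    everywhere = set()
    for lab in labels:
        everywhere.update(rec.class_id for rec in lab)
    # move one image per missing class from val/test into train (the split
    # ratio drifts by at most a few images on tiny datasets)
    for cls in sorted(everywhere - present):
        if cls in present:
            continue
        for part in ("val", "test"):
            cand = next((i for i in splits[part]
                         if any(r.class_id == cls for r in labels[i])), None)
            if cand is not None:
                splits[part].remove(cand)
                splits["train"].append(cand)
                present.update(r.class_id for r in labels[cand])
                break
    return splits


def generate_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate the full dataset deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.instances_per_image
    per_image = rng.integers(lo, hi + 1, size=spec.total_images)
    total = int(max(per_image.sum(), spec.num_classes))
    counts = sample_class_counts(spec.num_classes, spec.powerlaw_exponent, total, rng)
    pool = np.repeat(np.arange(spec.num_classes), counts)
    rng.shuffle(pool)
    images, labels = [], []
    cursor = 0
    for k in per_image:
        take = pool[cursor:cursor + int(k)]
        cursor += int(k)
        img, recs = render_scene(spec, take, rng)
        images.append(img)
        labels.append(recs)
    splits = _make_splits(labels, spec.num_classes, rng)
    return SyntheticDataset(spec=spec, images=images, labels=labels, splits=splits)
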