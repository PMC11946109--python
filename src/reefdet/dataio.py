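"""Readers and writers for the standard annotation formats.

YOLO text labels (one ``class cx cy w h`` record per line, normalised
center-size coordinates, 6-decimal fixed formatting), dataset-description
YAML (class names plus split directories), COCO-style detection JSON, and
PNG image IO.  Round-trips are exact to the printed precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .boxes import Box, BoxRep
from .losses import ClassDistribution
from .synthetic import LabelRecord, SyntheticDataset

__all__ = [
    "write_yolo_labels", "read_yolo_labels", "write_detections",
    "read_detections", "write_dataset", "write_dataset_yaml",
    "read_dataset_yaml", "export_coco_json", "coco_json_to_records",
    "class_distribution_from_labels", "save_image", "load_image",
]


class LabelParseError(ValueError):
    pass


def write_yolo_labels(records: list[LabelRecord], path) -> None:
    """One ``class cx cy w h`` line per instance, 6-decimal fixed format."""
    lines = []
    for rec in records:
        b = rec.box
        if b.rep is not BoxRep.CENTER_NORM:
            raise ValueError("YOLO labels require normalised center-size boxes")
        for v in (b.cx, b.cy, b.w, b.h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"normalised coordinate out of range: {v}")
        lines.append(f"{rec.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, num_classes: int | None = None) -> list[LabelRecord]:
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as e:
            raise LabelParseError(f"{path}:{ln}: {e}") from None
        if num_classes is not None and not 0 <= cls < num_classes:
            raise LabelParseError(f"{path}:{ln}: class id {cls} outside [0, {num_classes})")
        records.append(LabelRecord(cls, Box(cx, cy, w, h, BoxRep.CENTER_NORM)))
    return records


def write_detections(dets, path) -> None:
    """Detections as ``class cx cy w h score`` lines (normalised boxes)."""
    lines = [f"{c} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f} {s:.6f}"
             for c, cx, cy, w, h, s in dets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections(path):
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise LabelParseError(f"{path}:{ln}: expected 6 fields")
        out.append((int(parts[0]), *(float(p) for p in parts[1:])))
    return out


def save_image(img: np.ndarray, path) -> None:
    """(H, W, 3) float array in [0, 1] -> 8-bit PNG."""
    arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0


def write_dataset_yaml(path, names: list[str], root: str = ".") -> None:
    payload = {
        "path": root,
        "train": "images/train", "val": "images/val", "test": "images/test",
        "nc": len(names),
        "names": {i: n for i, n in enumerate(names)},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_dataset_yaml(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    names = cfg["names"]
    if isinstance(names, dict):
        names = [names[k] for k in sorted(names)]
    cfg["names"] = list(names)
    return cfg


def write_dataset(ds: SyntheticDataset, out_dir, coco: bool = False) -> Path:
    """Materialise a generated dataset as images/labels trees plus YAML."""
    out = Path(out_dir)
    for split, idx in ds.splits.items():
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
        for i in idx:
            stem = f"im{i:05d}"
            save_image(ds.images[i], out / "images" / split / f"{stem}.png")
            write_yolo_labels(ds.labels[i], out / "labels" / split / f"{stem}.txt")
    write_dataset_yaml(out / "dataset.yaml", ds.class_names, root=".")
    if coco:
        for split in ds.splits:
            export_coco_json(ds, split, out / f"annotations_{split}.json")
    return out


def export_coco_json(ds: SyntheticDataset, split: str, path) -> dict:
    """COCO detection JSON (xywh pixel boxes, positive areas) for one split."""
    size = ds.spec.image_size
    images, annotations = [], []
    ann_id = 1
    for i in ds.splits[split]:
        images.append({"id": i, "file_name": f"im{i:05d}.png",
                       "width": size, "height": size})
        for rec in ds.labels[i]:
            b = rec.box.to_corner_px(size, size)
            x1, y1, x2, y2 = b.corners()
            annotations.append({
                "id": ann_id, "image_id": i, "category_id": rec.class_id,
                "bbox": [x1, y1, x2 - x1, y2 - y1],
                "area": (x2 - x1) * (y2 - y1), "iscrowd": 0,
            })
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for i, n in enumerate(ds.class_names)],
    }
    Path(path).write_text(json.dumps(payload))
    return payload


def coco_json_to_records(path_or_dict) -> dict[int, list[LabelRecord]]:
    """COCO JSON -> per-image normalised label records (inverse of export)."""
    if isinstance(path_or_dict, dict):
        payload = path_or_dict
    else:
        payload = json.loads(Path(path_or_dict).read_text())
    dims = {im["id"]: (im["width"], im["height"]) for im in payload["images"]}
    out: dict[int, list[LabelRecord]] = {im["id"]: [] for im in payload["images"]}
    for ann in payload["annotations"]:
        w, h = dims[ann["image_id"]]
        x, y, bw, bh = ann["bbox"]
        out[ann["image_id"]].append(LabelRecord(
            int(ann["category_id"]),
            Box((x + bw / 2) / w, (y + bh / 2) / h, bw / w, bh / h, BoxRep.CENTER_NORM),
        ))
    return out


def load_yolo_dataset(yaml_path, split: str = "train"):
    """Load one split of an on-disk YOLO-format dataset.

    Returns ``(images (N, 3, H, W) float32, boxes, classes, names)`` with
    per-image xyxy pixel boxes.  Images in one split must share a size.
    """
    yaml_path = Path(yaml_path)
    cfg = read_dataset_yaml(yaml_path)
    root = Path(cfg.get("path", yaml_path.parent))
    if not root.is_absolute():
        root = (yaml_path.parent / root).resolve()
    img_dir = root / cfg[split]
    names = cfg["names"]
    imgs, boxes, classes = [], [], []
    for img_path in sorted(img_dir.glob("*.png")):
        img = load_image(img_path)
        h, w = img.shape[:2]
        label_path = root / "labels" / split / f"{img_path.stem}.txt"
        recs = read_yolo_labels(label_path, num_classes=len(names)) \
            if label_path.exists() else []
        bb = np.array([r.box.to_corner_px(w, h).corners() for r in recs],
                      dtype=np.float64).reshape(-1, 4)
        cc = np.array([r.class_id for r in recs], dtype=np.int64)
        imgs.append(img.transpose(2, 0, 1).astype(np.float32))
        boxes.append(bb)
        classes.append(cc)
    if not imgs:
        raise FileNotFoundError(f"no images found under {img_dir}")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"images in split {split!r} have mixed sizes: {shapes}")
    return np.stack(imgs), boxes, classes, names


def class_distribution_from_labels(label_dir, num_classes: int) -> ClassDistribution:
    """Instance counts per class over every ``.txt`` label file in a directory."""
    counts = np.zeros(num_classes, dtype=np.int64)
    files = sorted(Path(label_dir).glob("**/*.txt"))
    if not files:
        raise FileNotFoundError(f"no YOLO label files under {label_dir}")
    for f in files:
        for rec in read_yolo_labels(f, num_classes=num_classes):
            counts[rec.class_id] += 1
    return ClassDistribution(counts)
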