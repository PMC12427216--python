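"""YOLO-format annotation I/O, dataset splitting and online augmentation.

Labels are darknet-style text: one ``class cx cy w h`` line per object with
normalised centre coordinates.  A dataset is a manifest file listing one
image path per line; each image ``x.png`` has its labels in ``x.txt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import BoundingBox


@dataclass
class AnnotationRecord:
    image_id: str
    boxes: list = field(default_factory=list)

    def validate(self):
        for b in self.boxes:
            b.validate()
        if sum(1 for b in self.boxes if b.class_id == 1) > 1:
            raise ValueError(
                f"{self.image_id}: a piglet being born (class 1) can appear "
                "at most once per image")
        return self

    def counts(self, num_classes: int = 2) -> list:
        out = [0] * num_classes
        for b in self.boxes:
            if 0 <= b.class_id < num_classes:
                out[b.class_id] += 1
        return out


@dataclass
class DatasetIndex:
    train: list
    val: list
    test: list
    ratios: tuple
    seed: int


# ---------------------------------------------------------------------------
# label I/O
# ---------------------------------------------------------------------------

def read_yolo_labels(text: str, image_id: str = "<memory>") -> AnnotationRecord:
    """Parse YOLO label text; errors carry the offending line number."""
    boxes = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"{image_id}: line {lineno}: expected 5 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            vals = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise ValueError(f"{image_id}: line {lineno}: non-numeric token") from exc
        if cls < 0:
            raise ValueError(f"{image_id}: line {lineno}: negative class id")
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"{image_id}: line {lineno}: coordinate out of [0,1]")
        box = BoundingBox(cls, *vals)
        box.validate()
        boxes.append(box)
    return AnnotationRecord(image_id, boxes)


def write_yolo_labels(record: AnnotationRecord) -> str:
    lines = [f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
             for b in record.boxes]
    return "\n".join(lines) + ("\n" if lines else "")


def load_labels(path) -> AnnotationRecord:
    path = Path(path)
    return read_yolo_labels(path.read_text(), image_id=path.stem)


def save_labels(record: AnnotationRecord, path):
    Path(path).write_text(write_yolo_labels(record))


def read_manifest(path) -> list:
    base = Path(path).parent
    return [str((base / line.strip())) for line in Path(path).read_text().splitlines()
            if line.strip()]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(ids, ratios=(0.75, 0.15, 0.10), seed: int = 0) -> DatasetIndex:
    """Random disjoint train/val/test partition, deterministic given the seed.

    Train and validation sizes are floored; the remainder goes to the test
    set.  The split is meant to be performed once and persisted.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot split an empty id list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(ratios[0] * len(ids)))
    n_val = int(np.floor(ratios[1] * len(ids)))
    order = [ids[i] for i in perm]
    return DatasetIndex(order[:n_train], order[n_train:n_train + n_val],
                        order[n_train + n_val:], tuple(ratios), seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    hflip_prob: float = 0.5
    crop_prob: float = 0.3
    crop_min_scale: float = 0.6
    brightness_prob: float = 0.3
    brightness_range: tuple = (0.7, 1.3)
    mosaic_prob: float = 0.0   # mosaic is applied explicitly via `mosaic`
    min_visibility: float = 0.1  # fraction of original area kept after crop
    max_retries: int = 10


def hflip(image: np.ndarray, record: AnnotationRecord):
    out = AnnotationRecord(record.image_id, [
        BoundingBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in record.boxes])
    return image[:, ::-1].copy(), out


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    return np.clip(image.astype(np.float32) * factor, 0, 255).astype(np.uint8)


def _crop_boxes(boxes, x0, y0, w, h, min_visibility):
    """Remap normalised boxes into the crop window, dropping low-visibility ones."""
    out = []
    for b in boxes:
        bx1, by1, bx2, by2 = b.as_xyxy()
        nx1 = max(bx1, x0)
        ny1 = max(by1, y0)
        nx2 = min(bx2, x0 + w)
        ny2 = min(by2, y0 + h)
        if nx2 <= nx1 or ny2 <= ny1:
            continue
        vis = ((nx2 - nx1) * (ny2 - ny1)) / (b.w * b.h)
        if vis < min_visibility:
            continue
        out.append(BoundingBox(
            b.class_id,
            ((nx1 + nx2) / 2 - x0) / w, ((ny1 + ny2) / 2 - y0) / h,
            (nx2 - nx1) / w, (ny2 - ny1) / h))
    return out


def random_crop(image, record, rng, cfg: AugmentConfig):
    ih, iw = image.shape[:2]
    for _ in range(cfg.max_retries):
        scale = rng.uniform(cfg.crop_min_scale, 1.0)
        w, h = scale, scale
        x0 = rng.uniform(0, 1 - w)
        y0 = rng.uniform(0, 1 - h)
        boxes = _crop_boxes(record.boxes, x0, y0, w, h, cfg.min_visibility)
        if boxes or not record.boxes:
            px0, py0 = int(x0 * iw), int(y0 * ih)
            pw, ph = int(w * iw), int(h * ih)
            crop = image[py0:py0 + ph, px0:px0 + pw]
            return crop, AnnotationRecord(record.image_id, boxes)
    return image, record  # degenerate crops exhausted retries: identity


def augment(image: np.ndarray, record: AnnotationRecord, cfg: AugmentConfig,
            seed: int):
    """Photometric + geometric augmentation, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    if rng.random() < cfg.hflip_prob:
        image, record = hflip(image, record)
    if rng.random() < cfg.crop_prob:
        image, record = random_crop(image, record, rng, cfg)
    if rng.random() < cfg.brightness_prob:
        image = adjust_brightness(image, rng.uniform(*cfg.brightness_range))
    record.validate()
    return image, record


def mosaic(images: list, records: list, canvas_size: int, seed: int,
           min_visibility: float = 0.1):
    """Compose four annotated images into one canvas (2×2 mosaic).

    Each source image is resized into its quadrant by nearest-neighbour
    sampling; boxes are remapped into canvas coordinates and clipped.
    """
    assert len(images) == 4 and len(records) == 4
    rng = np.random.default_rng(seed)
    s = canvas_size
    cx = int(rng.uniform(0.35, 0.65) * s)
    cy = int(rng.uniform(0.35, 0.65) * s)
    canvas = np.zeros((s, s, 3), dtype=np.uint8)
    quads = [(0, 0, cx, cy), (cx, 0, s - cx, cy), (0, cy, cx, s - cy),
             (cx, cy, s - cx, s - cy)]
    boxes = []
    for (qx, qy, qw, qh), img, rec in zip(quads, images, records):
        if qw < 1 or qh < 1:
            continue
        ih, iw = img.shape[:2]
        yi = (np.arange(qh) * ih / qh).astype(int)
        xi = (np.arange(qw) * iw / qw).astype(int)
        canvas[qy:qy + qh, qx:qx + qw] = img[yi][:, xi]
        for b in rec.boxes:
            bx1, by1, bx2, by2 = b.as_xyxy()
            nx1 = (qx + bx1 * qw) / s
            ny1 = (qy + by1 * qh) / s
            nx2 = (qx + bx2 * qw) / s
            ny2 = (qy + by2 * qh) / s
            if nx2 <= nx1 or ny2 <= ny1:
                continue
            area0 = (nx2 - nx1) * (ny2 - ny1)
            cx1, cy1 = max(nx1, 0.0), max(ny1, 0.0)
            cx2, cy2 = min(nx2, 1.0), min(ny2, 1.0)
            if cx2 <= cx1 or cy2 <= cy1:
                continue
            if (cx2 - cx1) * (cy2 - cy1) < min_visibility * area0:
                continue
            boxes.append(BoundingBox(b.class_id, (cx1 + cx2) / 2, (cy1 + cy2) / 2,
                                     cx2 - cx1, cy2 - cy1))
    # the mosaic can merge two class-1 sources; keep only the largest
    class1 = [b for b in boxes if b.class_id == 1]
    if len(class1) > 1:
        keep = max(class1, key=lambda b: b.w * b.h)
        boxes = [b for b in boxes if b.class_id != 1 or b is keep]
    rec = AnnotationRecord("mosaic", boxes)
    rec.validate()
    return canvas, rec
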