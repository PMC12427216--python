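"""Synthetic farrowing-crate scene generator.

Emulates the statistical structure of overhead/rear-view farrowing-crate
images so that training and evaluation runs need no external data: textured
floor background, class-0 piglets as rotated textured ellipses with spatial
clustering, an optional class-1 piglet (one being born, at most one by
definition) partially emerged at a fixed sow-rear region, crate-bar stripes
that partially occlude piglets (present in 91% of scenes by default, the
frequency reported for the real data), and local overexposure patches from
heat lamps (11% of scenes by default).

Piglets are deliberately schematic rather than photorealistic — the
generator exists to exercise detection mechanism (assignment, losses,
counting), not appearance modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import BoundingBox
from .data_io import AnnotationRecord, write_yolo_labels


@dataclass
class SceneSpec:
    canvas: int = 640
    n_class0: int | None = None     # None: truncated Poisson, mean 6, on {0..14}
    has_class1: bool = False
    occlusion_prob: float = 0.91
    overexposure_prob: float = 0.11
    cluster_tightness: float = 0.5  # 0 = uniform placement, 1 = tight cluster
    box_mode: str = "visible"       # or "amodal": keep full-body extents
    seed: int = 0

    def validate(self):
        if self.canvas < 64:
            raise ValueError("canvas must be at least 64 px")
        if not (0 <= self.occlusion_prob <= 1 and 0 <= self.overexposure_prob <= 1):
            raise ValueError("probabilities must lie in [0,1]")
        if self.box_mode not in ("visible", "amodal"):
            raise ValueError(f"unknown box_mode {self.box_mode!r}")
        return self


@dataclass
class SceneInfo:
    occluded: bool
    overexposed: bool
    n_placed: int


def _truncated_poisson(rng, mean=6.0, hi=14):
    while True:
        k = rng.poisson(mean)
        if k <= hi:
            return int(k)


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(spec: SceneSpec):
    """Render one scene; returns (image, record, info).

    Fully deterministic given ``spec.seed``.  If a piglet cannot be placed
    within the retry budget the scene simply contains fewer piglets (with a
    warning); the annotation record is authoritative for counts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s = spec.canvas
    # floor: mid-dark slatted concrete with mild texture
    base = rng.uniform(70, 95)
    img = np.full((s, s, 3), base, dtype=np.float32)
    img += rng.normal(0, 6, size=(s, s, 1))
    slat = (np.sin(np.arange(s) * 2 * np.pi / max(24, s // 12))[None, :, None] * 4)
    img += slat

    n0 = spec.n_class0 if spec.n_class0 is not None else _truncated_poisson(rng)
    boxes = []
    masks = []
    # cluster centre pulled toward the middle of the pen
    ccy = rng.uniform(0.3, 0.7) * s
    ccx = rng.uniform(0.3, 0.7) * s
    body = 0.09 * s  # semi-major axis of a piglet body
    placed_centres = []
    n_placed = 0
    for _ in range(n0):
        ok = False
        for _try in range(20):
            spread = (1.0 - 0.75 * spec.cluster_tightness) * 0.45 * s
            cy = np.clip(rng.normal(ccy, spread), body, s - body)
            cx = np.clip(rng.normal(ccx, spread), body, s - body)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (0.55 * body) ** 2
                   for py, px in placed_centres):
                ok = True
                break
        if not ok:
            warnings.warn("piglet placement retries exhausted; scene has fewer piglets")
            continue
        placed_centres.append((cy, cx))
        a = body * rng.uniform(0.85, 1.15)
        b = a * rng.uniform(0.45, 0.6)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(s, s, cy, cx, a, b, theta)
        colour = np.array([225, 190, 185]) + rng.normal(0, 8, 3)  # pinkish-white
        img[mask] = colour + rng.normal(0, 5, (int(mask.sum()), 3))
        masks.append((0, mask))
        n_placed += 1

    if spec.has_class1:
        # sow rear region: fixed band at the top-centre of the crate; the
        # piglet is partially emerged, so only ~half the body is visible
        cy = 0.12 * s + rng.uniform(-0.02, 0.02) * s
        cx = 0.5 * s + rng.uniform(-0.08, 0.08) * s
        a = body * 0.8
        b = a * 0.55
        mask = _ellipse_mask(s, s, cy, cx, a, b, np.pi / 2)
        mask[: int(cy - 0.2 * a), :] = False  # body still inside the birth canal
        img[mask] = np.array([200, 150, 150]) + rng.normal(0, 6, (int(mask.sum()), 3))
        masks.append((1, mask))

    occluded = bool(rng.random() < spec.occlusion_prob)
    bar_mask = np.zeros((s, s), dtype=bool)
    if occluded:
        for _ in range(rng.integers(2, 5)):
            width = max(2, int(rng.uniform(0.015, 0.03) * s))
            pos = rng.integers(0, s - width)
            if rng.random() < 0.5:
                bar_mask[:, pos:pos + width] = True
            else:
                bar_mask[pos:pos + width, :] = True
        img[bar_mask] = np.array([45, 45, 50]) + rng.normal(0, 3, (int(bar_mask.sum()), 3))

    overexposed = bool(rng.random() < spec.overexposure_prob)
    if overexposed:
        cy = rng.uniform(0.2, 0.8) * s
        cx = rng.uniform(0.2, 0.8) * s
        r = rng.uniform(0.08, 0.18) * s
        glow = _ellipse_mask(s, s, cy, cx, r, r, 0.0)
        img[glow] = np.clip(img[glow] + 140, 0, 255)

    for cls, mask in masks:
        visible = mask & ~bar_mask if (occluded and spec.box_mode == "visible") else mask
        if visible.sum() < 9:  # fully hidden: not annotated
            continue
        ys, xs = np.nonzero(visible)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append(BoundingBox(cls, (x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                                 (x2 - x1) / s, (y2 - y1) / s).clipped().validate())

    record = AnnotationRecord(f"scene_{spec.seed}", boxes)
    record.validate()
    image = np.clip(img, 0, 255).astype(np.uint8)
    return image, record, SceneInfo(occluded, overexposed, n_placed)


def generate_dataset(out_dir, n_images: int, base_spec: SceneSpec | None = None,
                     seed: int = 0, class1_prob: float = 0.5):
    """Write ``n_images`` scenes (PNG + YOLO txt + manifest) to ``out_dir``.

    Per-image seeds are derived reproducibly from the master seed, so the
    whole dataset regenerates byte-identically.  Returns (manifest_path,
    records, infos).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_spec or SceneSpec()
    master = np.random.default_rng(seed)
    records, infos, names = [], [], []
    for i in range(n_images):
        child_seed = int(master.integers(0, 2**31 - 1))
        has1 = bool(master.random() < class1_prob)
        spec = SceneSpec(canvas=base.canvas, n_class0=base.n_class0,
                         has_class1=has1, occlusion_prob=base.occlusion_prob,
                         overexposure_prob=base.overexposure_prob,
                         cluster_tightness=base.cluster_tightness,
                         box_mode=base.box_mode, seed=child_seed)
        image, record, info = generate_scene(spec)
        name = f"scene_{i:04d}"
        record.image_id = name
        Image.fromarray(image).save(out / f"{name}.png")
        (out / f"{name}.txt").write_text(write_yolo_labels(record))
        records.append(record)
        infos.append(info)
        names.append(f"{name}.png")
    manifest = out / "manifest.txt"
    manifest.write_text("\n".join(names) + "\n")
    return manifest, records, infos
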