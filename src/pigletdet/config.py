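"""Model configuration and shared geometric types.

The detector works on RGB images with YOLO-style normalised annotations:
a box is (class_id, cx, cy, w, h) with all coordinates in [0,1] relative to
the image, centre-based, origin at the top-left pixel corner.

Two classes exist in the farrowing-crate task: class 0 — freely moving
pre-weaning piglets; class 1 — a piglet in the process of being born, which
by definition occurs at most once per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class BoundingBox:
    """Normalised centre-format box. Clipped boxes must lie in the unit square."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box centre out of range: {self}")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box extent out of range: {self}")
        eps = 1e-6
        if (self.cx - self.w / 2 < -eps or self.cx + self.w / 2 > 1 + eps
                or self.cy - self.h / 2 < -eps or self.cy + self.h / 2 > 1 + eps):
            raise ValueError(f"box exceeds unit square: {self}")
        return self

    def clipped(self) -> "BoundingBox":
        """Clip the box to the unit square, preserving the centre format."""
        x1 = max(0.0, self.cx - self.w / 2)
        y1 = max(0.0, self.cy - self.h / 2)
        x2 = min(1.0, self.cx + self.w / 2)
        y2 = min(1.0, self.cy + self.h / 2)
        return BoundingBox(self.class_id, (x1 + x2) / 2, (y1 + y2) / 2,
                           max(x2 - x1, 1e-9), max(y2 - y1, 1e-9))

    def as_xyxy(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass
class Detection:
    box: BoundingBox
    score: float

    def validate(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"detection score out of range: {self.score}")
        return self


@dataclass
class ModelConfig:
    """Central configuration for the detector, training and evaluation.

    Defaults follow the published training recipe (100 epochs, batch 16,
    learning rate 1e-3, IoU threshold 0.5, alignment default_alpha 0.5,
    three chunks in the multi-scale attention block).
    """

    input_size: int = 640
    num_classes: int = 2
    backbone_widths: tuple = (48, 96, 144, 192)
    n_chunks: int = 3
    # MSPA C2f internals (frozen by the configuration enumeration, see docs)
    bottleneck_expansion: float = 0.25
    cia_reduction: int = 4
    # neck widths (defaults calibrated so the assembled detector sits near the
    # published 1.249 M-parameter total; see docs/methods.md)
    local_width: int = 72
    fused_width: int = 86       # global/injected width; TIM requires equal widths
    ifm_blocks: int = 2
    # head
    head_depth: int = 2
    reg_max: int = 16
    # assignment / loss
    default_alpha: float = 0.5
    beta: float = 6.0
    topk: int = 10
    loss_weights: tuple = (0.5, 7.5, 1.5)  # cls, box, dfl
    # training
    max_epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 0.001
    optimizer: str = "sgd"
    momentum: float = 0.9
    warmup_epochs: int = 3
    # evaluation
    iou_threshold: float = 0.5
    conf_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self):
        self.backbone_widths = tuple(self.backbone_widths)
        self.loss_weights = tuple(self.loss_weights)
        if self.n_chunks < 2:
            raise ValueError("n_chunks must be >= 2")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie in (0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.default_alpha <= 1.0):
            raise ValueError("default_alpha must lie in [0,1]")
        if self.topk < 1:
            raise ValueError("topk must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    # -- file round-trip ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, **kw) -> "ModelConfig":
        d = self.to_dict()
        d.update(kw)
        return ModelConfig(**d)
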