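"""Full detector assembly: MSPA backbone → GD neck → single task-aligned head."""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.autograd import Tensor
from .backbone import Backbone
from .config import ModelConfig
from .evalcount import nms
from .head import TaskAlignedHead, HeadOutputs, decode_detections
from .neck import GDNeck


class PigletDetector(nn.Module):
    """Single-scale piglet detector with counting support.

    The backbone emits the B2..B5 pyramid (strides 4/8/16/32); the
    gather-and-distribute neck fuses all levels into one stride-8 map F_GD;
    the task-aligned head predicts per-anchor class scores and discretised
    box-side distributions on that single scale.
    """

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        nn.manual_seed(self.config.seed)
        self.backbone = Backbone(self.config)
        self.neck = GDNeck(self.config)
        self.head = TaskAlignedHead(self.config.fused_width, self.config.num_classes,
                                    self.config.reg_max, self.config.head_depth)

    def forward(self, images: Tensor) -> HeadOutputs:
        return self.head(self.neck(self.backbone(images)))

    # -- inference ------------------------------------------------------------
    def detect(self, images: np.ndarray, conf_threshold=None, iou_threshold=None):
        """Run inference on a float images array (N,3,H,W) in [0,1].

        Returns one score-sorted, NMS-filtered detection list per image with
        normalised boxes.
        """
        cfg = self.config
        conf = cfg.conf_threshold if conf_threshold is None else conf_threshold
        iou = cfg.iou_threshold if iou_threshold is None else iou_threshold
        self.eval()
        with nn.no_grad():
            out = self.forward(Tensor(images.astype(np.float32)))
        raw = decode_detections(out, (images.shape[2], images.shape[3]), conf)
        return [nms(dets, iou) for dets in raw]

    # -- weight archive -------------------------------------------------------
    def save_weights(self, path):
        np.savez(path, **self.state_dict())

    def load_weights(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def preprocess_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8 image → CHW float32 in [0,1]."""
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)
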