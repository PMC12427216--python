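"""Single task-aligned detection head.

The head consumes only the fused stride-8 map F_GD, so the assembled model
has exactly one detection scale and H·W anchors (one per grid cell).  A
shared task-interactive extractor — a short stack of modulated deformable
convolutions — feeds two task-specific feature decompositions (layer
attention over the stack, refined by another deformable convolution), which
emit classification logits and a discretised box-side distribution.

Box parameterisation is distribution-focal style: for each anchor the four
side distances (left, top, right, bottom, in stride units) are each a
categorical distribution over reg_max+1 bins; decoding takes the softmax
expectation, which keeps decoded widths/heights non-negative by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .config import BoundingBox, Detection
from .neck import FusedFeature


@dataclass
class HeadOutputs:
    cls_logits: Tensor        # (N, A, num_classes)
    box_dist: Tensor          # (N, A, 4, reg_max+1)
    anchor_points: np.ndarray  # (A, 2) grid-cell centres (x, y) in stride units
    stride: int
    grid_hw: tuple


def make_anchor_points(h: int, w: int) -> np.ndarray:
    """Grid-cell centres in stride units: (x + 0.5, y + 0.5), row-major."""
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1).astype(np.float64)


class DeformConvUnit(nn.Module):
    """DCNv2 followed by batch-norm and SiLU."""

    def __init__(self, cin, cout):
        super().__init__()
        self.dcn = nn.DeformConv2d(cin, cout, 3)
        self.bn = nn.BatchNorm2d(cout)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.bn(self.dcn(x)))


class SharedExtractor(nn.Module):
    """Task-interactive feature extractor; returns all intermediate maps."""

    def __init__(self, c, depth=2):
        super().__init__()
        self.units = nn.ModuleList([DeformConvUnit(c, c) for _ in range(depth)])

    def forward(self, x: Tensor) -> list:
        maps = []
        for u in self.units:
            x = u(x)
            maps.append(x)
        return maps


class FeatureDecomposition(nn.Module):
    """Layer attention over the extractor stack, one instance per task.

    Globally pooled stack features pass through a bottlenecked projection and
    a sigmoid to yield one gate per stack layer; the gated sum is refined by
    a deformable convolution.
    """

    def __init__(self, c, depth, reduction=4):
        super().__init__()
        self.depth = depth
        hidden = max(1, depth * c // reduction)
        self.fc1 = nn.Linear(depth * c, hidden, bias=True)
        self.fc2 = nn.Linear(hidden, depth, bias=True)
        self.refine = nn.DeformConv2d(c, c, 3)

    def attention(self, stack: list) -> Tensor:
        n = stack[0].shape[0]
        pooled = ag.concat(
            [ag.adaptive_avg_pool2d(m, (1, 1)).reshape((n, m.shape[1])) for m in stack],
            axis=1)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(pooled))))  # (N, depth)

    def forward(self, stack: list) -> Tensor:
        if not stack:
            raise ValueError("empty feature stack")
        w = self.attention(stack)
        n = stack[0].shape[0]
        mixed = stack[0] * w[:, 0].reshape((n, 1, 1, 1))
        for i in range(1, len(stack)):
            mixed = mixed + stack[i] * w[:, i].reshape((n, 1, 1, 1))
        return self.refine(mixed)


class TaskAlignedHead(nn.Module):
    def __init__(self, c, num_classes=2, reg_max=16, depth=2, stride=8):
        super().__init__()
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.stride = stride
        self.extractor = SharedExtractor(c, depth)
        self.cls_decomp = FeatureDecomposition(c, depth)
        self.reg_decomp = FeatureDecomposition(c, depth)
        self.cls_pred = nn.Conv2d(c, num_classes, 1, bias=True)
        # start classification at a low-confidence prior for stable early loss
        self.cls_pred.bias.data[:] = -4.0
        self.reg_pred = nn.Conv2d(c, 4 * (reg_max + 1), 1, bias=True)

    def forward(self, fused: FusedFeature) -> HeadOutputs:
        x = fused.map
        n, _, h, w = x.shape
        stack = self.extractor(x)
        cls_map = self.cls_pred(self.cls_decomp(stack))      # (N, nc, H, W)
        reg_map = self.reg_pred(self.reg_decomp(stack))      # (N, 4*(R+1), H, W)
        a = h * w
        cls_logits = cls_map.reshape((n, self.num_classes, a)).transpose((0, 2, 1))
        box_dist = reg_map.reshape((n, 4, self.reg_max + 1, a)).transpose((0, 3, 1, 2))
        return HeadOutputs(cls_logits, box_dist, make_anchor_points(h, w),
                           fused.stride, (h, w))


def decode_distances(box_dist: Tensor, reg_max: int) -> Tensor:
    """Expectation of the per-side bin distribution, in stride units."""
    probs = ag.softmax(box_dist, axis=-1)
    bins = Tensor(np.arange(reg_max + 1, dtype=box_dist.data.dtype).reshape(-1, 1))
    return ag.matmul(probs, bins)[..., 0]  # (N, A, 4)


def decode_pred_boxes(outputs: HeadOutputs) -> Tensor:
    """Predicted boxes (x1, y1, x2, y2) in stride units, differentiable."""
    d = decode_distances(outputs.box_dist, outputs.box_dist.shape[-1] - 1)
    ax = Tensor(outputs.anchor_points[None, :, 0].astype(d.data.dtype))
    ay = Tensor(outputs.anchor_points[None, :, 1].astype(d.data.dtype))
    x1 = ax - d[:, :, 0]
    y1 = ay - d[:, :, 1]
    x2 = ax + d[:, :, 2]
    y2 = ay + d[:, :, 3]
    stacked = [t.reshape(t.shape + (1,)) for t in (x1, y1, x2, y2)]
    return ag.concat(stacked, axis=2)  # (N, A, 4)


def decode_detections(outputs: HeadOutputs, img_size, conf_threshold: float = 0.25):
    """Decode raw head outputs into per-image lists of normalised detections."""
    if isinstance(img_size, int):
        img_size = (img_size, img_size)
    ih, iw = img_size
    n = outputs.cls_logits.shape[0]
    with nn.no_grad():
        scores = 1.0 / (1.0 + np.exp(-outputs.cls_logits.data))     # (N, A, nc)
        boxes = decode_pred_boxes(outputs).data * outputs.stride    # pixels
    results = []
    for i in range(n):
        dets = []
        keep = np.argwhere(scores[i] >= conf_threshold)
        for a, c in keep:
            x1, y1, x2, y2 = boxes[i, a]
            x1, x2 = np.clip([x1, x2], 0, iw)
            y1, y2 = np.clip([y1, y2], 0, ih)
            if x2 - x1 <= 0 or y2 - y1 <= 0:
                continue
            box = BoundingBox(int(c), (x1 + x2) / 2 / iw, (y1 + y2) / 2 / ih,
                              (x2 - x1) / iw, (y2 - y1) / ih)
            dets.append(Detection(box, float(scores[i, a, c])))
        results.append(dets)
    return results
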