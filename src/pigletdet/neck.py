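"""Gather-and-Distribute neck with ConvNeXt-V2 global fusion.

The neck gathers all four pyramid levels into one global representation and
injects it back at a single scale:

* **LAF** — local gathering of the shallow levels B2..B4, size-unified to
  B3 (stride 8): B2 average-pooled down, B4 bilinearly up-sampled, B3 passed
  through a 1×1 convolution; concatenated and projected.
* **FAM + IFM** — all four levels aligned to B4's size (stride 16),
  concatenated, fused by a 1×1 convolution and refined by a stack of
  ConvNeXt-V2 blocks (7×7 depthwise conv → layer norm → 4× MLP with GELU and
  global response normalisation → projection, residual).
* **TIM** — the global feature is copied to two branches: a sigmoid gate on
  the projected local feature, and a residual addition; copies are resampled
  to the local size (average pooling when the global map is larger,
  bilinear interpolation otherwise) and the fusion is refined by a terminal
  ConvNeXt-V2 block.

The fused map F_GD lives at the local feature's size (stride 8), which is
the single scale the detection head consumes — piglets are mid/small objects
in 640-pixel frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .backbone import PyramidLevels
from .config import ModelConfig


@dataclass
class FusedFeature:
    map: Tensor
    stride: int


def resample_to(global_feat: Tensor, target_hw) -> Tensor:
    """Resample a feature map to ``target_hw`` by the gather-distribute rule:
    strictly larger maps are average-pooled, smaller ones bilinearly
    interpolated, equal sizes pass through unchanged."""
    gh, gw = global_feat.shape[2], global_feat.shape[3]
    th, tw = target_hw
    if (gh, gw) == (th, tw):
        return global_feat
    if gh >= th and gw >= tw:
        return ag.adaptive_avg_pool2d(global_feat, (th, tw))
    return ag.interpolate_bilinear(global_feat, (th, tw))


class GRN(nn.Module):
    """Global response normalisation: per-channel spatial-norm competition.

    y = gamma * (x * n) + beta + x with n_c = g_c / mean_c(g) and
    g_c the spatial L2 norm of channel c.  gamma and beta start at zero, so
    a fresh block is the identity.
    """

    _countable = True

    def __init__(self, c, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32), requires_grad=True)

    def forward(self, x):
        g = ((x ** 2).sum(axis=(2, 3), keepdims=True) + self.eps) ** 0.5
        n = g / (g.mean(axis=1, keepdims=True) + self.eps)
        return self.gamma * (x * n) + self.beta + x


class ConvNeXtV2Block(nn.Module):
    def __init__(self, c):
        super().__init__()
        self.dwconv = nn.Conv2d(c, c, 7, padding=3, groups=c, bias=True)
        self.norm = nn.LayerNormChannels(c)
        self.pw1 = nn.Conv2d(c, 4 * c, 1, bias=True)
        self.act = nn.GELU()
        self.grn = GRN(4 * c)
        self.pw2 = nn.Conv2d(4 * c, c, 1, bias=True)

    def forward(self, x):
        y = self.pw2(self.grn(self.act(self.pw1(self.norm(self.dwconv(x))))))
        return x + y


class LAF(nn.Module):
    """Lightweight adjacent-layer fusion of B2, B3, B4 at B3's size."""

    def __init__(self, c2, c3, c4, c_local):
        super().__init__()
        self.conv_mid = nn.Conv2d(c3, c3, 1, bias=True)
        self.proj = nn.ConvBnAct(c2 + c3 + c4, c_local, 1)

    def forward(self, b2: Tensor, b3: Tensor, b4: Tensor) -> Tensor:
        h3, w3 = b3.shape[2], b3.shape[3]
        if b2.shape[2] != 2 * h3 or b2.shape[3] != 2 * w3 \
                or h3 != 2 * b4.shape[2] or w3 != 2 * b4.shape[3]:
            raise ValueError("B2/B3/B4 sizes are not a stride-4/8/16 pyramid of one image")
        down = ag.avg_pool2d(b2, 2)
        mid = self.conv_mid(b3)
        up = ag.interpolate_bilinear(b4, (h3, w3))
        return self.proj(ag.concat([down, mid, up], axis=1))


class FAMIFM(nn.Module):
    """Feature alignment to B4's size plus ConvNeXt-V2 information fusion."""

    def __init__(self, widths, c_global, n_blocks=2):
        super().__init__()
        c2, c3, c4, c5 = widths
        self.fuse = nn.ConvBnAct(c2 + c3 + c4 + c5, c_global, 1)
        self.blocks = nn.ModuleList([ConvNeXtV2Block(c_global) for _ in range(n_blocks)])

    def forward(self, levels: PyramidLevels) -> Tensor:
        b2, b3, b4, b5 = levels
        target = (b4.shape[2], b4.shape[3])
        aligned = [resample_to(b2, target), resample_to(b3, target), b4,
                   resample_to(b5, target)]
        x = self.fuse(ag.concat(aligned, axis=1))
        for blk in self.blocks:
            x = blk(x)
        return x


class TIM(nn.Module):
    """Information injection: gate the local feature with the global one."""

    def __init__(self, c_local, c_fused):
        super().__init__()
        self.c_fused = c_fused
        self.local_proj = nn.Conv2d(c_local, c_fused, 1, bias=True)
        self.refine = ConvNeXtV2Block(c_fused)

    def forward(self, local: Tensor, global_feat: Tensor) -> FusedFeature:
        if global_feat.shape[1] != self.c_fused:
            raise ValueError(
                f"global feature width {global_feat.shape[1]} irreconcilable with "
                f"fused width {self.c_fused}")
        target = (local.shape[2], local.shape[3])
        g = resample_to(global_feat, target)
        gate = ag.sigmoid(g)
        fused = gate * self.local_proj(local) + g
        return FusedFeature(self.refine(fused), stride=8)


class GDNeck(nn.Module):
    """LAF + FAM/IFM + TIM producing the single fused map F_GD at stride 8."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        w = config.backbone_widths
        self.laf = LAF(w[0], w[1], w[2], config.local_width)
        self.famifm = FAMIFM(w, config.fused_width, config.ifm_blocks)
        self.tim = TIM(config.local_width, config.fused_width)

    def forward(self, levels: PyramidLevels) -> FusedFeature:
        local = self.laf(levels.B2, levels.B3, levels.B4)
        global_feat = self.famifm(levels)
        return self.tim(local, global_feat)
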