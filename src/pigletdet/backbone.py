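"""Backbone: the Multi-Scale Spatial Pyramid Attention (MSPA) C2f block.

The block replaces the standard YOLOv8 C2f unit.  It has four stages:

* **EHPC** (enhanced hierarchical-phantom convolution): the input is split
  along channels into three chunks F1..F3; F̂1 = Conv1(F1), F̂2 =
  Conv2(F̂1 ⊕ F2), F̂3 = Bottleneck(F̂2 ⊕ F3), where ⊕ is element-wise
  summation and Conv1/Conv2 are 1×1 convolutions.  The branches are
  concatenated and projected by a 1×1 convolution Conv3 to the output width.
* **SPA** (spatial pyramid aggregation): per branch, a descriptor of length
  5ω — the per-channel global mean (ω) concatenated with the flattened 2×2
  adaptive average pooling (4ω).
* **CIA** (channel interaction attention): a bottlenecked two-layer
  projection 5ω → d → ω with ReLU and sigmoid, yielding per-channel gates.
* **Softmax** across the three chunks, per channel; the resulting weights
  rescale the branches before the Conv3 aggregation.

Internal hyperparameters that the block's published description leaves open
(compression of the 1×1 convolutions, bottleneck expansion, CIA reduction
ratio, bias/normalisation placement) were resolved by enumerating the small
discrete configuration space against the published parameter count of the
block at the 64-in/128-out comparison configuration; the unique match is
frozen as the default: biased, norm-free 1×1 convolutions; bottleneck
expansion 0.25 with batch-norm; a single CIA shared across the three chunks
with hidden width ⌊5ω/4⌋.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .config import ModelConfig


# ---------------------------------------------------------------------------
# channel chunking
# ---------------------------------------------------------------------------

def chunk_widths(channels: int, n_chunks: int) -> tuple:
    """Even channel partition; remainder channels go to the earliest chunks."""
    if channels < n_chunks:
        raise ValueError(f"cannot split {channels} channels into {n_chunks} chunks")
    base, rem = divmod(channels, n_chunks)
    return tuple(base + (1 if i < rem else 0) for i in range(n_chunks))


def split_channels(x: Tensor, n_chunks: int) -> list:
    """Split an NCHW feature map into contiguous, order-preserving chunks."""
    widths = chunk_widths(x.shape[1], n_chunks)
    offs = np.cumsum((0,) + widths)
    return [x[:, lo:hi] for lo, hi in zip(offs[:-1], offs[1:])]


# ---------------------------------------------------------------------------
# reference C2f (YOLOv8 baseline block, used for the complexity comparison)
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    """Two 3×3 convolutions with an optional residual connection."""

    def __init__(self, cin, cout, shortcut=True, e=1.0):
        super().__init__()
        hidden = max(1, int(cout * e))
        self.cv1 = nn.ConvBnAct(cin, hidden, 3)
        self.cv2 = nn.ConvBnAct(hidden, cout, 3)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Standard YOLOv8 'faster CSP bottleneck with two convolutions'."""

    def __init__(self, cin, cout, n=1, shortcut=True, e=0.5):
        super().__init__()
        self.c = int(cout * e)
        self.cv1 = nn.ConvBnAct(cin, 2 * self.c, 1)
        self.cv2 = nn.ConvBnAct((2 + n) * self.c, cout, 1)
        self.bottlenecks = nn.ModuleList(
            [Bottleneck(self.c, self.c, shortcut, e=1.0) for _ in range(n)]
        )

    def forward(self, x):
        y = split_channels(self.cv1(x), 2)
        for b in self.bottlenecks:
            y.append(b(y[-1]))
        return self.cv2(ag.concat(y, axis=1))


# ---------------------------------------------------------------------------
# MSPA C2f
# ---------------------------------------------------------------------------

class EHPC(nn.Module):
    """Split / Conv / element-wise sum / concat hierarchy (without Conv3)."""

    def __init__(self, cin, n_chunks=3, expansion=0.25):
        super().__init__()
        self.n_chunks = n_chunks
        w = chunk_widths(cin, n_chunks)
        self.widths = w
        # 1×1 convolutions with bias, no normalisation (frozen configuration);
        # Conv1 maps chunk 1 onto chunk 2's width so the ⊕ sums typecheck.
        self.conv1 = nn.Conv2d(w[0], w[1], 1, bias=True)
        self.conv2 = nn.Conv2d(w[1], w[2], 1, bias=True)
        self.bottleneck = Bottleneck(w[2], w[2], shortcut=True, e=expansion)

    @property
    def branch_widths(self) -> tuple:
        w = self.widths
        return (w[1], w[2], w[2])

    def branches(self, x: Tensor) -> list:
        chunks = split_channels(x, self.n_chunks)
        f1 = self.conv1(chunks[0])
        if f1.shape[1] != chunks[1].shape[1]:
            raise ValueError("chunk width mismatch prevents element-wise summation")
        f2 = self.conv2(f1 + chunks[1])
        if f2.shape[1] != chunks[2].shape[1]:
            raise ValueError("chunk width mismatch prevents element-wise summation")
        f3 = self.bottleneck(f2 + chunks[2])
        return [f1, f2, f3]


def spa_forward(fhat: Tensor) -> Tensor:
    """Spatial pyramid aggregation descriptor of one branch.

    Returns (N, 5ω): per-channel global mean (ω) followed by the flattened
    2×2 adaptive average pooling (4ω, channel-major then row-major spatial).
    """
    n, c, h, w = fhat.shape
    if h < 2 or w < 2:
        raise ValueError("SPA needs spatial size >= 2 in both dimensions")
    global_ = ag.adaptive_avg_pool2d(fhat, (1, 1)).reshape((n, c))
    local = ag.adaptive_avg_pool2d(fhat, (2, 2)).reshape((n, 4 * c))
    return ag.concat([global_, local], axis=1)


class CIA(nn.Module):
    """Channel interaction attention: 5ω → d → ω with ReLU then sigmoid."""

    def __init__(self, omega: int, reduction: int = 4):
        super().__init__()
        self.omega = omega
        d = (5 * omega) // reduction
        if d < 1:
            raise ValueError(f"CIA hidden width collapsed to {d} (omega={omega}, r={reduction})")
        self.down = nn.Linear(5 * omega, d, bias=True)
        self.up = nn.Linear(d, omega, bias=True)

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[-1] != 5 * self.omega:
            raise ValueError(f"descriptor length {z.shape[-1]} != 5*omega={5 * self.omega}")
        return ag.sigmoid(self.up(ag.relu(self.down(z))))


def mspa_softmax_weights(vs: list) -> list:
    """Softmax across the chunk axis, independently per channel."""
    stacked = ag.concat([v.reshape((1,) + v.shape) for v in vs], axis=0)
    sm = ag.softmax(stacked, axis=0)
    return [sm[i] for i in range(len(vs))]


class MSPAC2f(nn.Module):
    """The full multi-scale spatial pyramid attention block."""

    def __init__(self, cin, cout, n_chunks=3, expansion=0.25, reduction=4):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.ehpc = EHPC(cin, n_chunks, expansion)
        bw = self.ehpc.branch_widths
        if len(set(bw)) != 1:
            raise ValueError(
                f"branch widths {bw} differ; the chunk-wise softmax needs equal widths "
                f"(choose cin with cin mod {n_chunks} != {n_chunks - 1})")
        self.omega = bw[0]
        # one CIA shared across the three branches (frozen configuration)
        self.cia = CIA(self.omega, reduction)
        self.conv3 = nn.Conv2d(sum(bw), cout, 1, bias=True)

    def ehpc_forward(self, x: Tensor) -> Tensor:
        """EHPC only: aggregation without attention reweighting."""
        return self.conv3(ag.concat(self.ehpc.branches(x), axis=1))

    def forward(self, x: Tensor) -> Tensor:
        branches = self.ehpc.branches(x)
        vs = [self.cia(spa_forward(f)) for f in branches]
        ws = mspa_softmax_weights(vs)
        n = x.shape[0]
        weighted = [f * w.reshape((n, self.omega, 1, 1)) for f, w in zip(branches, ws)]
        return self.conv3(ag.concat(weighted, axis=1))


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

@dataclass
class PyramidLevels:
    """Backbone outputs at strides 4, 8, 16 and 32 of the input image."""

    B2: Tensor
    B3: Tensor
    B4: Tensor
    B5: Tensor

    def __iter__(self):
        return iter((self.B2, self.B3, self.B4, self.B5))


class Backbone(nn.Module):
    """YOLOv8n-style backbone with every C2f position using MSPA C2f."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        w2, w3, w4, w5 = config.backbone_widths
        nc, e, r = config.n_chunks, config.bottleneck_expansion, config.cia_reduction
        self.stem = nn.ConvBnAct(3, max(8, w2 // 2), 3, stride=2)
        self.down2 = nn.ConvBnAct(max(8, w2 // 2), w2, 3, stride=2)
        self.c2 = MSPAC2f(w2, w2, nc, e, r)
        self.down3 = nn.ConvBnAct(w2, w3, 3, stride=2)
        self.c3 = MSPAC2f(w3, w3, nc, e, r)
        self.down4 = nn.ConvBnAct(w3, w4, 3, stride=2)
        self.c4 = MSPAC2f(w4, w4, nc, e, r)
        self.down5 = nn.ConvBnAct(w4, w5, 3, stride=2)
        self.c5 = MSPAC2f(w5, w5, nc, e, r)

    def forward(self, x: Tensor) -> PyramidLevels:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size ({h},{w}) must be divisible by 32; "
                "letterbox-pad the image first")
        b2 = self.c2(self.down2(self.stem(x)))
        b3 = self.c3(self.down3(b2))
        b4 = self.c4(self.down4(b3))
        b5 = self.c5(self.down5(b4))
        return PyramidLevels(b2, b3, b4, b5)
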