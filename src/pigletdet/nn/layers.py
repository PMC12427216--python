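"""Neural-network layers on top of the autograd engine.

Module tree conventions follow the familiar torch-style API surface
(``parameters()``, ``state_dict()``, ``train()/eval()``) so the detector
code reads like any other detection codebase.  All feature maps are NCHW.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_rng = np.random.default_rng(0)


def manual_seed(seed: int):
    """Seed the global weight-initialisation stream."""
    global _rng
    _rng = np.random.default_rng(seed)


# A thread-unsafe but simple profiler hook used by the accounting module:
# when `_profile_sink` is a list, every leaf layer appends (layer, macs).
_profile_sink = None


class profile_macs:
    """Context manager collecting per-layer multiply-accumulate counts."""

    def __init__(self):
        self.entries = []

    def __enter__(self):
        global _profile_sink
        self._prev = _profile_sink
        _profile_sink = self.entries
        return self

    def __exit__(self, *exc):
        global _profile_sink
        _profile_sink = self._prev
        return False


def _record(layer, macs: int):
    if _profile_sink is not None:
        _profile_sink.append((layer, int(macs)))


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- tree walking ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = "") -> Iterator[tuple]:
        yield prefix, self
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield (f"{prefix}.{name}" if prefix else name), val
        for name, child in self._children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- weight archive (flat name -> array) ----------------------------------
    buffer_names: tuple = ()  # non-learnable arrays persisted alongside weights

    def named_buffers(self, prefix: str = ""):
        for mod_name, m in self.named_modules(prefix):
            for bname in m.buffer_names:
                key = f"{mod_name}.{bname}" if mod_name else bname
                yield key, m, bname

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        for key, m, bname in self.named_buffers():
            out[key] = np.array(getattr(m, bname))
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = {key: (m, bname) for key, m, bname in self.named_buffers()}
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, v in state.items():
            if k in bufs:
                m, bname = bufs[k]
                setattr(m, bname, np.array(v, dtype=np.float32))
                continue
            arr = np.asarray(v, dtype=own[k].data.dtype)
            if arr.shape != own[k].data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {own[k].data.shape}")
            own[k].data = arr


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = list(mods)

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def append(self, m):
        self.mods.append(m)


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in):
    bound = math.sqrt(2.0 / fan_in) if fan_in > 0 else 0.0
    return (_rng.standard_normal(shape) * bound).astype(np.float32)


class Conv2d(Module):
    """Plain convolution (optionally biased); no normalisation, no activation."""

    def __init__(self, cin, cout, k, stride=1, padding=None, groups=1, bias=True,
                 zero_init=False):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        w = np.zeros((cout, cin // groups, k, k), dtype=np.float32) if zero_init else _kaiming(
            (cout, cin // groups, k, k), fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        _record(self, (self.cin // self.groups) * self.k * self.k * self.cout
                * out.data.shape[-2] * out.data.shape[-1])
        return out


class Linear(Module):
    def __init__(self, fin, fout, bias=True):
        super().__init__()
        self.fin, self.fout = fin, fout
        self.weight = Tensor(_kaiming((fin, fout), fin), requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        _record(self, self.fin * self.fout * int(np.prod(x.data.shape[:-1])))
        return out


class BatchNorm2d(Module):
    """Batch normalisation with learnable affine terms and running statistics.

    The running mean/var are non-learnable buffers and are excluded from
    parameter counts, matching standard profiler behaviour.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xn = (x - Tensor(mu)) * Tensor(inv)
        out = xn * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)
        _record(self, 2 * int(np.prod(x.data.shape)))
        return out


class LayerNormChannels(Module):
    """Layer normalisation over the channel axis of an NCHW map."""

    def __init__(self, c, eps=1e-6):
        super().__init__()
        self.c = c
        self.eps = eps
        self.weight = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xn = (x - mu) * ((var + self.eps) ** -0.5)
        out = xn * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)
        _record(self, 2 * int(np.prod(x.data.shape)))
        return out


class _Act(Module):
    fn = staticmethod(lambda x: x)

    def forward(self, x):
        out = self.fn(x)
        _record(self, 2 * int(np.prod(x.data.shape)))
        return out


class SiLU(_Act):
    fn = staticmethod(ag.silu)


class ReLU(_Act):
    fn = staticmethod(ag.relu)


class GELU(_Act):
    fn = staticmethod(ag.gelu)


class Sigmoid(_Act):
    fn = staticmethod(ag.sigmoid)


class ConvBnAct(Module):
    """Conv → BatchNorm → SiLU, the standard YOLO convolution unit."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, act=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DeformConv2d(Module):
    """Modulated deformable convolution (DCN v2).

    A parallel standard convolution on the input predicts, per output
    position, a 2-D offset and a modulation logit for each of the k×k kernel
    taps.  Each tap samples the input at its integer grid location displaced
    by the offset (bilinear interpolation, zero outside the map) and is
    scaled by sigmoid(modulation).  Offset/mask producers are zero-initialised
    so training starts exactly at the masked standard-convolution point.
    """

    def __init__(self, cin, cout, k=3, stride=1, padding=None, bias=False):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = cin * k * k
        self.weight = Tensor(_kaiming((cout, cin, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.offset_conv = Conv2d(cin, 2 * k * k, k, stride, self.padding, bias=True,
                                  zero_init=True)
        self.mask_conv = Conv2d(cin, k * k, k, stride, self.padding, bias=True,
                                zero_init=True)

    def forward(self, x):
        N, C, H, W = x.data.shape
        k, s, p = self.k, self.stride, self.padding
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        off = self.offset_conv(x)  # (N, 2*K, Ho, Wo) — (dy, dx) pairs per tap
        mask = ag.sigmoid(self.mask_conv(x))  # (N, K, Ho, Wo)
        K = k * k
        off = off.reshape((N, K, 2, Ho, Wo))
        base_y = (np.arange(Ho) * s - p)[None, None, :, None]
        base_x = (np.arange(Wo) * s - p)[None, None, None, :]
        tap_dy = np.repeat(np.arange(k), k).reshape(1, K, 1, 1)
        tap_dx = np.tile(np.arange(k), k).reshape(1, K, 1, 1)
        py = off[:, :, 0] + Tensor((base_y + tap_dy).astype(x.data.dtype))
        px = off[:, :, 1] + Tensor((base_x + tap_dx).astype(x.data.dtype))
        sampled = ag.bilinear_sample(x, py, px)  # (N,C,K,Ho,Wo)
        gated = sampled * mask.reshape((N, 1, K, Ho, Wo))
        flat = gated.reshape((N, C * K, Ho, Wo))
        wflat = self.weight.reshape((self.cout, C * K, 1, 1))
        out = ag.conv2d(flat, wflat, self.bias, stride=1, padding=0)
        _record(self, 10 * int(np.prod(sampled.data.shape)))  # sampling + gating
        return out
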