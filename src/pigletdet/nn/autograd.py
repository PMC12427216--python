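"""Reverse-mode automatic differentiation on NumPy arrays.

A small dynamic-graph engine: each operation returns a new :class:`Tensor`
holding the forward value, references to its parents and a closure that
propagates the output gradient back to them.  ``Tensor.backward`` runs a
topological sweep.  The primitive set is intentionally minimal — everything
higher-level (normalisation layers, attention, losses) is composed from these
primitives so their gradients come for free.

Arrays keep whatever float dtype they were created with; the network layers
default to float32, while gradient-checking tests use float64 inputs.
"""

from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, np.generic):
            data = np.asarray(data)
        elif not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backward -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = _ensure(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # method-style sugar
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _make(data, parents, backward):
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype)
    else:
        t.grad += g


# -- elementwise --------------------------------------------------------------

def add(a, b):
    a, b = _ensure(a), _ensure(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _ensure(a), _ensure(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float):
    a = _ensure(a)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a):
    a = _ensure(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = _ensure(a)
    out_data = np.log(a.data)

    def backward(g):
        _accum(a, g / a.data)

    return _make(out_data, (a,), backward)


def atan(a):
    a = _ensure(a)
    out_data = np.arctan(a.data)

    def backward(g):
        _accum(a, g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), backward)


def tanh(a):
    a = _ensure(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _ensure(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a):
    a = _ensure(a)
    mask = a.data > 0
    out_data = a.data * mask

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


def silu(a):
    """x * sigmoid(x) — the convolution activation used throughout."""
    a = _ensure(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def backward(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _make(out_data, (a,), backward)


def gelu(a):
    """Gaussian error linear unit (tanh approximation)."""
    a = _ensure(a)
    c = np.sqrt(2.0 / np.pi)
    inner = c * (a.data + 0.044715 * a.data ** 3)
    th = np.tanh(inner)
    out_data = 0.5 * a.data * (1.0 + th)

    def backward(g):
        dinner = c * (1.0 + 3 * 0.044715 * a.data ** 2)
        _accum(a, g * (0.5 * (1.0 + th) + 0.5 * a.data * (1.0 - th * th) * dinner))

    return _make(out_data, (a,), backward)


def maximum(a, b):
    a, b = _ensure(a), _ensure(b)
    out_data = np.maximum(a.data, b.data)
    amask = a.data >= b.data

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.data.shape))
        _accum(b, _unbroadcast(g * (~amask), b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b):
    a, b = _ensure(a), _ensure(b)
    out_data = np.minimum(a.data, b.data)
    amask = a.data <= b.data

    def backward(g):
        _accum(a, _unbroadcast(g * amask, a.data.shape))
        _accum(b, _unbroadcast(g * (~amask), b.data.shape))

    return _make(out_data, (a, b), backward)


def clamp_min(a, lo: float):
    a = _ensure(a)
    mask = a.data > lo
    out_data = np.maximum(a.data, lo)

    def backward(g):
        _accum(a, g * mask)

    return _make(out_data, (a,), backward)


# -- reductions / shaping ------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = _ensure(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = g
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _ensure(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = _ensure(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = _ensure(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = _ensure(a)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _make(out_data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [_ensure(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def matmul(a, b):
    """2-D (or batched trailing-2-D) matrix product."""
    a, b = _ensure(a), _ensure(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def softmax(a, axis=-1):
    a = _ensure(a)
    shifted = a - Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(a, axis=-1):
    a = _ensure(a)
    shifted = a - Tensor(a.data.max(axis=axis, keepdims=True))
    return shifted - log(tsum(exp(shifted), axis=axis, keepdims=True))


# -- spatial ops (NCHW) --------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0, groups: int = 1):
    """2-D cross-correlation on NCHW input.

    ``w`` has shape (O, C/groups, kh, kw).  Implemented as one einsum per
    kernel tap, which keeps memory flat and backpropagates exactly.
    """
    x, w = _ensure(x), _ensure(w)
    N, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    g = groups
    assert C % g == 0 and O % g == 0 and C // g == Cg
    s, p = stride, padding
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    xg = xp.reshape(N, g, Cg, xp.shape[2], xp.shape[3])
    wg = w.data.reshape(g, O // g, Cg, kh, kw)
    out = np.zeros((N, g, O // g, Ho, Wo), dtype=x.data.dtype)
    taps = []
    for di in range(kh):
        for dj in range(kw):
            xs = xg[:, :, :, di:di + s * Ho:s, dj:dj + s * Wo:s]
            taps.append(xs)
            out += np.einsum("goc,ngchw->ngohw", wg[:, :, :, di, dj], xs, optimize=True)
    out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        b = _ensure(b)
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(gout):
        gout5 = gout.reshape(N, g, O // g, Ho, Wo)
        if w.requires_grad:
            gw = np.zeros_like(w.data).reshape(g, O // g, Cg, kh, kw)
            for t, (di, dj) in zip(taps, [(i, j) for i in range(kh) for j in range(kw)]):
                gw[:, :, :, di, dj] = np.einsum("ngohw,ngchw->goc", gout5, t, optimize=True)
            _accum(w, gw.reshape(w.data.shape))
        if x.requires_grad:
            gxp = np.zeros_like(xp).reshape(N, g, Cg, xp.shape[2], xp.shape[3])
            for (di, dj) in [(i, j) for i in range(kh) for j in range(kw)]:
                gslice = np.einsum("goc,ngohw->ngchw", wg[:, :, :, di, dj], gout5, optimize=True)
                gxp[:, :, :, di:di + s * Ho:s, dj:dj + s * Wo:s] += gslice
            gxp = gxp.reshape(xp.shape)
            if p:
                gxp = gxp[:, :, p:-p, p:-p]
            _accum(x, gxp)
        if b is not None and b.requires_grad:
            _accum(b, gout.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def avg_pool2d(x, k: int):
    """Non-overlapping k×k average pooling; H and W must divide by k."""
    x = _ensure(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial size ({H},{W}) not divisible by {k}")
    Ho, Wo = H // k, W // k
    out = x.data.reshape(N, C, Ho, k, Wo, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        _accum(x, gx)

    return _make(out, (x,), backward)


def adaptive_avg_pool2d(x, out_hw):
    """Adaptive average pooling to an arbitrary (Ho, Wo) output grid.

    Regions follow the standard convention: cell (i,j) averages rows
    [floor(i*H/Ho), ceil((i+1)*H/Ho)) and likewise for columns.
    """
    x = _ensure(x)
    N, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if H % Ho == 0 and W % Wo == 0 and H // Ho == W // Wo:
        return avg_pool2d(x, H // Ho)
    ys = [(int(np.floor(i * H / Ho)), int(np.ceil((i + 1) * H / Ho))) for i in range(Ho)]
    xs = [(int(np.floor(j * W / Wo)), int(np.ceil((j + 1) * W / Wo))) for j in range(Wo)]
    out = np.empty((N, C, Ho, Wo), dtype=x.data.dtype)
    for i, (y0, y1) in enumerate(ys):
        for j, (x0, x1) in enumerate(xs):
            out[:, :, i, j] = x.data[:, :, y0:y1, x0:x1].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i, (y0, y1) in enumerate(ys):
            for j, (x0, x1) in enumerate(xs):
                gx[:, :, y0:y1, x0:x1] += (g[:, :, i, j] / ((y1 - y0) * (x1 - x0)))[
                    :, :, None, None
                ]
        _accum(x, gx)

    return _make(out, (x,), backward)


def _bilinear_coeffs(n_in: int, n_out: int):
    """Half-pixel-center source coordinates, clamped to the valid range."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def interpolate_bilinear(x, out_hw):
    """Bilinear resampling with half-pixel-center alignment."""
    x = _ensure(x)
    N, C, H, W = x.data.shape
    Ho, Wo = out_hw
    y0, y1, wy0, wy1 = _bilinear_coeffs(H, Ho)
    x0, x1, wx0, wx1 = _bilinear_coeffs(W, Wo)
    d = x.data
    rows0 = d[:, :, y0, :] * wy0[None, None, :, None] + d[:, :, y1, :] * wy1[None, None, :, None]
    out = rows0[:, :, :, x0] * wx0[None, None, None, :] + rows0[:, :, :, x1] * wx1[None, None, None, :]

    def backward(g):
        grows = np.zeros((N, C, Ho, W), dtype=d.dtype)
        np.add.at(grows.transpose(3, 0, 1, 2), x0, (g * wx0[None, None, None, :]).transpose(3, 0, 1, 2))
        np.add.at(grows.transpose(3, 0, 1, 2), x1, (g * wx1[None, None, None, :]).transpose(3, 0, 1, 2))
        gx = np.zeros_like(d)
        np.add.at(gx.transpose(2, 0, 1, 3), y0, (grows * wy0[None, None, :, None]).transpose(2, 0, 1, 3))
        np.add.at(gx.transpose(2, 0, 1, 3), y1, (grows * wy1[None, None, :, None]).transpose(2, 0, 1, 3))
        _accum(x, gx)

    return _make(out, (x,), backward)


def bilinear_sample(x, py, px):
    """Sample ``x`` (N,C,H,W) at float coordinates with zero padding outside.

    ``py``/``px`` have shape (N, K, Ho, Wo); the result is (N, C, K, Ho, Wo).
    Differentiable in the input map and in both coordinate fields — this is
    the kernel behind modulated deformable convolution.
    """
    x, py, px = _ensure(x), _ensure(py), _ensure(px)
    N, C, H, W = x.data.shape
    _, K, Ho, Wo = py.data.shape
    y0f = np.floor(py.data)
    x0f = np.floor(px.data)
    ly = py.data - y0f
    lx = px.data - x0f
    y0 = y0f.astype(np.int64)
    x0 = x0f.astype(np.int64)
    corners = []  # (yi, xi, wy, wx, valid)
    for dy, wy in ((0, 1.0 - ly), (1, ly)):
        for dx, wx in ((0, 1.0 - lx), (1, lx)):
            yi, xi = y0 + dy, x0 + dx
            valid = (yi >= 0) & (yi < H) & (xi >= 0) & (xi < W)
            corners.append((np.clip(yi, 0, H - 1), np.clip(xi, 0, W - 1), wy, wx, valid))
    nidx = np.arange(N)[:, None, None, None]
    out = np.zeros((N, K, Ho, Wo, C), dtype=x.data.dtype)
    vals = []
    for yi, xi, wy, wx, valid in corners:
        v = x.data[nidx, :, yi, xi] * valid[..., None]  # (N,K,Ho,Wo,C)
        vals.append(v)
        out += v * (wy * wx)[..., None]
    out_nc = np.moveaxis(out, -1, 1)  # (N,C,K,Ho,Wo)

    def backward(g):
        gperm = np.moveaxis(g, 1, -1)  # (N,K,Ho,Wo,C)
        if x.requires_grad:
            gx = np.zeros((N, H * W, C), dtype=x.data.dtype)
            nb = np.broadcast_to(nidx, py.data.shape)
            for (yi, xi, wy, wx, valid) in corners:
                contrib = gperm * ((wy * wx) * valid)[..., None]
                np.add.at(gx, (nb, yi * W + xi), contrib)
            _accum(x, gx.reshape(N, H, W, C).transpose(0, 3, 1, 2))
        if py.requires_grad or px.requires_grad:
            gpy = np.zeros_like(py.data)
            gpx = np.zeros_like(px.data)
            # d(weight)/d(ly): corner order is (0,0),(0,1),(1,0),(1,1) in (dy,dx)
            dwy = (-1.0, -1.0, 1.0, 1.0)
            dwx = (-1.0, 1.0, -1.0, 1.0)
            for v, (yi, xi, wy, wx, valid), sy, sx in zip(vals, corners, dwy, dwx):
                dot = (gperm * v).sum(axis=-1)
                gpy += dot * sy * wx
                gpx += dot * sx * wy
            _accum(py, gpy)
            _accum(px, gpx)

    return _make(out_nc, (x, py, px), backward)
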