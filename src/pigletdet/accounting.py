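"""Parameter and computational-complexity accounting.

Parameter counts include every learnable array (convolution kernels, biases,
normalisation affine terms, attention projections, deformable offset/mask
kernels) and exclude non-learnable buffers such as batch-norm running
statistics — the standard profiler convention.

MAC counting convention: one multiply-accumulate per kernel weight per output
position for convolutions and linear layers; normalisation layers cost 2
operations per input element and activations 2 per element; deformable
sampling costs 10 per sampled value.  The convention is reported alongside
the numbers so comparisons against other profilers are explicit.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.autograd import Tensor
from .nn.layers import (
    BatchNorm2d, Conv2d, DeformConv2d, LayerNormChannels, Linear, Module, _Act,
    profile_macs,
)

MAC_CONVENTION = ("conv/linear: weights x output positions; "
                  "norm: 2/element; activation: 2/element; "
                  "deformable sampling: 10/sample")

_COUNTABLE = (Conv2d, Linear, BatchNorm2d, LayerNormChannels, DeformConv2d)


def count_parameters(module) -> int:
    """Exact number of scalar learnable values in a module tree.

    Raises a TypeError naming the object if it is not a network module.
    """
    if not isinstance(module, Module):
        raise TypeError(f"cannot count parameters of {type(module).__name__!r}: "
                        "not a network module")
    for name, m in module.named_modules():
        direct = [v for v in vars(m).items() if isinstance(v[1], Tensor) and v[1].requires_grad]
        if direct and not isinstance(m, _COUNTABLE) and not _is_known_composite(m):
            raise TypeError(f"unknown layer kind with direct parameters: "
                            f"{type(m).__name__} at {name or '<root>'}")
    return sum(p.data.size for p in module.parameters())


def _is_known_composite(m) -> bool:
    # composite modules holding Tensors directly (e.g. GRN gamma/beta) opt in
    return getattr(m, "_countable", False)


def count_macs(module: Module, input_hw, in_channels: int = 3,
               conv_only: bool = False, input_tensor=None) -> int:
    """Multiply-accumulate count of one forward pass at the given input size.

    The module is executed once on a zero input of shape
    (1, in_channels, H, W) with instrumentation; the count is additive over
    submodules by construction.  ``conv_only=True`` restricts the count to
    convolution/linear kernel MACs (no normalisation/activation overhead).
    """
    if isinstance(input_hw, int):
        input_hw = (input_hw, input_hw)
    x = input_tensor if input_tensor is not None else Tensor(
        np.zeros((1, in_channels, input_hw[0], input_hw[1]), dtype=np.float32))
    module.eval()
    with profile_macs() as prof, nn.no_grad():
        module(x)
    total = 0
    for layer, macs in prof.entries:
        if conv_only and not isinstance(layer, (Conv2d, Linear)):
            continue
        total += macs
    return total


def parameter_report(module: Module, input_hw=None, in_channels: int = 3) -> dict:
    """Per-child table of (name, params, MACs) plus totals.

    MACs are omitted (None) when no input size is given.
    """
    rows = []
    child_macs = {}
    if input_hw is not None:
        if isinstance(input_hw, int):
            input_hw = (input_hw, input_hw)
        x = Tensor(np.zeros((1, in_channels, input_hw[0], input_hw[1]), dtype=np.float32))
        module.eval()
        with profile_macs() as prof, nn.no_grad():
            module(x)
        # attribute each leaf record to the top-level child owning it
        owner = {}
        for name, child in module._children():
            for _, sub in child.named_modules():
                owner[id(sub)] = name
        for layer, macs in prof.entries:
            key = owner.get(id(layer), "<root>")
            child_macs[key] = child_macs.get(key, 0) + macs
    for name, child in module._children():
        rows.append({
            "name": name,
            "params": count_parameters(child),
            "macs": child_macs.get(name) if input_hw is not None else None,
        })
    total_params = count_parameters(module)
    total_macs = sum(child_macs.values()) if input_hw is not None else None
    return {"rows": rows, "total_params": total_params, "total_macs": total_macs,
            "convention": MAC_CONVENTION}


def format_report(report: dict) -> str:
    lines = [f"{'module':<28}{'params':>12}{'MACs':>16}"]
    for r in report["rows"]:
        macs = "-" if r["macs"] is None else f"{r['macs']:,}"
        lines.append(f"{r['name']:<28}{r['params']:>12,}{macs:>16}")
    tm = "-" if report["total_macs"] is None else f"{report['total_macs']:,}"
    lines.append(f"{'TOTAL':<28}{report['total_params']:>12,}{tm:>16}")
    lines.append(f"convention: {report['convention']}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# comparison-configuration resolution
# ---------------------------------------------------------------------------

def resolve_comparison_config(target_c2f: int = 107_264, target_mspa: int = 14_402):
    """Resolve the under-specified block-comparison configuration by search.

    Enumerates small C2f configurations (in/out channels in {16,...,256},
    1-3 bottlenecks) to locate the one matching the published baseline
    parameter count, then enumerates the discrete MSPA C2f internal space
    (chunk rule, bottleneck expansion, CIA reduction and sharing, bias vs
    norm on the 1x1 convolutions, output width) for the published block
    count.  Returns both resolved configurations as dicts.
    """
    from .backbone import C2f, MSPAC2f

    c2f_hit = None
    for cin in (16, 32, 64, 128, 256):
        for cout in (16, 32, 64, 128, 256):
            for n in (1, 2, 3):
                if _c2f_params(cin, cout, n) == target_c2f:
                    c2f_hit = {"cin": cin, "cout": cout, "n": n}
    if c2f_hit is None:
        raise RuntimeError("no standard C2f configuration matches the baseline count")
    mspa_hits = []
    for e in (0.25, 0.5, 1.0):
        for r in (1, 2, 4, 8, 16):
            for cout in (64, 128):
                if _mspa_params(c2f_hit["cin"], cout, e, r) == target_mspa:
                    mspa_hits.append({"cin": c2f_hit["cin"], "cout": cout,
                                      "expansion": e, "reduction": r})
    if len(mspa_hits) != 1:
        raise RuntimeError(f"MSPA enumeration found {len(mspa_hits)} matches, expected 1")
    # cross-check the closed-form enumeration against real module instances
    c2f = C2f(c2f_hit["cin"], c2f_hit["cout"], c2f_hit["n"])
    m = mspa_hits[0]
    mspa = MSPAC2f(m["cin"], m["cout"], expansion=m["expansion"], reduction=m["reduction"])
    assert count_parameters(c2f) == target_c2f
    assert count_parameters(mspa) == target_mspa
    return c2f_hit, mspa_hits[0]


def _conv_p(cin, cout, k, bn=True, bias=False):
    return cin * cout * k * k + (2 * cout if bn else 0) + (cout if bias else 0)


def _c2f_params(cin, cout, n):
    c = cout // 2
    p = _conv_p(cin, 2 * c, 1) + _conv_p((2 + n) * c, cout, 1)
    p += n * (_conv_p(c, c, 3) + _conv_p(c, c, 3))
    return p


def _mspa_params(cin, cout, e, r):
    from .backbone import chunk_widths

    w1, w2, w3 = chunk_widths(cin, 3)
    if w2 != w3:
        return -1
    p = _conv_p(w1, w2, 1, bn=False, bias=True) + _conv_p(w2, w3, 1, bn=False, bias=True)
    h = max(1, int(w3 * e))
    p += _conv_p(w3, h, 3) + _conv_p(h, w3, 3)
    p += _conv_p(w2 + 2 * w3, cout, 1, bn=False, bias=True)
    d = (5 * w2) // r
    if d < 1:
        return -1
    p += 5 * w2 * d + d + d * w2 + w2  # shared CIA
    return p
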