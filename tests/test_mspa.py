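"""MSPA C2f block: chunking, EHPC/SPA/CIA behaviour, and agreement with an
independent straight-line transcription of the block's defining equations."""

import numpy as np
import pytest

from pigletdet import nn
from pigletdet.nn.autograd import Tensor
from pigletdet.accounting import count_parameters
from pigletdet.backbone import (Backbone, C2f, CIA, EHPC, MSPAC2f, chunk_widths,
                                spa_forward, split_channels, mspa_softmax_weights)
from pigletdet.config import ModelConfig


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("c,n,expect", [
    (63, 3, (21, 21, 21)),
    (64, 3, (22, 21, 21)),
    (65, 3, (22, 22, 21)),
    (7, 2, (4, 3)),
])
def test_chunk_widths_remainder_goes_to_front(c, n, expect):
    assert chunk_widths(c, n) == expect


def test_chunking_too_few_channels_errors():
    with pytest.raises(ValueError):
        chunk_widths(2, 3)


def test_split_channels_is_contiguous_and_order_preserving(rng):
    x = Tensor(rng.standard_normal((2, 7, 3, 3)))
    chunks = split_channels(x, 3)
    assert [c.shape[1] for c in chunks] == [3, 2, 2]
    assert np.array_equal(np.concatenate([c.data for c in chunks], axis=1), x.data)


# ---------------------------------------------------------------------------
# EHPC
# ---------------------------------------------------------------------------

def test_ehpc_identity_kernels_give_plain_chunk_sum(rng):
    """With 1×1 convolutions set to identity, the second branch is F1 + F2."""
    m = EHPC(6)
    m.conv1.weight.data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
    m.conv1.bias.data[:] = 0
    m.conv2.weight.data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
    m.conv2.bias.data[:] = 0
    x = rng.standard_normal((1, 6, 4, 4))
    f1, f2, _ = m.branches(Tensor(x))
    assert np.allclose(f1.data, x[:, 0:2])
    assert np.allclose(f2.data, x[:, 0:2] + x[:, 2:4])


def test_ehpc_output_shape_contract(rng, ):
    m = MSPAC2f(6, 10)
    out = m.ehpc_forward(Tensor(rng.standard_normal((2, 6, 4, 4)).astype(np.float32)))
    assert out.shape == (2, 10, 4, 4)


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def test_spa_constant_input_gives_constant_descriptor():
    x = Tensor(np.full((1, 3, 4, 4), 2.75))
    z = spa_forward(x)
    assert z.shape == (1, 15)
    assert np.allclose(z.data, 2.75)


def test_spa_hand_computed_descriptor():
    x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))  # omega=1, 2x2 map
    z = spa_forward(x)
    assert np.allclose(z.data[0], [2.5, 1, 2, 3, 4])


def test_spa_rejects_degenerate_spatial_size():
    with pytest.raises(ValueError):
        spa_forward(Tensor(np.zeros((1, 2, 1, 4))))


# ---------------------------------------------------------------------------
# CIA + softmax
# ---------------------------------------------------------------------------

def test_cia_zero_weights_give_half(rng):
    m = CIA(4)
    for p in m.parameters():
        p.data[:] = 0
    out = m(Tensor(rng.standard_normal((3, 20))))
    assert out.shape == (3, 4)
    assert np.allclose(out.data, 0.5)


def test_cia_hand_computed_two_step_affine(rng):
    m = CIA(2, reduction=10)  # hidden width = 10//10 = 1
    m.down.weight.data = np.arange(10, dtype=np.float32).reshape(10, 1) * 0.01
    m.down.bias.data[:] = 0.1
    m.up.weight.data = np.array([[0.5, -2.0]], dtype=np.float32)
    m.up.bias.data[:] = np.array([0.2, 0.3], dtype=np.float32)
    z = np.linspace(-1, 1, 10)[None]
    hidden = np.maximum(0.0, z @ (np.arange(10)[:, None] * 0.01) + 0.1)
    expect = 1 / (1 + np.exp(-(hidden * np.array([0.5, -2.0]) + np.array([0.2, 0.3]))))
    assert np.allclose(m(Tensor(z)).data, expect, atol=1e-7)


def test_cia_collapsed_hidden_width_errors():
    with pytest.raises(ValueError):
        CIA(1, reduction=8)


def test_softmax_weights_normalise_and_follow_dominance(rng):
    v = [Tensor(rng.random((2, 5))) for _ in range(3)]
    ws = mspa_softmax_weights(v)
    total = sum(w.data for w in ws)
    assert np.allclose(total, 1.0, atol=1e-12)
    equal = mspa_softmax_weights([v[0], v[0], v[0]])
    assert all(np.allclose(w.data, 1 / 3) for w in equal)
    # a dominant pre-softmax score wins, monotonically in the gap
    big = mspa_softmax_weights([Tensor(np.full((1, 1), 0.99)),
                                Tensor(np.full((1, 1), 0.01)),
                                Tensor(np.full((1, 1), 0.01))])
    ref = np.exp([0.99, 0.01, 0.01])
    assert np.allclose([w.data.item() for w in big], ref / ref.sum())


# ---------------------------------------------------------------------------
# assembled block vs straight-line equation transcription
# ---------------------------------------------------------------------------

def straight_line_mspa(m: MSPAC2f, x: np.ndarray) -> np.ndarray:
    """Independent transcription of the block: split, the three-branch
    hierarchy, pooled descriptors, gated channel weights, chunk softmax,
    reweighting and the 1×1 aggregation — plain NumPy, no module calls."""

    def conv1x1(w, b, t):
        return np.einsum("oc,nchw->nohw", w[:, :, 0, 0], t) + b[None, :, None, None]

    def conv3x3_bn_silu(conv, bn, t):
        w = conv.weight.data
        tp = np.pad(t, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((t.shape[0], w.shape[0]) + t.shape[2:])
        for di in range(3):
            for dj in range(3):
                out += np.einsum("oc,nchw->nohw", w[:, :, di, dj],
                                 tp[:, :, di:di + t.shape[2], dj:dj + t.shape[3]])
        mu = bn.running_mean[None, :, None, None]
        var = bn.running_var[None, :, None, None]
        out = (out - mu) / np.sqrt(var + bn.eps)
        out = out * bn.weight.data[None, :, None, None] + bn.bias.data[None, :, None, None]
        return out * (1 / (1 + np.exp(-out)))  # SiLU

    widths = m.ehpc.widths
    offs = np.cumsum((0,) + widths)
    f = [x[:, lo:hi] for lo, hi in zip(offs[:-1], offs[1:])]
    f1 = conv1x1(m.ehpc.conv1.weight.data, m.ehpc.conv1.bias.data, f[0])
    f2 = conv1x1(m.ehpc.conv2.weight.data, m.ehpc.conv2.bias.data, f1 + f[1])
    bsum = f2 + f[2]
    bott = conv3x3_bn_silu(m.ehpc.bottleneck.cv2.conv, m.ehpc.bottleneck.cv2.bn,
                           conv3x3_bn_silu(m.ehpc.bottleneck.cv1.conv,
                                           m.ehpc.bottleneck.cv1.bn, bsum))
    f3 = bsum + bott
    branches = [f1, f2, f3]
    vs = []
    for br in branches:
        n, c, h, w = br.shape
        glob = br.mean(axis=(2, 3))
        loc = br.reshape(n, c, 2, h // 2, 2, w // 2).mean(axis=(3, 5)).reshape(n, 4 * c)
        z = np.concatenate([glob, loc], axis=1)
        hid = np.maximum(0.0, z @ m.cia.down.weight.data + m.cia.down.bias.data)
        vs.append(1 / (1 + np.exp(-(hid @ m.cia.up.weight.data + m.cia.up.bias.data))))
    stacked = np.stack(vs)
    sm = np.exp(stacked) / np.exp(stacked).sum(axis=0, keepdims=True)
    weighted = np.concatenate(
        [br * sm[i][:, :, None, None] for i, br in enumerate(branches)], axis=1)
    return conv1x1(m.conv3.weight.data, m.conv3.bias.data, weighted)


def test_block_matches_equation_transcription(rng):
    """20 random small inputs agree with the straight-line oracle to 1e-6."""
    m = MSPAC2f(6, 5)
    # randomise normalisation statistics and affine terms so the oracle
    # exercises them beyond the fresh-initialisation identity
    for bn in (m.ehpc.bottleneck.cv1.bn, m.ehpc.bottleneck.cv2.bn):
        c = bn.c
        bn.running_mean = rng.normal(0, 0.3, c).astype(np.float32)
        bn.running_var = rng.uniform(0.5, 1.5, c).astype(np.float32)
        bn.weight.data = rng.uniform(0.8, 1.2, c).astype(np.float32)
        bn.bias.data = rng.normal(0, 0.1, c).astype(np.float32)
    m.eval()
    for _ in range(20):
        x = rng.standard_normal((2, 6, 4, 4))
        got = m(Tensor(x)).data
        want = straight_line_mspa(m, x)
        assert np.abs(got - want).max() < 1e-6


def test_uniform_attention_reduces_to_scaled_ehpc(rng):
    """Zeroed CIA gives uniform 1/3 weights: the block equals its own
    aggregation applied to 1/3-scaled branches."""
    m = MSPAC2f(6, 5)
    for p in m.cia.parameters():
        p.data[:] = 0
    m.eval()
    x = Tensor(rng.standard_normal((1, 6, 4, 4)))
    got = m(x).data
    branches = m.ehpc.branches(x)
    from pigletdet.nn import autograd as ag
    scaled = ag.concat([b * (1 / 3) for b in branches], axis=1)
    want = m.conv3(scaled).data
    assert np.abs(got - want).max() < 1e-6


def test_spatial_permutation_equivariance_with_global_attention(rng):
    """With constant attention and a pointwise pipeline, permuting spatial
    positions of the input permutes the output identically."""
    m = MSPAC2f(6, 5)
    for p in m.cia.parameters():
        p.data[:] = 0  # attention constant regardless of input
    for conv in (m.ehpc.bottleneck.cv1.conv, m.ehpc.bottleneck.cv2.conv):
        w = conv.weight.data
        centre = w[:, :, 1, 1].copy()
        w[:] = 0
        w[:, :, 1, 1] = centre  # 3×3 kernels reduced to pointwise
    m.eval()
    x = rng.standard_normal((1, 6, 4, 4))
    perm = rng.permutation(16)
    xp = x.reshape(1, 6, 16)[:, :, perm].reshape(1, 6, 4, 4)
    out = m(Tensor(x)).data
    out_p = m(Tensor(xp)).data
    assert np.allclose(out.reshape(1, 5, 16)[:, :, perm].reshape(1, 5, 4, 4),
                       out_p, atol=1e-6)


def test_parameter_reduction_ratio_vs_standard_c2f():
    """The attention block is at least 86% smaller than the block it replaces."""
    ratio = count_parameters(MSPAC2f(64, 128)) / count_parameters(C2f(64, 128, 1))
    assert ratio <= 0.14


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def test_backbone_strides_and_widths(tiny_config):
    bb = Backbone(tiny_config)
    levels = bb(Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32)))
    shapes = [t.shape for t in levels]
    assert shapes == [(1, 12, 32, 32), (1, 24, 16, 16), (1, 36, 8, 8), (1, 48, 4, 4)]


def test_backbone_rejects_indivisible_input(tiny_config):
    bb = Backbone(tiny_config)
    with pytest.raises(ValueError, match="letterbox"):
        bb(Tensor(np.zeros((1, 3, 100, 100), dtype=np.float32)))
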