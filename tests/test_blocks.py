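"""Architectural blocks: residual identity, concat widths, attention contracts."""

import numpy as np
import pytest

import granulonet as gn
from granulonet.autograd import Tensor, mul, tsum
from granulonet.blocks import (BlockSpec, ConvAttention, DenseAttention,
                               DownsampleModule, LearnableSoftmaxHead, RBlock,
                               XModule, XModuleSpec)


def zero_module_convs(module):
    """Zero every convolution weight/bias below a module (not BN/LAF)."""
    from granulonet.autograd import Conv2d

    def walk(m):
        if isinstance(m, Conv2d):
            m.weight.data[...] = 0
            if m.bias is not None:
                m.bias.data[...] = 0
        for child in getattr(m, "_children", {}).values():
            if hasattr(child, "_list"):
                for sub in child:
                    walk(sub)
            else:
                walk(child)
    walk(module)


# ---------------------------------------------------------------------------
# R-block
# ---------------------------------------------------------------------------

def test_rblock_zeroed_residual_branch_is_exact_identity(rng):
    spec = BlockSpec(kind="R3", in_channels=4, out_channels=4)
    block = RBlock(spec, rng=rng)
    zero_module_convs(block)
    block.eval()
    x = rng.random((2, 4, 8, 8)).astype(np.float32)
    out = block(Tensor(x)).data
    assert np.array_equal(out, x)  # bit-exact additive skip


@pytest.mark.parametrize("kind,filters", [("R3", (3, 3)), ("R5", (5, 5)),
                                          ("R35", (3, 5))])
def test_rblock_variants_and_shape_contract(rng, kind, filters):
    spec = BlockSpec(kind=kind, in_channels=3, out_channels=6)
    block = RBlock(spec, rng=rng)
    assert spec.filters == filters
    assert block.conv1.weight.shape[2] == filters[0]
    assert block.conv2.weight.shape[2] == filters[1]
    out = block(Tensor(rng.random((2, 3, 12, 12)).astype(np.float32)))
    assert out.data.shape == (2, 6, 12, 12)  # same padding, projected channels


def test_rblock_channel_mismatch_without_projection_rejected(rng):
    spec = BlockSpec(kind="R3", in_channels=3, out_channels=6)
    with pytest.raises(ValueError):
        RBlock(spec, rng=rng, allow_projection=False)


def test_rblock_gradient_reaches_conv1_through_skip(rng):
    spec = BlockSpec(kind="R3", in_channels=2, out_channels=2)
    block = RBlock(spec, rng=rng)
    x = Tensor(rng.random((1, 2, 4, 4)).astype(np.float32))
    out = block(x)
    tsum(mul(out, out)).backward()
    assert block.conv1.weight.grad is not None
    assert np.any(block.conv1.weight.grad != 0)


# ---------------------------------------------------------------------------
# X-module
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", ["R3_R3_R3", "R5_R5_R5", "R3_R5_R35"])
def test_xmodule_output_width_is_sum_of_branches(rng, variant):
    spec = XModuleSpec.for_variant(variant, in_channels=6, branch_width=4)
    mod = XModule(spec, rng=rng)
    out = mod(Tensor(rng.random((2, 6, 10, 10)).astype(np.float32)))
    assert spec.out_channels == 3 * 4 + 4
    assert out.data.shape == (2, spec.out_channels, 10, 10)


def test_variant_orders_filter_sizes():
    spec = XModuleSpec.for_variant("R3_R5_R35", in_channels=4, branch_width=4)
    assert [b.filters for b in spec.branch_specs] == [(3, 3), (5, 5), (3, 5)]


def test_reducers_cut_parameter_count():
    """Closed-form arithmetic: 1x1 reducers shrink the conv parameter total
    at equal output width."""
    def conv_params(cin, cout, k):
        return cin * cout * k * k + cout

    cin, width = 64, 32
    # R5 branch with reducer: 1x1 (64->32) then two 5x5 at 32 channels
    with_red = conv_params(cin, width, 1) + conv_params(width, width, 5) \
        + conv_params(width, width, 5)
    # without reducer: two 5x5, the first straight from 64 channels, plus
    # the 1x1 projection shortcut the channel change requires
    without = conv_params(cin, width, 5) + conv_params(width, width, 5) \
        + conv_params(cin, width, 1)
    assert with_red < without

    import granulonet as gn
    rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
    m_red = XModule(XModuleSpec.for_variant("R5_R5_R5", cin, width), rng=rng1)
    m_no = XModule(XModuleSpec.for_variant("R5_R5_R5", cin, width,
                                           use_reducers=False), rng=rng2)
    assert gn.count_parameters(m_red) < gn.count_parameters(m_no)


# ---------------------------------------------------------------------------
# Downsample
# ---------------------------------------------------------------------------

def test_downsample_halves_and_concatenates(rng):
    mod = DownsampleModule(6, conv_channels=8, rng=rng)
    out = mod(Tensor(rng.random((2, 6, 28, 28)).astype(np.float32)))
    assert out.data.shape == (2, 6 + 8, 14, 14)
    odd = mod(Tensor(rng.random((1, 6, 27, 27)).astype(np.float32)))
    assert odd.data.shape[2:] == (14, 14)  # ceil halving


def test_downsample_pool_branch_of_constant_is_constant(rng):
    mod = DownsampleModule(2, conv_channels=2, rng=rng)
    x = np.full((1, 2, 8, 8), 0.7, np.float32)
    out = mod(Tensor(x)).data
    assert np.allclose(out[:, :2], 0.7)  # first block = max-pool branch


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

def test_attention_map_sums_to_one(rng):
    att = ConvAttention(3, rng=rng)
    x = rng.random((4, 3, 16, 16)).astype(np.float32)
    _, weights = att(Tensor(x))
    assert np.allclose(weights.sum(axis=(1, 2)), 1.0, atol=1e-6)
    amap = ConvAttention.attention_map(weights, 0)
    assert amap.weights.shape == (16, 16)


def test_zero_weight_attention_is_identity(rng):
    """All-zero attention layers -> uniform map -> H*W rescale restores x."""
    att = ConvAttention(1, rng=rng)
    zero_module_convs(att)
    x = rng.random((2, 1, 64, 64)).astype(np.float32)
    attended, weights = att(Tensor(x))
    assert np.allclose(weights, 1.0 / 4096)
    assert np.array_equal(attended.data, x)  # 1/4096 * 4096 is exact


def test_spiked_score_wins(rng):
    att = ConvAttention(1, k=1, hidden=1, rng=rng)
    att.conv.weight.data[...] = 1.0
    att.conv.bias.data[...] = 0.0
    att.score.weight.data[...] = 1.0
    att.score.bias.data[...] = 0.0
    x = np.zeros((1, 1, 8, 8), np.float32)
    x[0, 0, 3, 5] = 1.0
    _, weights = att(Tensor(x))
    assert np.unravel_index(weights[0].argmax(), (8, 8)) == (3, 5)


def test_dense_attention_contracts(rng):
    datt = DenseAttention(5, rng=rng)
    f = rng.random((3, 5, 4, 4)).astype(np.float32)

    # uniform scores -> spatial mean
    datt.score.weight.data[...] = 0
    datt.score.bias.data[...] = 0
    pooled, scores = datt(Tensor(f))
    assert np.allclose(scores.sum(axis=(1, 2)), 1.0, atol=1e-6)
    assert np.allclose(pooled.data, f.mean(axis=(2, 3)), atol=1e-6)

    # a (near) one-hot weighting returns that position's feature vector
    datt.score.bias.data[...] = 0
    datt.score.weight.data[...] = 0
    f2 = np.zeros((1, 5, 2, 2), np.float32)
    f2[0, :, 1, 1] = [1, 2, 3, 4, 5]
    datt.score.weight.data[:, :, 0, 0] = 50.0  # huge score at the hot pixel
    pooled2, _ = datt(Tensor(f2))
    assert np.allclose(pooled2.data[0], [1, 2, 3, 4, 5], atol=1e-3)


def test_learnable_softmax_head_is_a_simplex_map(rng):
    head = LearnableSoftmaxHead(6, 3, rng=rng)
    v = rng.standard_normal((4, 6)).astype(np.float32)
    p = head(Tensor(v)).data
    assert np.all(p >= 0)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    # zero input weights -> zero logits -> uniform distribution
    head.fc2.weight.data[...] = 0
    head.fc2.bias.data[...] = 0
    p0 = head(Tensor(v)).data
    assert np.allclose(p0, 1 / 3, atol=1e-6)

    with pytest.raises(ValueError):
        LearnableSoftmaxHead(6, 1, rng=rng)


def test_blocks_no_nan_on_unit_inputs(rng):
    """Default-initialized blocks keep batch size and never emit NaN."""
    x = rng.random((3, 4, 12, 12)).astype(np.float32)
    for mod in (RBlock(BlockSpec("R35", 4, 8), rng=rng),
                XModule(XModuleSpec.for_variant("R3_R5_R35", 4, 4), rng=rng),
                DownsampleModule(4, 4, rng=rng)):
        out = mod(Tensor(x)).data
        assert out.shape[0] == 3
        assert np.isfinite(out).all()
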