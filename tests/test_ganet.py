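"""Architecture contracts: shapes, oracle equivalence, degenerate cases."""

import numpy as np
import pytest

from oracles import (attention_weights, conv1x1, naive_channel_attention,
                     naive_spatial_attention)
from sats.ganet import (ChannelAttention, GANet, GANetConfig, RefineBlock,
                        SpatialAttention, load_checkpoint, masked_attention,
                        save_checkpoint, spatial_flatten, spatial_unflatten)
from sats.losses import LossConfig, multiscale_loss
from sats.nn import Tensor

RNG = np.random.default_rng(77)


def _zero_bias_attention(cls, channels, seed):
    layer = cls(channels, np.random.default_rng(seed))
    return layer


# -- encoder ------------------------------------------------------------------

def test_encoder_shape_ladder_and_finiteness():
    model = GANet(GANetConfig(depth=3, base_channels=8), seed=0)
    feats = model.encode(np.zeros((3, 64, 64), dtype=np.float32))
    assert [tuple(f.shape) for f in feats] == [
        (1, 8, 32, 32), (1, 16, 16, 16), (1, 32, 8, 8)]
    assert all(np.isfinite(f.data).all() for f in feats)


def test_encoder_rejects_non_divisible_size_with_hint():
    model = GANet(GANetConfig(depth=3, base_channels=8), seed=0)
    with pytest.raises(ValueError, match="pad"):
        model.encode(np.zeros((3, 60, 60), dtype=np.float32))


# -- flatten / unflatten ------------------------------------------------------

def test_flatten_index_identity_and_bijection(rng):
    x = rng.normal(size=(3, 2, 4)).astype(np.float32)
    flat = spatial_flatten(x)
    assert flat.shape == (3, 8)
    assert flat[0, 1 * 4 + 2] == x[0, 1, 2]
    np.testing.assert_array_equal(spatial_unflatten(flat, 2, 4), x)
    assert spatial_unflatten(flat, 2, 4)[0, 1, 2] == flat[0, 6]
    with pytest.raises(ValueError):
        spatial_unflatten(flat, 3, 4)


# -- attention oracles --------------------------------------------------------

def test_channel_attention_matches_naive_loop_oracle(rng):
    layer = ChannelAttention(2, np.random.default_rng(1))
    x = rng.normal(size=(2, 2, 2)).astype(np.float32)
    out, attn = layer(x, return_attn=True)
    expected, expected_attn = naive_channel_attention(
        x.astype(float), *attention_weights(layer))
    np.testing.assert_allclose(out.data[0], expected, atol=1e-6)
    np.testing.assert_allclose(attn.data[0], expected_attn, atol=1e-6)


def test_channel_attention_rows_stochastic_and_zero_input_uniform(rng):
    layer = ChannelAttention(4, np.random.default_rng(2))
    x = rng.normal(size=(2, 4, 3, 3)).astype(np.float32)
    _, attn = layer(Tensor(x), return_attn=True)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)
    # zero input -> scores depend only on biases -> uniform rows
    zero_layer = ChannelAttention(4, np.random.default_rng(3))
    zero_layer.q.bias.data[:] = 0
    zero_layer.k.bias.data[:] = 0
    _, attn0 = zero_layer(np.zeros((4, 3, 3), dtype=np.float32),
                          return_attn=True)
    np.testing.assert_allclose(attn0.data, 0.25, atol=1e-6)


def test_spatial_attention_matches_naive_loop_oracle(rng):
    layer = SpatialAttention(2, np.random.default_rng(4))
    x = rng.normal(size=(2, 2, 2)).astype(np.float32)
    out, attn = layer(x, return_attn=True)
    expected, expected_attn = naive_spatial_attention(
        x.astype(float), *attention_weights(layer))
    np.testing.assert_allclose(out.data[0], expected, atol=1e-6)
    np.testing.assert_allclose(attn.data[0], expected_attn, atol=1e-6)
    np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)


def test_spatial_attention_permutation_equivariance(rng):
    """1x1 projections make position tokens exchangeable: permuting input
    pixels permutes output pixels identically."""
    layer = SpatialAttention(3, np.random.default_rng(5))
    x = rng.normal(size=(1, 3, 2, 3)).astype(np.float32)
    out = layer(Tensor(x)).data
    perm = np.random.default_rng(6).permutation(6)
    x_flat = x.reshape(1, 3, 6)[:, :, perm].reshape(1, 3, 2, 3)
    out_perm = layer(Tensor(x_flat)).data
    np.testing.assert_allclose(out.reshape(1, 3, 6)[:, :, perm],
                               out_perm.reshape(1, 3, 6), atol=1e-5)


# -- identify / masked attention ---------------------------------------------

def test_identify_block_is_channel_then_spatial_composition(rng):
    model = GANet(GANetConfig(depth=2, base_channels=4), seed=1)
    z = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
    o_sp, p_ini = model.identify(Tensor(z))
    manual = model.identify.attn_sp(model.identify.attn_ch(Tensor(z)))
    np.testing.assert_array_equal(o_sp.data, manual.data)
    assert p_ini.data.min() >= 0 and p_ini.data.max() <= 1
    assert p_ini.shape[-2:] == z.shape[-2:]


def test_masked_attention_gate_contracts(rng):
    layer = SpatialAttention(2, np.random.default_rng(7))
    z = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
    ones = np.ones((1, 1, 3, 3), dtype=np.float32)
    np.testing.assert_array_equal(
        masked_attention(Tensor(z), Tensor(ones), layer).data,
        layer(Tensor(z)).data)
    zeros = np.zeros((1, 1, 3, 3), dtype=np.float32)
    np.testing.assert_array_equal(
        masked_attention(Tensor(z), Tensor(zeros), layer).data,
        layer(Tensor(np.zeros_like(z))).data)
    with pytest.raises(ValueError):
        masked_attention(Tensor(z), Tensor(np.ones((1, 1, 2, 2))), layer)


def test_masked_attention_matches_naive_oracle(rng):
    layer = SpatialAttention(2, np.random.default_rng(8))
    z = rng.normal(size=(2, 2, 2)).astype(np.float32)
    gate = rng.uniform(size=(2, 2)).astype(np.float32)
    out = masked_attention(Tensor(z[None]), Tensor(gate[None, None]), layer)
    expected, _ = naive_spatial_attention(
        (z * gate).astype(float), *attention_weights(layer))
    np.testing.assert_allclose(out.data[0], expected, atol=1e-6)


# -- refine block -------------------------------------------------------------

def test_refine_block_gamma_zero_passthrough(rng):
    block = RefineBlock(4, np.random.default_rng(9))
    block.gamma1.data = np.float32(0.0)
    block.gamma2.data = np.float32(0.0)
    z = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
    o_prev = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
    p_prev = rng.uniform(size=(1, 1, 4, 4)).astype(np.float32)
    z_out, p = block(Tensor(z), Tensor(o_prev), Tensor(p_prev))
    np.testing.assert_allclose(z_out.data, o_prev, atol=1e-7)
    assert p.data.min() >= 0 and p.data.max() <= 1
    with pytest.raises(ValueError):
        block(Tensor(z), Tensor(o_prev[:, :, :2, :2]), Tensor(p_prev))


def test_refine_block_matches_scripted_oracle(rng):
    """Straight-line independent evaluation of the combination
    o_prev - g1*Attn_fg(P z) + g2*Attn_bg((1-P) z) on a hand-sized case."""
    block = RefineBlock(2, np.random.default_rng(10))
    z = rng.normal(size=(2, 2, 2)).astype(np.float32)
    o_prev = rng.normal(size=(2, 2, 2)).astype(np.float32)
    p_prev = rng.uniform(size=(2, 2)).astype(np.float32)
    z_out, p_out = block(Tensor(z[None]), Tensor(o_prev[None]),
                         Tensor(p_prev[None, None]))

    z_all, _ = naive_spatial_attention(z.astype(float),
                                       *attention_weights(block.attn_all))
    z_fg, _ = naive_spatial_attention(z_all * p_prev,
                                      *attention_weights(block.attn_fg))
    z_bg, _ = naive_spatial_attention(z_all * (1 - p_prev),
                                      *attention_weights(block.attn_bg))
    g1 = float(block.gamma1.data)
    g2 = float(block.gamma2.data)
    expected_z = o_prev - g1 * z_fg + g2 * z_bg
    head_w = block.head.weight.data.astype(float)
    head_b = block.head.bias.data.astype(float)
    expected_p = 1.0 / (1.0 + np.exp(-conv1x1(expected_z, head_w, head_b)))
    np.testing.assert_allclose(z_out.data[0], expected_z, atol=1e-5)
    np.testing.assert_allclose(p_out.data[0], expected_p, atol=1e-5)


# -- full forward -------------------------------------------------------------

def test_forward_pyramid_shapes_range_determinism():
    model = GANet(GANetConfig(depth=3, base_channels=8), seed=2).eval()
    x = np.random.default_rng(0).random((2, 3, 64, 64), dtype=np.float32)
    pyr = model(Tensor(x))
    assert [tuple(p.shape[-2:]) for p in pyr.masks] == [(32, 32), (16, 16),
                                                        (8, 8)]
    assert tuple(pyr.full_res.shape[-2:]) == (64, 64)
    for p in pyr.masks:
        assert p.data.min() >= 0 and p.data.max() <= 1
    sizes = [p.shape[-1] for p in reversed(pyr.masks)]
    assert sizes == sorted(sizes)
    pyr2 = model(Tensor(x))
    for a, b in zip(pyr.masks, pyr2.masks):
        np.testing.assert_array_equal(a.data, b.data)


def test_gradient_reaches_every_parameter():
    """Deep supervision leaves no dead branch: every learned kernel gets a
    nonzero gradient on a random batch."""
    model = GANet(GANetConfig(depth=3, base_channels=8), seed=3)
    rng = np.random.default_rng(1)
    x = rng.random((2, 3, 32, 32), dtype=np.float32)
    y = (rng.random((2, 32, 32)) > 0.6).astype(np.float32)
    loss = multiscale_loss(model(Tensor(x)), y, LossConfig())
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"no gradient reached {name}"
        assert np.abs(p.grad).max() > 0, f"zero gradient at {name}"


def test_checkpoint_roundtrip(tmp_path):
    model = GANet(GANetConfig(depth=2, base_channels=4), seed=4).eval()
    x = np.random.default_rng(2).random((1, 3, 32, 32), dtype=np.float32)
    ref = model(Tensor(x)).full_res.data
    save_checkpoint(model, tmp_path / "m.npz")
    loaded = load_checkpoint(tmp_path / "m.npz").eval()
    np.testing.assert_array_equal(loaded(Tensor(x)).full_res.data, ref)
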