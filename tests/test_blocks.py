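"""Block semantics: residual identities, attention gates, oracle equivalence."""

import numpy as np
import pytest

from jujubenet.models import (
    CBAM,
    CBAMConfig,
    ChannelAttention,
    ConvNeXtBlock,
    MDCBlock,
    MDCVariant,
    SpatialAttention,
    drop_path,
)
from jujubenet.nn import Tensor

from oracles import naive_cbam, naive_convnext_block, naive_mdc_block


def _randomize_gammas(blk, rng):
    for name in ("gamma", "a_gamma", "b_gamma"):
        if hasattr(blk, name):
            getattr(blk, name).data = rng.normal(0, 0.5, getattr(blk, name).data.shape).astype(
                np.float32
            )


# ---------------------------------------------------------------------------
# Residual identities and shapes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("make", [
    lambda rng: ConvNeXtBlock(8, layer_scale_init=0.0, rng=rng),
    lambda rng: MDCBlock(8, MDCVariant(), layer_scale_init=0.0, rng=rng),
    lambda rng: MDCBlock(8, MDCVariant(2, 3, "per_conv"), layer_scale_init=0.0, rng=rng),
])
def test_residual_identity_at_zero_layer_scale(make, rng):
    blk = make(rng).eval()
    x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
    out = blk(Tensor(x)).data
    assert np.array_equal(out, x)


def test_blocks_preserve_shape(rng):
    x = rng.normal(size=(1, 96, 56, 56)).astype(np.float32)
    assert MDCBlock(96, MDCVariant(), rng=rng).eval()(Tensor(x)).shape == x.shape
    y = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
    assert ConvNeXtBlock(8, rng=rng).eval()(Tensor(y)).shape == y.shape


def test_mdc_block_rejects_odd_channels():
    with pytest.raises(ValueError, match="even"):
        MDCBlock(7, MDCVariant())


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence (<= 6x6 spatial inputs)
# ---------------------------------------------------------------------------

def test_convnext_block_matches_naive_loop_oracle(rng):
    blk = ConvNeXtBlock(4, rng=rng).eval()
    _randomize_gammas(blk, rng)
    x = rng.normal(size=(4, 3, 3)).astype(np.float32)
    got = blk(Tensor(x[None])).data[0]
    want = naive_convnext_block(x, blk)
    assert np.allclose(got, want, rtol=1e-5, atol=1e-6)


@pytest.mark.parametrize("variant", [
    MDCVariant(4, 3, "per_conv"),
    MDCVariant(4, 5, "none"),
    MDCVariant(2, 7, "single_final"),
])
def test_mdc_block_matches_naive_loop_oracle(variant, rng):
    blk = MDCBlock(4, variant, rng=rng).eval()
    _randomize_gammas(blk, rng)
    x = rng.normal(size=(4, 4, 4)).astype(np.float32)
    got = blk(Tensor(x[None])).data[0]
    want = naive_mdc_block(x, blk)
    assert np.allclose(got, want, rtol=1e-5, atol=1e-6)


def test_cbam_matches_naive_oracle(rng):
    mod = CBAM(4, CBAMConfig(reduction_ratio=2, spatial_kernel=3), rng=rng).eval()
    x = rng.normal(size=(4, 6, 6)).astype(np.float32)
    got = mod(Tensor(x[None])).data[0]
    want = naive_cbam(x, mod)
    assert np.allclose(got, want, rtol=1e-5, atol=1e-6)


# ---------------------------------------------------------------------------
# Attention gate closed forms and bounds
# ---------------------------------------------------------------------------

def _zero_params(mod):
    for _, p in mod.named_parameters():
        p.data = np.zeros_like(p.data)


def test_channel_attention_zero_weights_gives_half_gate(rng):
    att = ChannelAttention(16, CBAMConfig(), rng=rng)
    _zero_params(att)
    gate = att(Tensor(rng.normal(size=(1, 16, 7, 7)).astype(np.float32)))
    assert gate.shape == (1, 16, 1, 1)
    assert np.allclose(gate.data, 0.5)


def test_channel_attention_constant_map_closed_form(rng):
    # spatially constant channels: avg-pool equals max-pool, so the gate is
    # sigmoid(2 * MLP(channel means))
    att = ChannelAttention(2, CBAMConfig(reduction_ratio=2), rng=rng)
    att.fc1.weight.data = np.array([[0.5], [-0.25]], dtype=np.float32)
    att.fc1.bias.data = np.array([0.1], dtype=np.float32)
    att.fc2.weight.data = np.array([[1.0, -2.0]], dtype=np.float32)
    att.fc2.bias.data = np.array([0.05, -0.05], dtype=np.float32)
    means = np.array([0.8, -0.4], dtype=np.float32)
    x = np.broadcast_to(means[:, None, None], (2, 2, 2)).astype(np.float32)
    gate = att(Tensor(x[None])).data[0, :, 0, 0]
    h = max(0.0, 0.5 * 0.8 - 0.25 * (-0.4) + 0.1)
    mlp_out = np.array([h * 1.0 + 0.05, h * -2.0 - 0.05])
    want = 1.0 / (1.0 + np.exp(-2.0 * mlp_out))
    assert np.allclose(gate, want, rtol=1e-5)


def test_spatial_attention_zero_conv_gives_half_gate(rng):
    att = SpatialAttention(CBAMConfig(), rng=rng)
    _zero_params(att)
    gate = att(Tensor(rng.normal(size=(1, 8, 14, 14)).astype(np.float32)))
    assert gate.shape == (1, 1, 14, 14)
    assert np.allclose(gate.data, 0.5)


def test_cbam_zero_weights_quarters_input(rng):
    mod = CBAM(16, CBAMConfig(), rng=rng)
    _zero_params(mod)
    x = rng.normal(size=(2, 16, 4, 4)).astype(np.float32)
    out = mod(Tensor(x)).data
    assert np.allclose(out, 0.25 * x, rtol=1e-6)


def test_cbam_gates_shrink_magnitudes(rng):
    mod = CBAM(8, CBAMConfig(reduction_ratio=4), rng=rng)
    x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
    out = mod(Tensor(x)).data
    assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


def test_channel_attention_rejects_indivisible_channels(rng):
    with pytest.raises(ValueError, match="divide"):
        ChannelAttention(10, CBAMConfig(reduction_ratio=16), rng=rng)


# ---------------------------------------------------------------------------
# Drop path
# ---------------------------------------------------------------------------

def test_drop_path_identity_cases(rng):
    x = Tensor(rng.normal(size=(4, 3, 2, 2)).astype(np.float32))
    assert np.array_equal(drop_path(x, 0.0, True, np.random.default_rng(0)).data, x.data)
    assert np.array_equal(drop_path(x, 0.7, False, np.random.default_rng(0)).data, x.data)
    with pytest.raises(ValueError):
        drop_path(x, 1.0, True, np.random.default_rng(0))


def test_drop_path_is_unbiased():
    # 10,000 unit samples at rate 0.5: the empirical mean of the kept/rescaled
    # values must lie within 3 standard errors of 1
    gen = np.random.default_rng(42)
    x = Tensor(np.ones((10000, 1, 1, 1), dtype=np.float32))
    out = drop_path(x, 0.5, True, gen).data
    se = 1.0 / np.sqrt(10000)  # per-sample std is 1 at rate 0.5 (values 0 or 2)
    assert abs(out.mean() - 1.0) < 3 * se
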