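"""Attention blocks against literal loop-based transcriptions of their math."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdparts.attention_blocks import (CBAM, ChannelAttention,
                                        ChannelAttentionParams, Res2NetCBAM,
                                        Res2NetCbamParams, SpatialAttention,
                                        SpatialAttentionParams, cbam,
                                        channel_attention, res2net_cbam,
                                        spatial_attention)
from birdparts.autodiff import Tensor, no_grad

import oracles


class TestChannelAttention:
    def test_zero_weights_give_half(self):
        p = ChannelAttentionParams(w0=np.zeros((2, 8)), w1=np.zeros((8, 2)))
        out = channel_attention(np.random.default_rng(0).random((8, 5, 5)), p)
        assert np.allclose(out, 0.5)

    def test_constant_map_pools_equal(self, rng):
        """Spatially constant input: avg == max, so Mc = sigma(2·MLP(c))."""
        p = ChannelAttentionParams.random(4, r=2, rng=rng)
        const = np.tile(rng.random((4, 1, 1)), (1, 6, 3))
        out = channel_attention(const, p)
        vec = const[:, 0, 0]
        mlp = p.w1 @ np.maximum(p.w0 @ vec, 0)
        assert np.allclose(out, 1 / (1 + np.exp(-2 * mlp)), rtol=1e-10)

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            c = int(rng.integers(2, 9)) * 2
            f = rng.standard_normal((c, int(rng.integers(2, 7)),
                                     int(rng.integers(2, 7))))
            p = ChannelAttentionParams.random(c, r=2, rng=rng)
            got = channel_attention(f, p)
            want = oracles.channel_attention_oracle(f, p.w0, p.w1)
            assert np.allclose(got, want, rtol=1e-5)
            assert np.all((got > 0) & (got < 1))


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        p = SpatialAttentionParams(kernel=np.zeros((1, 2, 7, 7)))
        out = spatial_attention(rng.random((3, 6, 6)), p)
        assert np.allclose(out, 0.5)

    def test_constant_input_constant_output_interior(self, rng):
        """Away from borders a constant map gives a constant attention map."""
        p = SpatialAttentionParams.random(rng=rng)
        out = spatial_attention(np.full((3, 20, 20), 1.7), p)
        interior = out[7:-7, 7:-7]
        assert np.allclose(interior, interior[0, 0], rtol=1e-10)

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(25):
            f = rng.standard_normal((int(rng.integers(1, 5)), 8, 8))
            p = SpatialAttentionParams.random(rng=rng)
            got = spatial_attention(f, p)
            want = oracles.spatial_attention_oracle(f, p.kernel)
            assert got.shape == f.shape[1:]
            assert np.allclose(got, want, rtol=1e-5)


class TestCbam:
    def test_zero_input_zero_output(self, rng):
        ca = ChannelAttentionParams.random(4, r=2, rng=rng)
        sa = SpatialAttentionParams.random(rng=rng)
        assert np.allclose(cbam(np.zeros((4, 5, 5)), ca, sa), 0.0)

    def test_all_zero_params_scale_by_quarter(self, rng):
        """Both gates sit at 0.5, so the output is F/4."""
        f = rng.standard_normal((6, 4, 4))
        ca = ChannelAttentionParams(w0=np.zeros((3, 6)), w1=np.zeros((6, 3)))
        sa = SpatialAttentionParams(kernel=np.zeros((1, 2, 7, 7)))
        assert np.allclose(cbam(f, ca, sa), 0.25 * f, rtol=1e-10)

    def test_matches_composition_oracle(self, rng):
        for _ in range(25):
            c = int(rng.integers(2, 7)) * 2
            f = rng.standard_normal((c, 6, 6))
            ca = ChannelAttentionParams.random(c, r=2, rng=rng)
            sa = SpatialAttentionParams.random(rng=rng)
            got = cbam(f, ca, sa)
            want = oracles.cbam_oracle(f, ca.w0, ca.w1, sa.kernel)
            assert got.shape == f.shape
            assert np.allclose(got, want, rtol=1e-5)


class TestRes2NetCbam:
    def test_scale_one_has_no_group_convs(self, rng):
        p = Res2NetCbamParams.random(8, scale=1, rng=rng)
        assert p.groups == []
        out = res2net_cbam(rng.standard_normal((8, 5, 5)), p)
        assert out.shape == (8, 5, 5)

    def test_zero_convolutions_are_pure_residual(self, rng):
        """Zero conv path makes Y = 0 and F2 = 0, so the unit is the identity."""
        p = Res2NetCbamParams.random(8, scale=4, rng=rng)
        p.entry = np.zeros_like(p.entry)
        x = rng.standard_normal((8, 6, 6))
        assert np.allclose(res2net_cbam(x, p), x, atol=1e-12)

    def test_matches_literal_equation_oracle(self, rng):
        for _ in range(25):
            p = Res2NetCbamParams.random(8, scale=4, r=2, rng=rng)
            x = rng.standard_normal((8, 4, 4))
            got = res2net_cbam(x, p)
            want = oracles.res2net_cbam_oracle(x, p)
            assert np.allclose(got, want, rtol=1e-5)

    def test_indivisible_scale_rejected(self):
        with pytest.raises(ValueError):
            Res2NetCBAM(10, 10, scale=4)
        with pytest.raises(ValueError):
            Res2NetCBAM(8, 16, scale=4)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(c=st.sampled_from([4, 8, 12]), h=st.integers(2, 8), w=st.integers(2, 8),
       n=st.integers(1, 3))
def test_blocks_preserve_shape_and_bound_attention(c, h, w, n):
    """Module forms: shape preservation and (0,1)-bounded attention maps."""
    rng = np.random.default_rng(c * 1000 + h * 100 + w * 10 + n)
    x = Tensor(rng.standard_normal((n, c, h, w)).astype(np.float32))
    with no_grad():
        ca = ChannelAttention(c, r=4).eval()(x)
        sa = SpatialAttention().eval()(x)
        cb = CBAM(c, r=4).eval()(x)
        rb = Res2NetCBAM(c, c, scale=2, r=4).eval()(x)
    assert ca.shape == (n, c, 1, 1)
    assert np.all((ca.data > 0) & (ca.data < 1))
    assert sa.shape == (n, 1, h, w)
    assert np.all((sa.data > 0) & (sa.data < 1))
    assert cb.shape == x.shape
    assert rb.shape == x.shape
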