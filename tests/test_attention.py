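"""Attention blocks: closed forms at zero weights, oracle equivalence, ranges."""
import numpy as np
import pytest

from sswan.attention import (
    ChannelAttentionParams,
    SpatialAttentionParams,
    channel_attention,
    channel_descriptor,
    identity_conv_kernel,
    spatial_attention,
    spatial_descriptor,
    ssab_block,
)

from oracles import channel_descriptor_oracle, spatial_descriptor_oracle


def zero_channel_params(width=4, reduction=2):
    hidden = width // reduction
    return ChannelAttentionParams(
        w1=np.zeros((width, hidden)), b1=np.zeros(hidden),
        w2=np.zeros((hidden, width)), b2=np.zeros(width))


def zero_spatial_params():
    return SpatialAttentionParams(kernel=np.zeros((7, 7, 2, 1)), bias=0.0)


def random_channel_params(width, reduction, rng):
    hidden = width // reduction
    return ChannelAttentionParams(
        w1=rng.normal(size=(width, hidden)), b1=rng.normal(size=hidden),
        w2=rng.normal(size=(hidden, width)), b2=rng.normal(size=width))


class TestChannelAttention:
    def test_zero_weights_give_half_descriptor(self, rng):
        feat = rng.normal(size=(6, 5, 4))
        np.testing.assert_array_equal(
            channel_descriptor(feat, zero_channel_params()), np.full(4, 0.5))
        np.testing.assert_allclose(
            channel_attention(feat, zero_channel_params()), 0.5 * feat,
            atol=1e-12)

    def test_constant_map_doubles_the_shared_mlp(self, rng):
        """On a constant map max-pool equals avg-pool, so the gate is
        sigmoid(2 * MLP(p))."""
        p = random_channel_params(4, 2, rng)
        const = np.ones((3, 3, 1)) * np.array([1.0, -2.0, 0.5, 3.0])
        desc = channel_descriptor(const, p, alpha=0.2)
        vec = np.array([1.0, -2.0, 0.5, 3.0])
        hidden = np.where((vec @ p.w1 + p.b1) >= 0, vec @ p.w1 + p.b1,
                          0.2 * (vec @ p.w1 + p.b1))
        mlp = hidden @ p.w2 + p.b2
        np.testing.assert_allclose(desc, 1 / (1 + np.exp(-2 * mlp)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        feat = rng.normal(size=(8, 8, 4))
        p = random_channel_params(4, 2, rng)
        desc = channel_descriptor(feat, p, alpha=0.1)
        ref = channel_descriptor_oracle(feat, p.w1, p.b1, p.w2, p.b2, alpha=0.1)
        np.testing.assert_allclose(desc, ref, atol=1e-12)
        np.testing.assert_allclose(
            channel_attention(feat, p, alpha=0.1), feat * ref, atol=1e-12)

    def test_shared_mlp_is_symmetric_in_pooled_vectors(self, rng):
        """Summing before the sigmoid makes the two pooled paths exchangeable:
        feeding (max, avg) or (avg, max) through the shared MLP must give the
        same gate."""
        p = random_channel_params(8, 4, rng)
        feat = rng.normal(size=(5, 7, 8))
        pmax = feat.max(axis=(0, 1))
        pavg = feat.mean(axis=(0, 1))

        def mlp(v):
            h = v @ p.w1 + p.b1
            h = np.where(h >= 0, h, 0.2 * h)
            return h @ p.w2 + p.b2

        gate_a = 1 / (1 + np.exp(-(mlp(pmax) + mlp(pavg))))
        gate_b = 1 / (1 + np.exp(-(mlp(pavg) + mlp(pmax))))
        np.testing.assert_array_equal(gate_a, gate_b)
        np.testing.assert_allclose(channel_descriptor(feat, p), gate_a, atol=1e-12)

    def test_descriptor_strictly_inside_unit_interval(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            d = channel_descriptor(r.normal(size=(6, 6, 8)),
                                   random_channel_params(8, 4, r))
            assert np.all(d > 0) and np.all(d < 1)

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_descriptor(rng.normal(size=(4, 4, 6)), zero_channel_params(4, 2))


class TestSpatialAttention:
    def test_zero_kernel_gives_half_everywhere(self, rng):
        feat = rng.normal(size=(5, 6, 3))
        np.testing.assert_array_equal(
            spatial_descriptor(feat, zero_spatial_params()), np.full((5, 6), 0.5))
        np.testing.assert_allclose(
            spatial_attention(feat, zero_spatial_params()), 0.5 * feat, atol=1e-12)

    def test_uniform_single_channel_gives_uniform_gate(self):
        """A constant one-channel map makes max and avg maps equal constants
        away from the zero-padded border, so the interior gate is uniform."""
        rng = np.random.default_rng(3)
        p = SpatialAttentionParams(kernel=rng.normal(size=(7, 7, 2, 1)), bias=0.4)
        feat = np.full((16, 16, 1), 1.7)
        d = spatial_descriptor(feat, p)
        interior = d[3:-3, 3:-3]
        expected = 1 / (1 + np.exp(-(1.7 * p.kernel.sum() + 0.4)))
        np.testing.assert_allclose(interior, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        feat = rng.normal(size=(8, 8, 4))
        p = SpatialAttentionParams(kernel=rng.normal(size=(7, 7, 2, 1)),
                                   bias=float(rng.normal()))
        d = spatial_descriptor(feat, p)
        ref = spatial_descriptor_oracle(feat, p.kernel, p.bias)
        np.testing.assert_allclose(d, ref, atol=1e-10)
        np.testing.assert_allclose(
            spatial_attention(feat, p), feat * ref[..., None], atol=1e-10)

    def test_gate_strictly_inside_unit_interval(self, rng):
        p = SpatialAttentionParams(kernel=rng.normal(size=(7, 7, 2, 1)), bias=0.0)
        d = spatial_descriptor(rng.normal(size=(9, 9, 5)), p)
        assert np.all(d > 0) and np.all(d < 1)

    def test_kernel_shape_enforced(self):
        with pytest.raises(ValueError):
            SpatialAttentionParams(kernel=np.zeros((5, 5, 2, 1)))


class TestSSAB:
    def test_all_zero_weights_is_identity(self, rng):
        """Zero conv makes the block body vanish, leaving only the skip."""
        feat = rng.normal(size=(6, 6, 4))
        out = ssab_block(feat, np.zeros((3, 3, 4, 4)), np.zeros(4),
                         zero_channel_params(4, 2), zero_spatial_params())
        np.testing.assert_allclose(out, feat, atol=1e-12)

    def test_identity_conv_with_zero_attention_scales_by_1p25(self, rng):
        """Identity conv + two 0.5 gates + skip: out = 0.25 x + x."""
        feat = rng.normal(size=(6, 6, 4))
        out = ssab_block(feat, identity_conv_kernel(4), np.zeros(4),
                         zero_channel_params(4, 2), zero_spatial_params())
        np.testing.assert_allclose(out, 1.25 * feat, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_block_composes_suboperations(self, seed):
        rng = np.random.default_rng(seed)
        feat = rng.normal(size=(8, 8, 4))
        kernel = rng.normal(size=(3, 3, 4, 4)) * 0.3
        bias = rng.normal(size=4) * 0.1
        cp = random_channel_params(4, 2, rng)
        sp = SpatialAttentionParams(kernel=rng.normal(size=(7, 7, 2, 1)),
                                    bias=float(rng.normal()))
        from oracles import conv2d_same_oracle

        conv = conv2d_same_oracle(feat, kernel, bias)
        gated = conv * channel_descriptor_oracle(
            conv, cp.w1, cp.b1, cp.w2, cp.b2, alpha=0.2)
        gated = gated * spatial_descriptor_oracle(gated, sp.kernel, sp.bias)[..., None]
        np.testing.assert_allclose(
            ssab_block(feat, kernel, bias, cp, sp), gated + feat, atol=1e-9)

    @pytest.mark.parametrize("shape", [(4, 4, 4), (8, 6, 8), (5, 9, 16)])
    def test_shape_preserved(self, shape, rng):
        w = shape[2]
        out = ssab_block(rng.normal(size=shape), np.zeros((3, 3, w, w)),
                         np.zeros(w), zero_channel_params(w, 2),
                         zero_spatial_params())
        assert out.shape == shape

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssab_block(rng.normal(size=(4, 4, 4)), np.zeros((3, 3, 8, 8)),
                       np.zeros(8), zero_channel_params(8, 2), zero_spatial_params())
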