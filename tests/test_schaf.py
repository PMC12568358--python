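"""scHAF attention block: loop oracles, fusion algebra, shape conservation."""

import numpy as np
import pytest

from udrnet import Schaf, SchafConfig
from udrnet._autodiff import Tensor

from conftest import numerical_gradient


def _block(channels, activation="none", seed=0):
    return Schaf(channels, SchafConfig(attention_activation=activation),
                 np.random.default_rng(seed))


def _rand(rng, shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


class TestChannelBranch:
    def test_matches_elementwise_loop_oracle(self, rng):
        blk = _block(2, activation="none")
        f = _rand(rng, (1, 2, 3, 3, 3))
        out = blk.channel_branch(f).data
        w = blk.spatial_map_conv.weight.data  # (1, 2, 1, 1, 1)
        for c in range(2):
            for z in range(3):
                for y in range(3):
                    for x in range(3):
                        amap = sum(w[0, ci, 0, 0, 0] * f.data[0, ci, z, y, x]
                                   for ci in range(2)) + blk.spatial_map_conv.bias.data[0]
                        assert out[0, c, z, y, x] == pytest.approx(
                            amap * f.data[0, c, z, y, x], rel=1e-4)

    def test_forced_identity_and_annihilation(self, rng):
        blk = _block(3, activation="none")
        f = _rand(rng, (1, 3, 4, 4, 4))
        blk.spatial_map_conv.weight.data[:] = 0
        blk.spatial_map_conv.bias.data[:] = 1.0  # attention map == 1 everywhere
        assert np.allclose(blk.channel_branch(f).data, f.data, atol=1e-6)
        blk.spatial_map_conv.bias.data[:] = 0.0  # == 0 everywhere
        assert np.all(blk.channel_branch(f).data == 0)


class TestSpaceBranch:
    def test_pooled_vectors_match_loop_oracle(self, rng):
        f = _rand(rng, (1, 2, 2, 2, 2))
        from udrnet._autodiff import global_maxpool
        mp = global_maxpool(f).data
        ap = f.mean(axis=(2, 3, 4)).data
        for c in range(2):
            vals = [f.data[0, c, z, y, x]
                    for z in range(2) for y in range(2) for x in range(2)]
            assert mp[0, c] == pytest.approx(max(vals), rel=1e-6)
            assert ap[0, c] == pytest.approx(np.mean(vals), rel=1e-5)

    def test_constant_channels_give_equal_pools(self):
        data = np.stack([np.full((2, 2, 2), 3.0), np.full((2, 2, 2), -1.0)])[None]
        blk = _block(2)
        f = Tensor(data.astype(np.float32))
        from udrnet._autodiff import global_maxpool
        assert np.allclose(global_maxpool(f).data, [[3.0, -1.0]])
        assert np.allclose(f.mean(axis=(2, 3, 4)).data, [[3.0, -1.0]])

    def test_forced_identity_weights(self, rng):
        blk = _block(2, activation="none")
        f = _rand(rng, (1, 2, 3, 3, 3))
        blk.mlp1.weight.data[:] = 0
        blk.mlp1.bias.data[:] = 0
        blk.mlp2.weight.data[:] = 0
        blk.mlp2.bias.data[:] = 1.0  # per-channel weights == 1
        assert np.allclose(blk.space_branch(f).data, f.data, atol=1e-6)

    def test_mlp_hidden_width_compress_restore(self):
        assert SchafConfig().hidden_width(8) == 8     # 2C -> C -> C
        assert SchafConfig(mlp_ratio=4).hidden_width(8) == 4
        assert SchafConfig(mlp_ratio=100).hidden_width(1) == 1


class TestHybridFuse:
    def test_equal_inputs_give_square_double_same(self, rng):
        """fc == fs == X: the three fused maps are X^2, 2X and X."""
        blk = _block(2, activation="none")
        x = _rand(rng, (1, 2, 3, 3, 3))
        from udrnet._autodiff import concat, maximum
        fused = concat([x * x, x + x, maximum(x, x)], axis=1).data
        assert np.allclose(fused[:, 0:2], x.data ** 2, atol=1e-6)
        assert np.allclose(fused[:, 2:4], 2 * x.data, atol=1e-6)
        assert np.allclose(fused[:, 4:6], x.data, atol=1e-6)
        assert blk.hybrid_fuse(x, x).shape == x.shape

    def test_zero_branch_case(self, rng):
        x = _rand(rng, (1, 2, 2, 2, 2))
        zero = Tensor(np.zeros_like(x.data))
        from udrnet._autodiff import concat, maximum
        fused = concat([zero * x, zero + x, maximum(zero, x)], axis=1).data
        assert np.all(fused[:, 0:2] == 0)
        assert np.allclose(fused[:, 2:4], x.data)
        assert np.allclose(fused[:, 4:6], np.maximum(0, x.data))

    def test_pre_conv_maps_match_loop_oracle(self, rng):
        fc = _rand(rng, (1, 2, 3, 3, 3))
        fs = _rand(rng, (1, 2, 3, 3, 3))
        from udrnet._autodiff import concat, maximum
        fused = concat([fc * fs, fc + fs, maximum(fc, fs)], axis=1).data
        for c in range(2):
            for z in range(3):
                for y in range(3):
                    for x in range(3):
                        a, b = fc.data[0, c, z, y, x], fs.data[0, c, z, y, x]
                        assert fused[0, c, z, y, x] == pytest.approx(a * b, rel=1e-5)
                        assert fused[0, 2 + c, z, y, x] == pytest.approx(a + b, rel=1e-5)
                        assert fused[0, 4 + c, z, y, x] == pytest.approx(max(a, b), rel=1e-5)

    def test_fusion_symmetry_and_dominance(self, rng):
        from udrnet._autodiff import maximum
        fc = _rand(rng, (1, 3, 2, 2, 2))
        fs = _rand(rng, (1, 3, 2, 2, 2))
        assert np.allclose((fc + fs).data, (fs + fc).data)
        m = maximum(fc, fs).data
        assert np.all(m >= fc.data) and np.all(m >= fs.data)

    def test_shape_mismatch_rejected(self, rng):
        blk = _block(2)
        with pytest.raises(ValueError, match="shapes differ"):
            blk.hybrid_fuse(_rand(rng, (1, 2, 2, 2, 2)), _rand(rng, (1, 2, 4, 4, 4)))


class TestForward:
    @pytest.mark.parametrize("channels,spatial", [(4, 4), (8, 6)])
    def test_shape_conservation(self, rng, channels, spatial):
        blk = _block(channels)
        f = _rand(rng, (1, channels, spatial, spatial, spatial))
        assert blk(f).shape == f.shape

    def test_gradient_wrt_input_finite_and_nonzero(self, rng):
        blk = _block(2)
        f = Tensor(rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float32),
                   requires_grad=True)
        blk(f).sum().backward()
        assert np.all(np.isfinite(f.grad))
        assert np.abs(f.grad).max() > 0

    def test_gradient_wrt_parameters_matches_numerics(self, rng):
        blk = _block(2, activation="sigmoid")
        f = Tensor(rng.normal(size=(1, 2, 2, 2, 2)).astype(np.float32))
        loss = lambda: blk(f).square().sum() * 0.1
        loss().backward()
        w = blk.mlp2.weight
        ng = numerical_gradient(lambda: float(loss().data), w.data)
        assert np.abs(ng - w.grad).max() / (np.abs(ng).max() + 1e-6) < 5e-2
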