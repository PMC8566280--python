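"""Convolution primitives vs dense brute-force oracles, and gradient checks."""

import numpy as np
import pytest

from dstripe.layers import (
    BatchNorm,
    BilinearUpsample,
    ConcatPool,
    ConvBlock,
    DepthwiseConv3d,
    PointwiseConv,
    SeparableConv,
    gaussian_kernel_1d,
    FixedGaussianInplane,
    FixedHighpassZ,
)


def brute_force_depthwise(x, W, b, z_dilation=1):
    """Dense zero-padded depthwise conv oracle (nested loops)."""
    C, X, Y, Z = x.shape
    out = np.zeros_like(x)
    for c in range(C):
        for ix in range(X):
            for iy in range(Y):
                for iz in range(Z):
                    acc = b[c]
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                jx, jy = ix + i - 1, iy + j - 1
                                jz = iz + (k - 1) * z_dilation
                                if 0 <= jx < X and 0 <= jy < Y and 0 <= jz < Z:
                                    acc += W[c, i, j, k] * x[c, jx, jy, jz]
                    out[c, ix, iy, iz] = acc
    return out


def _f64(layer):
    for k in layer.params:
        layer.params[k] = layer.params[k].astype(np.float64)
        layer.grads[k] = layer.grads[k].astype(np.float64)
    return layer


class TestDepthwiseConv:
    @pytest.mark.parametrize("dil", [1, 2, 3])
    def test_matches_brute_force(self, rng, dil):
        layer = _f64(DepthwiseConv3d(3, z_dilation=dil, rng=rng))
        x = rng.normal(size=(3, 5, 6, 7))
        y, _ = layer.forward(x)
        ref = brute_force_depthwise(x, layer.params["W"], layer.params["b"], dil)
        np.testing.assert_allclose(y, ref, atol=1e-6)

    def test_identity_kernel_passthrough(self, rng):
        layer = _f64(DepthwiseConv3d(2, rng=rng))
        layer.params["W"][...] = 0.0
        layer.params["W"][:, 1, 1, 1] = 1.0
        layer.params["b"][...] = 0.0
        x = rng.normal(size=(2, 4, 4, 5))
        y, _ = layer.forward(x)
        np.testing.assert_allclose(y, x, atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        layer = _f64(DepthwiseConv3d(2, z_dilation=2, rng=rng))
        x = rng.normal(size=(2, 4, 5, 6))
        y, cache = layer.forward(x)
        dy = rng.normal(size=y.shape)
        layer.zero_grad()
        dx = layer.backward(dy, cache)
        eps = 1e-6
        # input gradient
        for idx in [(0, 1, 2, 3), (1, 3, 4, 5), (0, 0, 0, 0)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = ((layer.forward(xp)[0] - layer.forward(xm)[0]) * dy).sum() / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-5, abs=1e-8)
        # weight gradient
        for widx in [(0, 0, 1, 2), (1, 2, 0, 1)]:
            old = layer.params["W"][widx]
            layer.params["W"][widx] = old + eps
            lp = (layer.forward(x)[0] * dy).sum()
            layer.params["W"][widx] = old - eps
            lm = (layer.forward(x)[0] * dy).sum()
            layer.params["W"][widx] = old
            assert layer.grads["W"][widx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


class TestSeparableConv:
    def test_parameter_counts(self, rng):
        assert SeparableConv(1, 16, rng=rng).n_params() == 60
        assert PointwiseConv(64, 32, rng=rng).n_params() == 2080
        assert PointwiseConv(32, 1, rng=rng).n_params() == 33

    def test_zero_weights_zero_output(self, rng):
        layer = SeparableConv(2, 4, rng=rng)
        for p in (layer.depthwise, layer.pointwise):
            for k in p.params:
                p.params[k][...] = 0.0
        y, _ = layer.forward(rng.normal(size=(2, 4, 4, 5)).astype(np.float64))
        np.testing.assert_allclose(y, 0.0)

    def test_identity_filters_and_summing_pointwise(self, rng):
        # centre-1 depthwise filters + all-ones pointwise = channel sum
        layer = SeparableConv(3, 2, rng=rng)
        _f64(layer.depthwise)
        _f64(layer.pointwise)
        layer.depthwise.params["W"][...] = 0.0
        layer.depthwise.params["W"][:, 1, 1, 1] = 1.0
        layer.depthwise.params["b"][...] = 0.0
        layer.pointwise.params["W"][...] = 1.0
        layer.pointwise.params["b"][...] = 0.0
        x = rng.normal(size=(3, 5, 5, 5))
        y, _ = layer.forward(x)
        ref = x.sum(axis=0)
        np.testing.assert_allclose(y[0], ref, atol=1e-10)
        np.testing.assert_allclose(y[1], ref, atol=1e-10)

    def test_single_output_channel_skips_pointwise(self, rng):
        layer = SeparableConv(1, 1, rng=rng)
        assert layer.pointwise is None
        assert layer.n_params() == 28


class TestConvBlock:
    def test_parameter_counts(self, rng):
        assert ConvBlock(16, rng=rng).n_params() == 2128
        assert ConvBlock(32, rng=rng).n_params() == 5792

    def test_zero_weights_relu_zero_output(self, rng):
        blk = ConvBlock(4, with_relu=True, rng=rng)
        for lyr in blk.branches + [blk.pointwise]:
            for k in lyr.params:
                lyr.params[k][...] = 0.0
        y, _ = blk.forward(rng.normal(size=(4, 4, 4, 8)).astype(np.float64))
        np.testing.assert_allclose(y, 0.0)

    def test_gradcheck(self, rng):
        blk = ConvBlock(2, with_relu=True, rng=rng)
        for lyr in blk.branches + [blk.pointwise]:
            _f64(lyr)
        x = rng.normal(size=(2, 4, 4, 8))
        y, cache = blk.forward(x)
        dy = rng.normal(size=y.shape)
        for lyr in blk.branches + [blk.pointwise]:
            lyr.zero_grad()
        dx = blk.backward(dy, cache)
        eps = 1e-6
        idx = (1, 2, 3, 4)
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = ((blk.forward(xp)[0] - blk.forward(xm)[0]) * dy).sum() / (2 * eps)
        assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestConcatPool:
    def test_constant_input_both_branches_constant(self):
        pool = ConcatPool(mode="factor")
        x = np.full((3, 8, 8, 4), 2.5)
        y, _ = pool.forward(x)
        assert y.shape == (6, 4, 4, 4)
        np.testing.assert_allclose(y, 2.5)

    def test_channel_doubling_and_shape(self, rng):
        pool = ConcatPool(mode="factor")
        y, _ = pool.forward(rng.normal(size=(16, 48, 48, 8)))
        assert y.shape == (32, 24, 24, 8)
        pool2 = ConcatPool(mode="adaptive", target=16)
        y2, _ = pool2.forward(y)
        assert y2.shape == (64, 16, 16, 8)

    def test_max_branch_dominates_average(self, rng):
        pool = ConcatPool(mode="adaptive", target=4)
        x = rng.normal(size=(2, 12, 12, 3))
        y, _ = pool.forward(x)
        assert np.all(y[2:] >= y[:2] - 1e-12)

    def test_gradcheck_both_modes(self, rng):
        for pool, shape in [
            (ConcatPool(mode="factor"), (2, 6, 6, 3)),
            (ConcatPool(mode="adaptive", target=3), (2, 7, 7, 3)),
        ]:
            x = rng.normal(size=shape)
            y, cache = pool.forward(x)
            dy = rng.normal(size=y.shape)
            dx = pool.backward(dy, cache)
            eps = 1e-6
            for idx in [(0, 1, 2, 1), (1, 4, 5, 2)]:
                xp = x.copy(); xp[idx] += eps
                xm = x.copy(); xm[idx] -= eps
                num = ((pool.forward(xp)[0] - pool.forward(xm)[0]) * dy).sum() / (2 * eps)
                assert dx[idx] == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestBatchNorm:
    def test_train_mode_normalises(self, rng):
        bn = BatchNorm(3)
        x = rng.normal(2.0, 3.0, size=(3, 6, 6, 6))
        y, _ = bn.forward(x, train=True)
        np.testing.assert_allclose(y.mean(axis=(1, 2, 3)), 0.0, atol=1e-7)
        np.testing.assert_allclose(y.std(axis=(1, 2, 3)), 1.0, atol=1e-3)

    def test_eval_uses_running_stats(self, rng):
        bn = BatchNorm(2)
        x = rng.normal(size=(2, 5, 5, 5))
        for _ in range(200):
            bn.forward(x, train=True)
        y_eval, _ = bn.forward(x, train=False)
        y_train, _ = bn.forward(x, train=True)
        np.testing.assert_allclose(y_eval, y_train, atol=1e-3)

    def test_gradcheck_train_mode(self, rng):
        bn = BatchNorm(2)
        x = rng.normal(size=(2, 4, 4, 4))
        y, cache = bn.forward(x, train=True)
        dy = rng.normal(size=y.shape)
        bn.zero_grad()
        dx = bn.backward(dy, cache)
        eps = 1e-6
        idx = (1, 2, 3, 0)
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = ((bn.forward(xp, True)[0] - bn.forward(xm, True)[0]) * dy).sum() / (2 * eps)
        assert dx[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestFixedFilters:
    def test_gaussian_kernel_unit_sum(self):
        k = gaussian_kernel_1d(1.5, 9)
        assert k.sum() == pytest.approx(1.0)
        assert np.argmax(k) == 4

    def test_inplane_impulse_matches_dense_2d_oracle(self):
        g = FixedGaussianInplane(sigma=1.5, size=9)
        x = np.zeros((1, 15, 15, 1))
        x[0, 7, 7, 0] = 1.0
        y, _ = g.forward(x)
        k = gaussian_kernel_1d(1.5, 9)
        dense = np.outer(k, k)
        ref = np.zeros((15, 15))
        for i in range(9):
            for j in range(9):
                ref[7 + i - 4, 7 + j - 4] = dense[i, j]
        np.testing.assert_allclose(y[0, :, :, 0], ref, atol=1e-12)

    def test_highpass_annihilates_z_constant_interior(self, rng):
        hp = FixedHighpassZ(sigma=1.0, size=9)
        x = np.tile(rng.normal(size=(1, 6, 6, 1)), (1, 1, 1, 20))
        y, _ = hp.forward(x)
        np.testing.assert_allclose(y[..., 5:15], 0.0, atol=1e-9)


class TestBilinearUpsample:
    def test_constant_preserved(self):
        up = BilinearUpsample(source=4, pool_factor=2)
        x = np.full((1, 4, 4, 3), 1.7)
        y, _ = up.forward(x, out_shape=(16, 16))
        np.testing.assert_allclose(y, 1.7, rtol=1e-12)

    def test_adjoint_consistency(self, rng):
        # <up(x), y> == <x, up^T(y)> for a linear operator
        up = BilinearUpsample(source=4, pool_factor=2)
        x = rng.normal(size=(1, 4, 4, 2))
        y, cache = up.forward(x, out_shape=(12, 12))
        dy = rng.normal(size=y.shape)
        dx = up.backward(dy, cache)
        assert (y * dy).sum() == pytest.approx(
            (x * dx).sum() + ((dy * up.forward(np.zeros_like(x), out_shape=(12, 12))[0]).sum()), rel=1e-9
        )
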