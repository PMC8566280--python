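"""Minimal numpy layer primitives with hand-written reverse-mode gradients.

All feature maps are stored channel-first, ``(C, X, Y, Z)``.  Every layer is
functional: ``forward`` returns ``(y, cache)`` and ``backward(dy, cache)``
returns ``dx`` while accumulating parameter gradients into ``self.grads``.
Caches are owned by the caller, so several forward passes through shared
weights can coexist before their backward passes (needed for the paired
augmentation losses and the finite-difference SURE term).

Convolutions use zero padding and stride 1 and are implemented as explicit
shift-accumulate loops over the (small) kernel support, which is both exact
and fast for 3×3×3 kernels on desk-scale volumes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Layer",
    "DepthwiseConv3d",
    "PointwiseConv",
    "SeparableConv",
    "ConvBlock",
    "BatchNorm",
    "ConcatPool",
    "ReLU",
    "DRC",
    "Log",
    "Exp",
    "FixedGaussianInplane",
    "FixedHighpassZ",
    "BilinearUpsample",
    "gaussian_kernel_1d",
]


def gaussian_kernel_1d(sigma: float, size: int) -> np.ndarray:
    """Unit-sum sampled Gaussian kernel of odd length ``size``."""
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    x = np.arange(size) - size // 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


class Layer:
    """Base: trainable parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


def _conv1d_axis(x: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Zero-padded same-size correlation with a symmetric 1D kernel along ``axis``."""
    kernel = kernel.astype(x.dtype, copy=False)
    k = len(kernel)
    p = k // 2
    pad = [(0, 0)] * x.ndim
    pad[axis] = (p, p)
    xp = np.pad(x, pad)
    out = np.zeros_like(x)
    sl = [slice(None)] * x.ndim
    n = x.shape[axis]
    for i in range(k):
        sl[axis] = slice(i, i + n)
        out += kernel[i] * xp[tuple(sl)]
    return out


class DepthwiseConv3d(Layer):
    """Per-channel 3D convolution, kernel (kx,ky,kz), z-dilation supported."""

    def __init__(self, channels: int, kernel=(3, 3, 3), z_dilation: int = 1, rng=None):
        super().__init__()
        self.channels = channels
        self.kernel = tuple(kernel)
        self.dilation = (1, 1, z_dilation)
        fan_in = int(np.prod(kernel))
        bound = 1.0 / np.sqrt(fan_in)
        rng = rng or np.random.default_rng()
        self._register("W", rng.uniform(-bound, bound, size=(channels,) + self.kernel))
        self._register("b", rng.uniform(-bound, bound, size=(channels,)))

    def _pads(self):
        return tuple(d * (k // 2) for k, d in zip(self.kernel, self.dilation))

    @staticmethod
    def _correlate_zdil(x, W, dz, out):
        """Per-channel correlation with z-dilation via z-decimation.

        Slices with index ≡ r (mod dz) only interact with each other, so a
        dilated kernel equals a compact kernel on each decimated sub-array
        (zero padding is preserved by the decimation).
        """
        C = x.shape[0]
        if dz == 1:
            for c in range(C):
                ndimage.correlate(x[c], W[c], output=out[c], mode="constant")
            return
        for r in range(dz):
            sub = np.ascontiguousarray(x[:, :, :, r::dz])
            tmp = np.empty_like(sub)
            for c in range(C):
                ndimage.correlate(sub[c], W[c], output=tmp[c], mode="constant")
            out[:, :, :, r::dz] = tmp

    def forward(self, x, train=True):
        y = np.empty_like(x)
        self._correlate_zdil(x, self.params["W"], self.dilation[2], y)
        y += self.params["b"][:, None, None, None]
        return y, {"x": x}

    def backward(self, dy, cache):
        dy = np.ascontiguousarray(dy)
        x = cache["x"]
        C, X, Y, Z = x.shape
        px, py, pz = self._pads()
        xp = np.pad(x, ((0, 0), (px, px), (py, py), (pz, pz)))
        dW = self.grads["W"]
        dx_, dy_, dz_ = self.dilation
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    sl = (
                        slice(None),
                        slice(i * dx_, i * dx_ + X),
                        slice(j * dy_, j * dy_ + Y),
                        slice(k * dz_, k * dz_ + Z),
                    )
                    dW[:, i, j, k] += np.einsum("cxyz,cxyz->c", dy, xp[sl])
        self.grads["b"] += dy.sum(axis=(1, 2, 3))
        # adjoint of zero-padded same-size correlation = correlate w/ flipped kernel
        Wf = np.ascontiguousarray(self.params["W"][:, ::-1, ::-1, ::-1])
        dx = np.empty(dy.shape, dtype=dy.dtype)
        self._correlate_zdil(dy, Wf, self.dilation[2], dx)
        return dx


class PointwiseConv(Layer):
    """1×1×1 convolution mixing channels: y = W x + b."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        bound = 1.0 / np.sqrt(in_channels)
        rng = rng or np.random.default_rng()
        self._register("W", rng.uniform(-bound, bound, size=(out_channels, in_channels)))
        self._register("b", rng.uniform(-bound, bound, size=(out_channels,)))

    def forward(self, x, train=True):
        y = np.einsum("oi,ixyz->oxyz", self.params["W"], x, optimize=True)
        y += self.params["b"][:, None, None, None]
        return y, {"x": x}

    def backward(self, dy, cache):
        x = cache["x"]
        self.grads["W"] += np.einsum("oxyz,ixyz->oi", dy, x, optimize=True)
        self.grads["b"] += dy.sum(axis=(1, 2, 3))
        # keep C-contiguous: downstream convolutions are stride-sensitive
        return np.ascontiguousarray(np.einsum("oi,oxyz->ixyz", self.params["W"], dy, optimize=True))


class SeparableConv(Layer):
    """Depthwise 3D filters followed by pointwise channel mixing.

    With a single output channel the pointwise stage is omitted, matching
    the convention that channel mixing only happens when out_channels > 1.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel=(3, 3, 3), rng=None):
        super().__init__()
        self.depthwise = DepthwiseConv3d(in_channels, kernel, rng=rng)
        self.pointwise = PointwiseConv(in_channels, out_channels, rng=rng) if out_channels > 1 else None

    def n_params(self):
        n = self.depthwise.n_params()
        if self.pointwise is not None:
            n += self.pointwise.n_params()
        return n

    def zero_grad(self):
        self.depthwise.zero_grad()
        if self.pointwise is not None:
            self.pointwise.zero_grad()

    def forward(self, x, train=True):
        h, c1 = self.depthwise.forward(x, train)
        if self.pointwise is None:
            return h, {"c1": c1, "c2": None}
        y, c2 = self.pointwise.forward(h, train)
        return y, {"c1": c1, "c2": c2}

    def backward(self, dy, cache):
        if self.pointwise is not None:
            dy = self.pointwise.backward(dy, cache["c2"])
        return self.depthwise.backward(dy, cache["c1"])


class ConvBlock(Layer):
    """Three dilated depthwise 3×3×3 convs (z-dilations 1,2,3) + 1×1×1 mix.

    The branches are channel-concatenated (3·ch) before the pointwise
    convolution maps back to ch channels; optional ReLU.  Maximum z
    receptive extent is 7 voxels (dilation 3).
    """

    def __init__(self, channels: int, with_relu: bool = False, rng=None):
        super().__init__()
        self.channels = channels
        self.with_relu = with_relu
        self.branches = [DepthwiseConv3d(channels, (3, 3, 3), z_dilation=d, rng=rng) for d in (1, 2, 3)]
        self.pointwise = PointwiseConv(3 * channels, channels, rng=rng)

    def n_params(self):
        return sum(b.n_params() for b in self.branches) + self.pointwise.n_params()

    def zero_grad(self):
        for b in self.branches:
            b.zero_grad()
        self.pointwise.zero_grad()

    def forward(self, x, train=True):
        outs, caches = [], []
        for b in self.branches:
            o, c = b.forward(x, train)
            outs.append(o)
            caches.append(c)
        h = np.concatenate(outs, axis=0)
        y, cp = self.pointwise.forward(h, train)
        relu_mask = None
        if self.with_relu:
            relu_mask = y > 0
            y = y * relu_mask
        return y, {"branch": caches, "cp": cp, "relu": relu_mask}

    def backward(self, dy, cache):
        if self.with_relu:
            dy = dy * cache["relu"]
        dh = self.pointwise.backward(dy, cache["cp"])
        ch = self.channels
        dx = None
        for i, b in enumerate(self.branches):
            d = b.backward(dh[i * ch : (i + 1) * ch], cache["branch"][i])
            dx = d if dx is None else dx + d
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation over the spatial extent (batch of 1).

    Training uses batch statistics and updates exponential running
    statistics (momentum 0.1); evaluation uses the running statistics.
    Only the affine scale and shift are trainable.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self._register("gamma", np.ones(channels))
        self._register("beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        y = self.params["gamma"][:, None, None, None] * xhat + self.params["beta"][:, None, None, None]
        return y, {"xhat": xhat, "inv": inv, "train": train}

    def backward(self, dy, cache):
        xhat, inv = cache["xhat"], cache["inv"]
        gamma = self.params["gamma"]
        self.grads["beta"] += dy.sum(axis=(1, 2, 3))
        self.grads["gamma"] += (dy * xhat).sum(axis=(1, 2, 3))
        if not cache["train"]:
            return gamma[:, None, None, None] * inv[:, None, None, None] * dy
        n = dy[0].size
        dxhat = gamma[:, None, None, None] * dy
        mean_d = dxhat.mean(axis=(1, 2, 3))
        mean_dx = (dxhat * xhat).mean(axis=(1, 2, 3))
        return inv[:, None, None, None] * (
            dxhat - mean_d[:, None, None, None] - xhat * mean_dx[:, None, None, None]
        )


class ConcatPool(Layer):
    """Concatenated in-plane average and maximum pooling (z preserved).

    ``factor`` mode halves the in-plane extent with non-overlapping 2×2
    windows (odd trailing rows/columns are dropped); ``adaptive`` mode pools
    to a fixed target with equal-as-possible contiguous bins.  Output has
    2× the input channels.
    """

    def __init__(self, mode: str = "factor", factor: int = 2, target: int = 16):
        super().__init__()
        if mode not in ("factor", "adaptive"):
            raise ValueError("mode must be 'factor' or 'adaptive'")
        self.mode = mode
        self.factor = factor
        self.target = target

    @staticmethod
    def bin_edges(n: int, target: int) -> np.ndarray:
        return np.linspace(0, n, target + 1).round().astype(int)

    def forward(self, x, train=True):
        C, X, Y, Z = x.shape
        if self.mode == "factor":
            f = self.factor
            if X < f or Y < f:
                raise ValueError("in-plane extent smaller than pooling factor")
            Xo, Yo = X // f, Y // f
            xv = x[:, : Xo * f, : Yo * f].reshape(C, Xo, f, Yo, f, Z)
            avg = xv.mean(axis=(2, 4))
            win = xv.transpose(0, 1, 3, 5, 2, 4).reshape(C, Xo, Yo, Z, f * f)
            arg = win.argmax(axis=-1)
            mx = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
            cache = {"shape": x.shape, "arg": arg}
        else:
            t = self.target
            if X < t or Y < t:
                raise ValueError(f"in-plane extent must be ≥ {t} for adaptive pooling")
            ex = self.bin_edges(X, t)
            ey = self.bin_edges(Y, t)
            avg = np.empty((C, t, t, Z), dtype=x.dtype)
            mx = np.empty((C, t, t, Z), dtype=x.dtype)
            arg = np.empty((C, t, t, Z), dtype=np.int64)
            for a in range(t):
                for b in range(t):
                    blk = x[:, ex[a] : ex[a + 1], ey[b] : ey[b + 1]]
                    flat = blk.reshape(C, -1, Z)
                    avg[:, a, b] = flat.mean(axis=1)
                    am = flat.argmax(axis=1)
                    arg[:, a, b] = am
                    mx[:, a, b] = np.take_along_axis(flat, am[:, None, :], axis=1)[:, 0]
            cache = {"shape": x.shape, "arg": arg, "ex": ex, "ey": ey}
        return np.concatenate([avg, mx], axis=0), cache

    def backward(self, dy, cache):
        C2 = dy.shape[0]
        C = C2 // 2
        davg, dmax = dy[:C], dy[C:]
        X, Y, Z = cache["shape"][1:]
        dx = np.zeros(cache["shape"], dtype=dy.dtype)
        if self.mode == "factor":
            f = self.factor
            Xo, Yo = X // f, Y // f
            # average branch: distribute equally
            dv = np.repeat(np.repeat(davg, f, axis=1), f, axis=2) / (f * f)
            dx[:, : Xo * f, : Yo * f] += dv
            # max branch: route to argmax
            arg = cache["arg"]  # (C,Xo,Yo,Z) in window coords
            ci, xi, yi, zi = np.indices(arg.shape)
            wx, wy = np.divmod(arg, f)
            dx[ci, xi * f + wx, yi * f + wy, zi] += dmax
        else:
            ex, ey, arg = cache["ex"], cache["ey"], cache["arg"]
            t = self.target
            for a in range(t):
                for b in range(t):
                    sx = slice(ex[a], ex[a + 1])
                    sy = slice(ey[b], ey[b + 1])
                    nb = (ex[a + 1] - ex[a]) * (ey[b + 1] - ey[b])
                    dx[:, sx, sy] += (davg[:, a, b] / nb)[:, None, None, :]
                    flat = dx[:, sx, sy].reshape(C, -1, Z)
                    contrib = np.zeros_like(flat)
                    np.put_along_axis(contrib, arg[:, a, b][:, None, :], dmax[:, a, b][:, None, :], axis=1)
                    dx[:, sx, sy] += contrib.reshape(dx[:, sx, sy].shape)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        return x * mask, {"mask": mask}

    def backward(self, dy, cache):
        return dy * cache["mask"]


class DRC(Layer):
    """Dynamic range constraint: T ↦ scale·sigmoid(T) + offset.

    With scale 2.0 and offset 1e-4 this maps the non-negative (rectified)
    domain onto [1.0001, 2.0001], strictly monotonically.
    """

    def __init__(self, scale: float = 2.0, offset: float = 1e-4):
        super().__init__()
        self.scale = scale
        self.offset = offset

    def forward(self, x, train=True):
        s = 1.0 / (1.0 + np.exp(-x))
        return self.scale * s + self.offset, {"s": s}

    def backward(self, dy, cache):
        s = cache["s"]
        return dy * self.scale * s * (1.0 - s)


class Log(Layer):
    def forward(self, x, train=True):
        return np.log(x), {"x": x}

    def backward(self, dy, cache):
        return dy / cache["x"]


class Exp(Layer):
    def forward(self, x, train=True):
        y = np.exp(x)
        return y, {"y": y}

    def backward(self, dy, cache):
        return dy * cache["y"]


class FixedGaussianInplane(Layer):
    """Immutable in-plane Gaussian blur (kernel k×k×1), zero padding.

    Implemented separably; zero padding commutes with separability, so the
    result equals convolution with the dense outer-product kernel.  The
    kernel is symmetric, so the adjoint equals the forward operator.
    """

    def __init__(self, sigma: float = 1.5, size: int = 9):
        super().__init__()
        self.k = gaussian_kernel_1d(sigma, size)

    def forward(self, x, train=True):
        y = _conv1d_axis(_conv1d_axis(x, self.k, axis=1), self.k, axis=2)
        return y, {}

    def backward(self, dy, cache):
        return _conv1d_axis(_conv1d_axis(dy, self.k, axis=1), self.k, axis=2)


class FixedHighpassZ(Layer):
    """Immutable through-plane high-pass: T ↦ T − g_z(T), g Gaussian 1×1×k."""

    def __init__(self, sigma: float = 1.0, size: int = 9):
        super().__init__()
        self.k = gaussian_kernel_1d(sigma, size)

    def forward(self, x, train=True):
        return x - _conv1d_axis(x, self.k, axis=3), {}

    def backward(self, dy, cache):
        return dy - _conv1d_axis(dy, self.k, axis=3)


class BilinearUpsample(Layer):
    """In-plane linear interpolation from the adaptive-bin grid to (nx, ny).

    Source sample positions are the centres of the adaptive pooling bins
    (mapped back through the factor-2 pooling to full-resolution
    coordinates); targets are voxel centres.  Outside the outermost bin
    centres the field is extended as constant.
    """

    def __init__(self, source: int = 16, pool_factor: int = 2):
        super().__init__()
        self.source = source
        self.pool_factor = pool_factor
        self._cache_mats: dict[int, np.ndarray] = {}

    def _matrix(self, n_full: int) -> np.ndarray:
        if n_full in self._cache_mats:
            return self._cache_mats[n_full]
        f = self.pool_factor
        n_half = n_full // f
        edges = ConcatPool.bin_edges(n_half, self.source)
        centres_half = (edges[:-1] + edges[1:] - 1) / 2.0
        centres_full = centres_half * f + (f - 1) / 2.0
        t = np.arange(n_full, dtype=float)
        W = np.zeros((n_full, self.source))
        idx = np.clip(np.searchsorted(centres_full, t) - 1, 0, self.source - 2)
        left = centres_full[idx]
        right = centres_full[idx + 1]
        w = np.clip((t - left) / (right - left), 0.0, 1.0)
        W[np.arange(n_full), idx] = 1.0 - w
        W[np.arange(n_full), idx + 1] += w
        self._cache_mats[n_full] = W
        return W

    def forward(self, x, train=True, out_shape=None):
        nx, ny = out_shape
        Wx = self._matrix(nx).astype(x.dtype, copy=False)
        Wy = self._matrix(ny).astype(x.dtype, copy=False)
        y = np.einsum("Ai,Bj,cijz->cABz", Wx, Wy, x, optimize=True)
        return y, {"Wx": Wx, "Wy": Wy, "in_shape": x.shape}

    def backward(self, dy, cache):
        return np.einsum("Ai,Bj,cABz->cijz", cache["Wx"], cache["Wy"], dy, optimize=True)
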