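"""The constrained destripe-field estimation network.

A small (18,109 trainable parameters) fully-convolutional network maps a
single normalised 3D volume S (nx, ny, nz) to a strictly positive
multiplicative field F on the same grid; S ⊙ F is the corrected volume.
Structural constraints are baked into the architecture: the field logits
are bounded by a sigmoid dynamic range constraint (DRC), and fixed Gaussian
filters in the log domain enforce in-plane smoothness and (during training)
through-plane high-pass behaviour.  In-plane resolution is reduced to a
16×16 grid and bilinearly upsampled, so the field is inherently smooth
in-plane while keeping native through-plane resolution.

Layer stack (channels, in-plane extent):

    input S                      1, nx, ny, nz
    1  SeparableConv 3×3×3      16                    60 params
    2  BatchNorm                                      32
    3  ConvBlock (z-dil 1,2,3)                      2128
    4  ConvBlock + ReLU                             2128
    5  ConcatPool 2×2×1         32, nx/2, ny/2, nz
    6  BatchNorm                                      64
    7  ConvBlock                                    5792
    8  ConvBlock + ReLU                             5792
    9  ConcatPool adaptive      64, 16, 16, nz
    10 1×1×1 conv               32                  2080
    11 1×1×1 conv + ReLU         1                    33
    12 DRC  T ↦ 2·sigmoid(T) + 1e-4   (range [1.0001, 2.0001])
    13 log
    14 fixed in-plane Gaussian low-pass (σ=1.5, 9×9×1)
    15 fixed through-plane high-pass (σ=1, 1×1×9) — training only
    16 exp
    17 bilinear in-plane upsample to (nx, ny)
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    DRC,
    BatchNorm,
    BilinearUpsample,
    ConcatPool,
    ConvBlock,
    Exp,
    FixedGaussianInplane,
    FixedHighpassZ,
    Log,
    PointwiseConv,
    SeparableConv,
)

__all__ = ["NetworkConfig", "DStripeNet", "count_parameters", "drc", "ParameterCount"]

MIN_INPLANE = 32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters; defaults reproduce the reference dStripe network."""

    channels_stage1: int = 16
    channels_stage2: int = 32
    target_inplane: int = 16
    drc_scale: float = 2.0
    drc_offset: float = 1e-4
    gauss_inplane_sigma: float = 1.5
    gauss_inplane_size: int = 9
    gauss_z_sigma: float = 1.0
    gauss_z_size: int = 9
    mode: str = "train"  # 'train' keeps the built-in z high-pass, 'infer' removes it

    def __post_init__(self):
        if self.mode not in ("train", "infer"):
            raise ValueError("mode must be 'train' or 'infer'")


def drc(T, scale: float = 2.0, offset: float = 1e-4):
    """Dynamic range constraint: T ↦ scale/(1+exp(−T)) + offset.

    On the rectified domain T ≥ 0 the output lies in
    [scale/2 + offset, scale + offset] = [1.0001, 2.0001] at defaults,
    strictly increasing in T.
    """
    return scale / (1.0 + np.exp(-np.asarray(T, dtype=float))) + offset


@dataclass(frozen=True)
class ParameterCount:
    """Per-layer trainable parameter accounting."""

    per_layer: tuple[tuple[str, int], ...]
    total: int


def count_parameters(cfg: NetworkConfig = NetworkConfig()) -> ParameterCount:
    """Trainable parameter count per layer and in total.

    Batch normalisation counts affine scale+shift only (running statistics
    are state, not parameters); the fixed Gaussian filter layers, DRC,
    log/exp and pooling/upsampling layers are parameter-free.
    """
    c1, c2 = cfg.channels_stage1, cfg.channels_stage2
    k = 27  # 3×3×3
    sep1 = (1 * k + 1) + (1 * c1 + c1)
    bn1 = 2 * c1
    cb1 = 3 * (c1 * k + c1) + (3 * c1 * c1 + c1)
    bn2 = 2 * c2
    cb2 = 3 * (c2 * k + c2) + (3 * c2 * c2 + c2)
    pw1 = 2 * c2 * c2 + c2
    pw2 = c2 * 1 + 1
    per_layer = (
        ("SeparableConv", sep1),
        ("BatchNorm", bn1),
        ("ConvBlock", cb1),
        ("ConvBlock+ReLU", cb1),
        ("BatchNorm", bn2),
        ("ConvBlock", cb2),
        ("ConvBlock+ReLU", cb2),
        ("SeparableConv(pointwise)", pw1),
        ("SeparableConv(pointwise)+ReLU", pw2),
    )
    return ParameterCount(per_layer=per_layer, total=sum(n for _, n in per_layer))


class DStripeNet:
    """The field-estimation network with explicit forward/backward passes."""

    def __init__(self, cfg: NetworkConfig = NetworkConfig(), seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c1, c2 = cfg.channels_stage1, cfg.channels_stage2
        self.sep1 = SeparableConv(1, c1, (3, 3, 3), rng=rng)
        self.bn1 = BatchNorm(c1)
        self.cb1 = ConvBlock(c1, with_relu=False, rng=rng)
        self.cb2 = ConvBlock(c1, with_relu=True, rng=rng)
        self.pool1 = ConcatPool(mode="factor", factor=2)
        self.bn2 = BatchNorm(c2)
        self.cb3 = ConvBlock(c2, with_relu=False, rng=rng)
        self.cb4 = ConvBlock(c2, with_relu=True, rng=rng)
        self.pool2 = ConcatPool(mode="adaptive", target=cfg.target_inplane)
        self.pw1 = PointwiseConv(2 * c2, c2, rng=rng)
        self.pw2 = PointwiseConv(c2, 1, rng=rng)
        self.drc = DRC(cfg.drc_scale, cfg.drc_offset)
        self.log = Log()
        self.gauss2d = FixedGaussianInplane(cfg.gauss_inplane_sigma, cfg.gauss_inplane_size)
        self.hpz = FixedHighpassZ(cfg.gauss_z_sigma, cfg.gauss_z_size)
        self.exp = Exp()
        self.upsample = BilinearUpsample(cfg.target_inplane, pool_factor=2)
        self._to_dtype(dtype)

    # -- parameter plumbing ------------------------------------------------
    def _trainable_layers(self):
        return [
            ("sep1.dw", self.sep1.depthwise),
            ("sep1.pw", self.sep1.pointwise),
            ("bn1", self.bn1),
            ("cb1.d1", self.cb1.branches[0]),
            ("cb1.d2", self.cb1.branches[1]),
            ("cb1.d3", self.cb1.branches[2]),
            ("cb1.pw", self.cb1.pointwise),
            ("cb2.d1", self.cb2.branches[0]),
            ("cb2.d2", self.cb2.branches[1]),
            ("cb2.d3", self.cb2.branches[2]),
            ("cb2.pw", self.cb2.pointwise),
            ("bn2", self.bn2),
            ("cb3.d1", self.cb3.branches[0]),
            ("cb3.d2", self.cb3.branches[1]),
            ("cb3.d3", self.cb3.branches[2]),
            ("cb3.pw", self.cb3.pointwise),
            ("cb4.d1", self.cb4.branches[0]),
            ("cb4.d2", self.cb4.branches[1]),
            ("cb4.d3", self.cb4.branches[2]),
            ("cb4.pw", self.cb4.pointwise),
            ("pw1", self.pw1),
            ("pw2", self.pw2),
        ]

    def _to_dtype(self, dtype):
        for _, layer in self._trainable_layers():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(dtype)
                layer.grads[k] = layer.grads[k].astype(dtype)
        for bn in (self.bn1, self.bn2):
            bn.running_mean = bn.running_mean.astype(dtype)
            bn.running_var = bn.running_var.astype(dtype)

    def parameters(self):
        """Flat view of all trainable arrays as (name, param, grad) triples."""
        out = []
        for lname, layer in self._trainable_layers():
            for pname in layer.params:
                out.append((f"{lname}.{pname}", layer.params[pname], layer.grads[pname]))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def zero_grad(self):
        for _, layer in self._trainable_layers():
            layer.zero_grad()

    # -- forward / backward ------------------------------------------------
    def forward(self, S: np.ndarray, train: bool | None = None, return_cache: bool = False):
        """Estimate the multiplicative field F for a single volume S.

        Returns F of shape ``S.shape`` (and the backward cache when
        ``return_cache``).  ``train=None`` follows ``cfg.mode``.
        """
        if train is None:
            train = self.cfg.mode == "train"
        S = np.asarray(S)
        if S.ndim != 3:
            raise ValueError("input must be a single 3D volume")
        nx, ny, nz = S.shape
        if nx < MIN_INPLANE or ny < MIN_INPLANE:
            raise ValueError(f"in-plane extent must be ≥ {MIN_INPLANE}, got {nx}×{ny}")
        x = S.astype(self.dtype)[None]
        cache = {}
        x, cache["sep1"] = self.sep1.forward(x, train)
        x, cache["bn1"] = self.bn1.forward(x, train)
        x, cache["cb1"] = self.cb1.forward(x, train)
        x, cache["cb2"] = self.cb2.forward(x, train)
        x, cache["pool1"] = self.pool1.forward(x, train)
        x, cache["bn2"] = self.bn2.forward(x, train)
        x, cache["cb3"] = self.cb3.forward(x, train)
        x, cache["cb4"] = self.cb4.forward(x, train)
        x, cache["pool2"] = self.pool2.forward(x, train)
        x, cache["pw1"] = self.pw1.forward(x, train)
        x, cache["pw2"] = self.pw2.forward(x, train)
        relu_mask = x > 0
        x = x * relu_mask
        cache["relu11"] = relu_mask
        x, cache["drc"] = self.drc.forward(x, train)
        x, cache["log"] = self.log.forward(x, train)
        x, cache["gauss2d"] = self.gauss2d.forward(x, train)
        if train:
            x, cache["hpz"] = self.hpz.forward(x, train)
        x, cache["exp"] = self.exp.forward(x, train)
        x, cache["up"] = self.upsample.forward(x, train, out_shape=(nx, ny))
        cache["train"] = train
        F = x[0]
        if return_cache:
            return F, cache
        return F

    def backward(self, dF: np.ndarray, cache) -> None:
        """Accumulate parameter gradients for one forward pass."""
        dy = dF[None].astype(self.dtype)
        dy = self.upsample.backward(dy, cache["up"])
        dy = self.exp.backward(dy, cache["exp"])
        if cache["train"]:
            dy = self.hpz.backward(dy, cache["hpz"])
        dy = self.gauss2d.backward(dy, cache["gauss2d"])
        dy = self.log.backward(dy, cache["log"])
        dy = self.drc.backward(dy, cache["drc"])
        dy = dy * cache["relu11"]
        dy = self.pw2.backward(dy, cache["pw2"])
        dy = self.pw1.backward(dy, cache["pw1"])
        dy = self.pool2.backward(dy, cache["pool2"])
        dy = self.cb4.backward(dy, cache["cb4"])
        dy = self.cb3.backward(dy, cache["cb3"])
        dy = self.bn2.backward(dy, cache["bn2"])
        dy = self.pool1.backward(dy, cache["pool1"])
        dy = self.cb2.backward(dy, cache["cb2"])
        dy = self.cb1.backward(dy, cache["cb1"])
        dy = self.bn1.backward(dy, cache["bn1"])
        self.sep1.backward(dy, cache["sep1"])

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p for name, p, _ in self.parameters()}
        for bname, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            state[f"{bname}.running_mean"] = bn.running_mean
            state[f"{bname}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            p[...] = state[name]
        for bname, bn in (("bn1", self.bn1), ("bn2", self.bn2)):
            bn.running_mean = np.asarray(state[f"{bname}.running_mean"], dtype=self.dtype)
            bn.running_var = np.asarray(state[f"{bname}.running_var"], dtype=self.dtype)

    def save(self, path) -> None:
        """Write a checkpoint: zip archive of config.json + params npz."""
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.cfg), indent=1))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path, mode: str | None = None) -> "DStripeNet":
        with zipfile.ZipFile(path, "r") as zf:
            cfg_d = json.loads(zf.read("config.json"))
            if mode is not None:
                cfg_d["mode"] = mode
            cfg = NetworkConfig(**cfg_d)
            with zf.open("params.npz") as f:
                state = dict(np.load(io.BytesIO(f.read())))
        net = cls(cfg)
        net.load_state_dict(state)
        return net
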