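"""Inference pipeline: iterative field estimation with spectral constraints.

At inference the network's built-in through-plane high-pass is removed and
replaced with an FFT-based filter h_z applied to the *composed* field, so
repeated updates cannot drift out of the admissible frequency band:

    F₀ ≡ 1,   F_{i+1} ← h_z(F_i ⊙ f(S_o ⊙ F_i))

where f is the raw field output of the network.  h_z blends low and
mid/high frequency content with a mask-derived attention map A (to stop
unreliable field estimates outside the brain from leaking in) and divides
by a through-plane Butterworth low-pass component:

    step 1:  F ← exp(log(F / F_lp3d) ⊙ A) ⊙ F_lp3d
    step 2:  F ← F / fft_z⁻¹(fft_z(F) ⊙ b1)

Finally the field is low-pass filtered in-plane (log domain) to suppress
bilinear-upsampling artefacts.  Frequencies are normalised to Nyquist = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dwi_io import BrainMask, DWIDataset
from .network import DStripeNet

__all__ = [
    "ButterworthSpec",
    "InferenceConfig",
    "AttentionMap",
    "butterworth_gain",
    "lowpass_axis",
    "lowpass_z",
    "build_attention",
    "hz",
    "iterate_field",
    "final_lowpass_inplane",
    "destripe_dataset",
]


@dataclass(frozen=True)
class ButterworthSpec:
    """Zero-phase Butterworth magnitude response, Nyquist-normalised."""

    order: int
    cutoff: float  # normalised frequency, Nyquist = 1
    padding: int  # per-side edge-replication pad (voxels)

    def __post_init__(self):
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must be in (0, 1]")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")


@dataclass(frozen=True)
class InferenceConfig:
    """Iterative destriping configuration (reference dStripe defaults)."""

    iterations: int = 3
    b1: ButterworthSpec = field(default_factory=lambda: ButterworthSpec(4, 21 / 32, 17))
    final_inplane: ButterworthSpec = field(default_factory=lambda: ButterworthSpec(3, 2 / 32, 24))
    lp3d_sigma: tuple[float, float, float] = (5.0, 5.0, 11.0)
    attention_dilations: int = 13
    attention_sigma_inplane: float = 9.0
    attention_sigma_z: float = 3.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class AttentionMap:
    """Spatial weights in [0, 1] gating high-frequency field content."""

    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.min() < 0 or A.max() > 1:
            raise ValueError("attention values must lie in [0, 1]")
        self.A = A


def butterworth_gain(f, order: int, cutoff: float) -> np.ndarray:
    """Low-pass magnitude gain (1 + (f/fc)^{2n})^{-1/2}; real and even."""
    f = np.abs(np.asarray(f, dtype=float))
    return 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))


def lowpass_axis(x: np.ndarray, spec: ButterworthSpec, axis: int) -> np.ndarray:
    """Zero-phase Butterworth low-pass along one axis.

    Edge-replication padding (``spec.padding`` per side) suppresses wrap-
    around; the DC gain is exactly 1, so constants pass unchanged.
    """
    n = x.shape[axis]
    p = spec.padding
    if p > 0:
        pad = [(0, 0)] * x.ndim
        pad[axis] = (p, p)
        xp = np.pad(x, pad, mode="edge")
    else:
        xp = x
    m = xp.shape[axis]
    freqs = np.fft.rfftfreq(m) * 2.0  # Nyquist-normalised
    gain = butterworth_gain(freqs, spec.order, spec.cutoff)
    shape = [1] * x.ndim
    shape[axis] = len(gain)
    y = np.fft.irfft(np.fft.rfft(xp, axis=axis) * gain.reshape(shape), n=m, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(p, p + n)
    return y[tuple(sl)]


def lowpass_z(F: np.ndarray, spec: ButterworthSpec) -> np.ndarray:
    """Through-plane (z) Butterworth low-pass of a field."""
    return lowpass_axis(F, spec, axis=2)


def build_attention(mask: BrainMask, cfg: InferenceConfig = InferenceConfig()) -> AttentionMap:
    """Mask-derived attention: in-plane dilation + blur, then z smoothing.

    The binary mask is dilated in-plane (``attention_dilations`` iterations,
    4-connectivity), blurred in-plane with a Gaussian (σ=9 voxels) and then
    smoothed through-plane (σ=3 voxels); values are clipped to [0, 1].
    """
    m = mask.mask
    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[1, :, 0] = True
    structure[:, 1, 0] = True
    dil = ndimage.binary_dilation(m, structure=structure, iterations=cfg.attention_dilations)
    A = dil.astype(float)
    A = ndimage.gaussian_filter(A, sigma=(cfg.attention_sigma_inplane, cfg.attention_sigma_inplane, 0.0))
    A = ndimage.gaussian_filter(A, sigma=(0.0, 0.0, cfg.attention_sigma_z))
    return AttentionMap(A=np.clip(A, 0.0, 1.0))


def hz(F: np.ndarray, A: np.ndarray | AttentionMap, cfg: InferenceConfig = InferenceConfig()) -> np.ndarray:
    """Attention-gated through-plane high-pass of a positive field.

    Step 1 rescales the field's mid/high-frequency log-content by A around
    the 3D Gaussian background F_lp3d; step 2 divides by the through-plane
    Butterworth low-pass component.  h_z(1) = 1 exactly, and any z-constant
    positive field maps to 1 when A ≡ 1.
    """
    if np.any(F <= 0):
        raise ValueError("field must be strictly positive")
    if isinstance(A, AttentionMap):
        A = A.A
    lp3d = np.exp(ndimage.gaussian_filter(np.log(F), sigma=cfg.lp3d_sigma, mode="nearest"))
    F1 = np.exp(np.log(F / lp3d) * A) * lp3d
    return F1 / lowpass_z(F1, cfg.b1)


def final_lowpass_inplane(F: np.ndarray, cfg: InferenceConfig = InferenceConfig()) -> np.ndarray:
    """In-plane log-domain Butterworth low-pass to remove upsampling artefacts."""
    if np.any(F <= 0):
        raise ValueError("field must be strictly positive")
    logF = np.log(F)
    logF = lowpass_axis(logF, cfg.final_inplane, axis=0)
    logF = lowpass_axis(logF, cfg.final_inplane, axis=1)
    return np.exp(logF)


def iterate_field(
    S: np.ndarray,
    mask: BrainMask,
    net: DStripeNet,
    cfg: InferenceConfig = InferenceConfig(),
    attention: AttentionMap | None = None,
) -> np.ndarray:
    """Iteratively estimate the destripe field for one normalised volume.

    The network runs in inference mode (built-in z high-pass disabled); each
    update composes the previous field with the network's response to the
    current best corrected image and re-applies the h_z constraint.  The
    final in-plane low-pass is applied once after the last iteration.
    """
    if attention is None:
        attention = build_attention(mask, cfg)
    F = np.ones_like(S, dtype=float)
    for _ in range(cfg.iterations):
        upd = net.forward(S * F, train=False)
        F = hz(F * upd.astype(float), attention, cfg)
    return final_lowpass_inplane(F, cfg)


def destripe_dataset(
    dataset: DWIDataset,
    mask: BrainMask,
    net: DStripeNet,
    cfg: InferenceConfig = InferenceConfig(),
    percentile: float = 0.99,
) -> tuple[DWIDataset, np.ndarray]:
    """Destripe every volume of a dataset; returns (corrected, fields).

    Each volume is percentile-normalised before entering the network and the
    normalisation is inverted afterwards (the multiplicative field itself is
    scale-free).  ``fields`` has shape (nx, ny, nz, nvol) and the corrected
    signal equals ``signal * fields`` exactly.
    """
    if mask.mask.shape != dataset.spatial_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match data grid {dataset.spatial_shape}"
        )
    attention = build_attention(mask, cfg)
    fields = np.empty_like(dataset.signal)
    for v in range(dataset.nvol):
        vol = dataset.signal[..., v]
        scale = np.quantile(vol, percentile)
        if scale <= 0:
            fields[..., v] = 1.0
            continue
        fields[..., v] = iterate_field(vol / scale, mask, net, cfg, attention)
    out = replace(dataset, signal=dataset.signal * fields)
    return out, fields
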