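"""Stripe simulation, dihedral augmentation and synthetic multi-shell phantoms.

The stripe model: slices are excited in ``interleave`` temporally contiguous
blocks (slice i belongs to block i mod interleave).  Each block τ gets a
fixed centre μτ ~ U(centre_low, centre_high); each slice draws
mᵢ ~ N(μτ, στ²) and is squared to guarantee non-negativity.  The modulation
vector is finally normalised to unit geometric mean so global intensity
scaling is approximately preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dwi_io import BrainMask, DWIDataset, GradientTable

__all__ = [
    "ModulationConfig",
    "SliceModulation",
    "DihedralElement",
    "PhantomConfig",
    "PhantomResult",
    "sample_modulation",
    "normalize_gm",
    "apply_modulation",
    "sample_dihedral",
    "apply_dihedral",
    "invert_dihedral",
    "all_dihedral_elements",
    "make_phantom",
]


@dataclass(frozen=True)
class ModulationConfig:
    """Parameters of the interleave-correlated slice modulation distribution."""

    interleave: int = 3
    block_variance: float = 0.05  # στ²
    centre_low: float = 0.9
    centre_high: float = 1.1

    def __post_init__(self):
        if self.interleave < 1:
            raise ValueError("interleave must be ≥ 1")
        if self.block_variance <= 0:
            raise ValueError("block_variance must be positive")
        if not self.centre_low < self.centre_high:
            raise ValueError("centre bounds must be ordered")


@dataclass(frozen=True)
class SliceModulation:
    """Per-slice positive multiplicative factors with unit geometric mean."""

    m: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.m, dtype=float).ravel()
        if np.any(m <= 0):
            raise ValueError("slice modulation factors must be strictly positive")
        object.__setattr__(self, "m", m)

    def __len__(self) -> int:
        return len(self.m)


def normalize_gm(m) -> SliceModulation:
    """Scale a positive vector to unit geometric mean."""
    m = np.asarray(m, dtype=float).ravel()
    if np.any(m <= 0):
        raise ValueError("entries must be strictly positive")
    gm = np.exp(np.mean(np.log(m)))
    return SliceModulation(m=m / gm)


def sample_modulation(
    nz: int, cfg: ModulationConfig = ModulationConfig(), rng: np.random.Generator | None = None
) -> SliceModulation:
    """Draw one interleave-correlated slice modulation vector of length ``nz``.

    Each block τ (slices i with i mod interleave == τ) shares a centre
    μτ ~ U(centre_low, centre_high); slice factors are N(μτ, στ²) draws,
    squared, then normalised to unit geometric mean.
    """
    if rng is None:
        rng = np.random.default_rng()
    if nz < cfg.interleave:
        raise ValueError("need at least `interleave` slices")
    sigma = np.sqrt(cfg.block_variance)
    mu = rng.uniform(cfg.centre_low, cfg.centre_high, size=cfg.interleave)
    m = np.empty(nz, dtype=float)
    idx = np.arange(nz)
    for tau in range(cfg.interleave):
        sel = idx % cfg.interleave == tau
        m[sel] = rng.normal(mu[tau], sigma, size=int(sel.sum()))
    m = m**2
    # exact zeros have probability zero; re-draw defensively
    while np.any(m == 0.0):
        zero = m == 0.0
        m[zero] = rng.normal(1.0, sigma, size=int(zero.sum())) ** 2
    return normalize_gm(m)


def apply_modulation(volume: np.ndarray, m: SliceModulation | np.ndarray, axis: int = 2) -> np.ndarray:
    """Multiply each slice of ``volume`` along ``axis`` by its factor mₛ."""
    factors = m.m if isinstance(m, SliceModulation) else np.asarray(m, dtype=float).ravel()
    volume = np.asarray(volume)
    if volume.shape[axis] != len(factors):
        raise ValueError(
            f"modulation length {len(factors)} does not match volume extent "
            f"{volume.shape[axis]} along axis {axis}"
        )
    shape = [1, 1, 1]
    shape[axis] = len(factors)
    return volume * factors.reshape(shape)


@dataclass(frozen=True)
class DihedralElement:
    """An axis-aligned isometry of the voxel grid: permute axes, then flip.

    ``apply`` computes ``y = flip(transpose(x, axis_permutation), flips)``.
    The 48 such elements form the full symmetry group of the cube.
    """

    axis_permutation: tuple[int, int, int]
    flips: tuple[bool, bool, bool]

    def __post_init__(self):
        if sorted(self.axis_permutation) != [0, 1, 2]:
            raise ValueError("axis_permutation must be a permutation of (0,1,2)")

    @property
    def slice_axis_origin(self) -> int:
        """Which input axis ends up as the output z (network slice) axis."""
        return self.axis_permutation[2]


def apply_dihedral(volume: np.ndarray, d: DihedralElement) -> np.ndarray:
    out = np.transpose(volume, d.axis_permutation)
    flip_axes = [a for a, f in enumerate(d.flips) if f]
    if flip_axes:
        out = np.flip(out, axis=flip_axes)
    return out


def invert_dihedral(d: DihedralElement) -> DihedralElement:
    perm = d.axis_permutation
    inv = tuple(int(np.argsort(perm)[i]) for i in range(3))
    # flips of the inverse live in the pre-transpose frame: axis a of the
    # inverse transpose reads original axis inv[a]
    inv_flips = tuple(bool(d.flips[inv[a]]) for a in range(3))
    return DihedralElement(axis_permutation=inv, flips=inv_flips)


def all_dihedral_elements() -> list[DihedralElement]:
    """Enumerate all 48 axis-aligned isometries."""
    return [
        DihedralElement(axis_permutation=p, flips=f)
        for p in itertools.permutations((0, 1, 2))
        for f in itertools.product((False, True), repeat=3)
    ]


def sample_dihedral(rng: np.random.Generator, slice_axis_origin: int | None = None) -> DihedralElement:
    """Sample a dihedral element, stratified over the resulting slice axis.

    The original axis mapped onto the network slice axis (output z) is
    uniform over {0,1,2} unless pinned with ``slice_axis_origin``; the
    remaining in-plane arrangement and all flips are uniform.
    """
    if slice_axis_origin is None:
        slice_axis_origin = int(rng.integers(3))
    rest = [a for a in range(3) if a != slice_axis_origin]
    if rng.integers(2):
        rest = rest[::-1]
    perm = (rest[0], rest[1], slice_axis_origin)
    flips = tuple(bool(rng.integers(2)) for _ in range(3))
    return DihedralElement(axis_permutation=perm, flips=flips)


@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic multi-shell phantom: smooth blobby anatomy in an ellipsoid.

    Emulates the qualitative structure of neonatal multi-shell dMRI at desk
    scale: piecewise-smooth positive anatomy, shell-dependent mean signal
    attenuation, optional low-order angular modulation of the diffusion-
    weighted signal, and additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    shell_b: tuple[float, ...] = (0.0, 1000.0, 2600.0)
    shell_attenuation: tuple[float, ...] = (1.0, 0.35, 0.15)
    volumes_per_shell: tuple[int, ...] = (2, 4, 4)
    n_blobs: int = 20
    blob_smoothness: float = 3.0  # voxels, Gaussian σ of the anatomy texture
    noise_sd: float = 0.01  # additive noise, units of the b=0 plateau
    angular_order: int = 2  # 0 disables direction dependence
    angular_amplitude: float = 0.1  # relative amplitude of angular modulation
    modulation: ModulationConfig = field(default_factory=ModulationConfig)
    modulate: bool = True

    def __post_init__(self):
        if self.shape[0] < 16 or self.shape[1] < 16 or self.shape[2] < 9:
            raise ValueError("phantom grid must be at least 16×16 in-plane and 9 slices")
        if not all(0 < a <= 1 for a in self.shell_attenuation):
            raise ValueError("shell attenuations must be in (0, 1]")
        if not (len(self.shell_b) == len(self.shell_attenuation) == len(self.volumes_per_shell)):
            raise ValueError("shell parameter lengths must agree")


@dataclass
class PhantomResult:
    """Phantom generation output: modulated data, clean reference and truth."""

    dataset: DWIDataset  # stripe-modulated (or clean if cfg.modulate=False)
    clean: DWIDataset  # identical anatomy + noise, no slice modulation
    mask: BrainMask
    modulations: list[SliceModulation]  # applied per volume, along z


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximately uniform antipodally-spread unit directions."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i + rng.uniform(0, 2 * np.pi)
    cos_t = 1 - 2 * i / n
    sin_t = np.sqrt(np.clip(1 - cos_t**2, 0, 1))
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def make_phantom(cfg: PhantomConfig = PhantomConfig(), rng: np.random.Generator | None = None) -> PhantomResult:
    """Generate a synthetic multi-shell dMRI phantom with known stripe truth.

    Within a shell, volumes share the anatomy scaled by the shell
    attenuation, optionally modulated by a smooth even-order angular profile
    of the gradient direction, plus independent noise.  If ``cfg.modulate``,
    each volume is corrupted along z by an independently drawn interleave-
    correlated slice modulation (the returned ground truth).
    """
    if rng is None:
        rng = np.random.default_rng()
    nx, ny, nz = cfg.shape

    # anatomy: positive blobby texture, clipped to an ellipsoidal support
    blobs = np.zeros(cfg.shape)
    for _ in range(cfg.n_blobs):
        pos = rng.uniform(0.2, 0.8, size=3) * np.array(cfg.shape)
        amp = rng.uniform(0.5, 1.5)
        width = rng.uniform(1.5, 4.0)
        gx = np.exp(-0.5 * ((np.arange(nx) - pos[0]) / width) ** 2)
        gy = np.exp(-0.5 * ((np.arange(ny) - pos[1]) / width) ** 2)
        gz = np.exp(-0.5 * ((np.arange(nz) - pos[2]) / width) ** 2)
        blobs += amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    anatomy = ndimage.gaussian_filter(blobs, cfg.blob_smoothness)
    anatomy = 0.3 + anatomy / max(anatomy.max(), 1e-12)  # positive, O(1)

    xx, yy, zz = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) / (0.42 * nx),
        (np.arange(ny) - (ny - 1) / 2) / (0.42 * ny),
        (np.arange(nz) - (nz - 1) / 2) / (0.45 * nz),
        indexing="ij",
    )
    ellipsoid = xx**2 + yy**2 + zz**2 <= 1.0
    anatomy = anatomy * ellipsoid

    bvals, dirs, shells = [], [], []
    for s, (b, nv) in enumerate(zip(cfg.shell_b, cfg.volumes_per_shell)):
        if b == 0:
            bvals += [0.0] * nv
            dirs += [np.zeros(3)] * nv
        else:
            bvals += [b] * nv
            dirs += list(_fibonacci_directions(nv, rng))
        shells += [s] * nv
    bvals = np.asarray(bvals)
    dirs = np.asarray(dirs)

    nvol = len(bvals)
    # fixed per-dataset anisotropy axis for the angular profile
    u_axis = _fibonacci_directions(1, rng)[0]
    clean = np.empty(cfg.shape + (nvol,))
    for v in range(nvol):
        s = shells[v]
        att = cfg.shell_attenuation[s]
        vol = anatomy * att
        if cfg.angular_order > 0 and bvals[v] > 0:
            # smooth even angular profile: 1 + a·((g·u)² − 1/3)
            proj = float(np.dot(dirs[v], u_axis)) ** 2 - 1.0 / 3.0
            vol = vol * (1.0 + cfg.angular_amplitude * proj)
        clean[..., v] = vol
    clean += rng.normal(0.0, cfg.noise_sd, size=clean.shape) * ellipsoid[..., None]
    clean = np.clip(clean, 0.0, None)

    modulations: list[SliceModulation] = []
    signal = clean.copy()
    for v in range(nvol):
        mod = sample_modulation(nz, cfg.modulation, rng)
        modulations.append(mod)
        if cfg.modulate:
            signal[..., v] = apply_modulation(clean[..., v], mod, axis=2)

    grad = GradientTable(bvals=bvals, dirs=dirs)
    ds = DWIDataset(signal=signal, gradients=grad)
    ds_clean = DWIDataset(signal=clean, gradients=grad)
    return PhantomResult(
        dataset=ds, clean=ds_clean, mask=BrainMask(mask=ellipsoid), modulations=modulations
    )
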