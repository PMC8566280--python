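"""Stripiness metrics and field degrees-of-freedom reductions.

Through-plane intensity inconsistency is quantified with (i) the local
standard deviation of the signal (or of spherical-harmonics coefficient
volumes) in 1D patches of 7 voxels along each axis, (ii) the ℓ2-norm of
the real symmetric spherical-harmonics coefficients per harmonic band
(proportional to the root power spectral density of the angular signal),
and (iii) root-mean-square residuals of a log-linear diffusion tensor fit.
Field rank reductions: shell-wise voxelwise geometric means over the
angular domain (F_{b,x,y,z}) and additionally within slices (F_{b,z}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .dwi_io import BrainMask, DWIDataset, ShellIndex

__all__ = [
    "SHBasis",
    "sh_design_matrix",
    "sh_fit",
    "band_norm",
    "local_sd",
    "DTFitResult",
    "dti_fit",
    "field_geomean_angular",
    "field_geomean_slice",
]


# -- spherical harmonics ----------------------------------------------------


def _lm_pairs(lmax: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def sh_design_matrix(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Real symmetric (even-ℓ) orthonormal SH basis sampled at unit dirs.

    Row i holds all (ℓ, m) basis values at direction i, ℓ = 0, 2, …, lmax,
    m = −ℓ…ℓ; (lmax+1)(lmax+2)/2 columns.  The real basis is built from the
    complex orthonormal harmonics: m=0 → Y_ℓ⁰; m>0 → √2·(−1)^m·Re(Y_ℓ^m);
    m<0 → √2·(−1)^m·Im(Y_ℓ^{|m|}).
    """
    if lmax % 2 != 0:
        raise ValueError("lmax must be even")
    dirs = np.asarray(dirs, dtype=float)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    cols = []
    for l, m in _lm_pairs(lmax):
        am = abs(m)
        Y = sph_harm_y(l, am, theta, phi)
        if m == 0:
            cols.append(Y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** am * Y.imag)
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class SHBasis:
    """Design matrix of the real symmetric SH basis for a direction set."""

    lmax: int
    dirs: np.ndarray
    B: np.ndarray  # (ndir, ncoef)

    @classmethod
    def build(cls, dirs: np.ndarray, lmax: int) -> "SHBasis":
        return cls(lmax=lmax, dirs=np.asarray(dirs, float), B=sh_design_matrix(dirs, lmax))

    @property
    def n_coef(self) -> int:
        return self.B.shape[1]

    def band_slices(self) -> dict[int, slice]:
        out = {}
        start = 0
        for l in range(0, self.lmax + 1, 2):
            out[l] = slice(start, start + 2 * l + 1)
            start += 2 * l + 1
        return out


def sh_fit(signal: np.ndarray, dirs: np.ndarray, lmax: int, cond_limit: float = 1e6) -> np.ndarray:
    """Least-squares SH coefficients per voxel.

    ``signal`` is (..., ndir); returns (..., ncoef).  Raises if the design
    is rank-deficient (condition number above ``cond_limit``).
    """
    basis = sh_design_matrix(dirs, lmax)
    if basis.shape[0] < basis.shape[1]:
        raise ValueError(
            f"need ≥ {basis.shape[1]} directions for lmax={lmax}, got {basis.shape[0]}"
        )
    cond = np.linalg.cond(basis)
    if cond > cond_limit:
        raise ValueError(f"rank-deficient SH design matrix (condition number {cond:.3g})")
    pinv = np.linalg.pinv(basis)
    return np.einsum("cn,...n->...c", pinv, signal)


def band_norm(coefs: np.ndarray, l: int, lmax: int | None = None) -> np.ndarray:
    """ℓ2-norm of the band-ℓ coefficients per voxel: √(Σ_m c_ℓm²)."""
    if l % 2 != 0:
        raise ValueError("harmonic band ℓ must be even (symmetric signal)")
    ncoef = coefs.shape[-1]
    if lmax is None:
        # infer lmax from coefficient count (lmax+1)(lmax+2)/2
        lmax = int(round((np.sqrt(8 * ncoef + 1) - 3) / 2))
    if l > lmax:
        raise ValueError(f"band {l} exceeds lmax={lmax}")
    start = sum(2 * j + 1 for j in range(0, l, 2))
    sl = slice(start, start + 2 * l + 1)
    return np.sqrt(np.sum(coefs[..., sl] ** 2, axis=-1))


# -- local standard deviation ----------------------------------------------


def local_sd(volume: np.ndarray, axis: int, patch: int = 7, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel SD of a centred 1D window along ``axis`` (population SD).

    Boundary voxels use truncated windows.  When a mask is given the result
    is zeroed outside it (window contents are not mask-restricted).
    """
    if patch % 2 == 0:
        raise ValueError("patch length must be odd")
    if volume.shape[axis] < patch:
        raise ValueError("volume extent smaller than patch")
    # centre globally first: the SD is shift-invariant and the moment
    # formula cancels catastrophically on near-constant data otherwise
    volume = volume - volume.mean()
    ones = np.ones(volume.shape[axis])
    kernel = np.ones(patch)
    count = ndimage.correlate1d(ones, kernel, mode="constant", cval=0.0)
    shape = [1] * volume.ndim
    shape[axis] = volume.shape[axis]
    count = count.reshape(shape)
    s1 = ndimage.correlate1d(volume, kernel, axis=axis, mode="constant", cval=0.0)
    s2 = ndimage.correlate1d(volume**2, kernel, axis=axis, mode="constant", cval=0.0)
    mean = s1 / count
    var = np.clip(s2 / count - mean**2, 0.0, None)
    sd = np.sqrt(var)
    if mask is not None:
        sd = sd * mask
    return sd


# -- diffusion tensor fit ---------------------------------------------------


@dataclass
class DTFitResult:
    """Log-linear DT fit: per-voxel tensor, log-S0, derived maps, residuals."""

    tensor: np.ndarray  # (..., 3, 3) mm²/s, symmetric
    log_s0: np.ndarray  # (...,)
    md: np.ndarray  # mean diffusivity
    fa: np.ndarray  # fractional anisotropy
    shell_rms_residual: np.ndarray  # (nshell,) signal units
    usable: np.ndarray  # (...,) bool — voxels with ≥7 usable measurements


def _dt_design(bvals: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    g = dirs
    return np.stack(
        [
            np.ones_like(bvals),
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def dti_fit(dataset: DWIDataset, mask: BrainMask, shells: ShellIndex | None = None) -> DTFitResult:
    """Ordinary least-squares DT fit in the log domain, with residuals.

    log S = log S0 − b gᵀ D g is solved per masked voxel; non-positive
    signals are excluded measurement-wise and voxels with fewer than 7
    usable measurements are dropped.  Residuals are reported per shell as
    RMS of (S − Ŝ) over masked, usable voxels, in signal units.
    """
    bvals = dataset.gradients.bvals
    dirs = dataset.gradients.dirs
    dw = bvals > 0
    if dw.sum() < 6 or len(bvals) < 7:
        raise ValueError("need ≥7 volumes spanning ≥6 diffusion-weighted directions")
    X = _dt_design(bvals, dirs)  # (nmeas, 7)

    m = mask.mask
    S = dataset.signal[m]  # (nvox, nmeas)
    w = (S > 0).astype(float)
    logS = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), 0.0)
    usable = w.sum(axis=1) >= 7

    XtWX = np.einsum("vn,ni,nj->vij", w, X, X, optimize=True)
    XtWy = np.einsum("vn,ni,vn->vi", w, X, logS, optimize=True)
    beta = np.zeros((S.shape[0], 7))
    if usable.any():
        beta[usable] = np.linalg.solve(XtWX[usable], XtWy[usable][..., None])[..., 0]

    nvox_grid = dataset.spatial_shape
    full = lambda flat, fill=0.0: _scatter(flat, m, nvox_grid, fill)

    log_s0 = beta[:, 0]
    D = np.zeros((S.shape[0], 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]

    evals = np.linalg.eigvalsh(D)
    md = evals.mean(axis=1)
    num = np.sqrt(((evals - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((evals**2).sum(axis=1))
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)

    pred = np.exp(np.einsum("vi,ni->vn", beta, X, optimize=True))
    resid = (S - pred) * w * usable[:, None]
    if shells is None:
        from .dwi_io import group_shells

        shells = group_shells(dataset.gradients)
    shell_rms = np.zeros(shells.n_shells)
    for s in range(shells.n_shells):
        vols = shells.volumes_in_shell(s)
        r = resid[usable][:, vols]
        cnt = (w[usable][:, vols] > 0).sum()
        shell_rms[s] = np.sqrt((r**2).sum() / max(cnt, 1))

    tensor_grid = np.zeros(nvox_grid + (3, 3))
    tensor_grid[m] = D
    return DTFitResult(
        tensor=tensor_grid,
        log_s0=full(log_s0),
        md=full(md),
        fa=full(fa),
        shell_rms_residual=shell_rms,
        usable=_scatter(usable, m, nvox_grid, False),
    )


def _scatter(flat, mask, shape, fill):
    out = np.full(shape, fill, dtype=np.asarray(flat).dtype)
    out[mask] = flat
    return out


# -- field rank reductions --------------------------------------------------


def field_geomean_angular(
    fields: np.ndarray, shells: ShellIndex, mask: BrainMask | None = None
) -> np.ndarray:
    """Per-shell voxelwise geometric mean of per-volume fields: F_{b,x,y,z}.

    ``fields`` is (nx, ny, nz, nvol), strictly positive; the result is
    (nx, ny, nz, nshell).
    """
    if np.any(fields <= 0):
        raise ValueError("fields must be strictly positive")
    out = np.empty(fields.shape[:3] + (shells.n_shells,))
    logF = np.log(fields)
    for s in range(shells.n_shells):
        vols = shells.volumes_in_shell(s)
        out[..., s] = np.exp(logF[..., vols].mean(axis=-1))
    return out


def field_geomean_slice(field: np.ndarray, mask: BrainMask, axis: int = 2) -> np.ndarray:
    """Per-slice geometric mean of a 3D field over in-mask voxels: F_{b,z}.

    Slices with no masked voxel are NaN.
    """
    if np.any(field <= 0):
        raise ValueError("field must be strictly positive")
    nz = field.shape[axis]
    out = np.full(nz, np.nan)
    logF = np.log(field)
    for s in range(nz):
        sl = [slice(None)] * 3
        sl[axis] = s
        msl = mask.mask[tuple(sl)]
        if msl.any():
            out[s] = np.exp(logF[tuple(sl)][msl].mean())
    return out
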