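"""Reading, writing and basic handling of diffusion MRI datasets.

Volumes are stored ``(x, y, z, volume)`` with 0-based voxel indexing; the
acquisition slice axis defaults to z (axis 2).  Gradient tables follow the
FSL dialect: a 3×N whitespace-separated ``bvec`` file of unit direction
vectors and a 1×N ``bval`` file of diffusion weightings in s/mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIDataset",
    "BrainMask",
    "ShellIndex",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "group_shells",
    "percentile_normalize",
]

#: widest through-plane receptive extent of the field-estimation network
MIN_SLICES = 9


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion weightings and unit gradient directions.

    ``dirs`` rows are unit vectors for diffusion-weighted volumes and may be
    the zero vector for b=0 volumes.
    """

    bvals: np.ndarray  # (nvol,) s/mm²
    dirs: np.ndarray  # (nvol, 3), unit norm or zero

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        dirs = np.asarray(self.dirs, dtype=float).reshape(-1, 3)
        if len(bvals) != len(dirs):
            raise ValueError(
                f"gradient table length mismatch: {len(bvals)} bvals vs "
                f"{len(dirs)} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value in gradient table")
        norms = np.linalg.norm(dirs, axis=1)
        nonzero = norms > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ValueError("nonzero gradient directions must have unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "dirs", dirs)

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DWIDataset:
    """A 4D diffusion MRI series with its gradient table.

    ``signal`` has shape (nx, ny, nz, nvol), arbitrary units, all finite and
    non-negative.  ``affine`` carries the NIfTI spatial metadata and is
    propagated unchanged to every output written for this dataset.
    """

    signal: np.ndarray
    gradients: GradientTable
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_axis: int = 2
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {sig.shape}")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal contains non-finite values")
        if sig.shape[3] != len(self.gradients):
            raise ValueError(
                f"volume count mismatch: image has {sig.shape[3]} volumes, "
                f"gradient table has {len(self.gradients)} entries"
            )
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")
        if sig.shape[self.slice_axis] < MIN_SLICES:
            raise ValueError(
                f"need at least {MIN_SLICES} slices along the slice axis, "
                f"got {sig.shape[self.slice_axis]}"
            )
        self.signal = sig

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def nvol(self) -> int:
        return self.signal.shape[3]

    def volume(self, v: int) -> np.ndarray:
        return self.signal[..., v]


@dataclass
class BrainMask:
    """Boolean brain mask on the spatial grid of a :class:`DWIDataset`."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask).astype(bool)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if not m.any():
            raise ValueError("brain mask is empty")
        self.mask = m

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ShellIndex:
    """Assignment of volumes to b-value shells."""

    shell_of_volume: np.ndarray  # (nvol,) int shell ids
    shell_b: np.ndarray  # (nshell,) representative b per shell, increasing

    @property
    def n_shells(self) -> int:
        return len(self.shell_b)

    def volumes_in_shell(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.shell_of_volume == s)


def _read_fsl_table(bvec_path, bval_path, nvol: int) -> GradientTable:
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    dirs = bvecs.T
    if len(bvals) != nvol or len(dirs) != nvol:
        raise ValueError(
            f"gradient files describe {len(bvals)} bvals / {len(dirs)} "
            f"directions but the image has {nvol} volumes"
        )
    # renormalise mild text round-off; keep exact zeros for b=0
    norms = np.linalg.norm(dirs, axis=1)
    nz = norms > 1e-12
    dirs = dirs.copy()
    dirs[nz] /= norms[nz, None]
    return GradientTable(bvals=bvals, dirs=dirs)


def read_dwi(image_path, bvec_path, bval_path, slice_axis: int = 2) -> DWIDataset:
    """Load a 4D NIfTI plus FSL-style bvec/bval files into a :class:`DWIDataset`."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    grad = _read_fsl_table(bvec_path, bval_path, data.shape[3])
    zooms = img.header.get_zooms()[:3]
    return DWIDataset(
        signal=data,
        gradients=grad,
        voxel_size=tuple(float(z) for z in zooms),
        slice_axis=slice_axis,
        affine=np.asarray(img.affine),
    )


def write_dwi(dataset: DWIDataset, image_path, bvec_path=None, bval_path=None) -> None:
    """Write a dataset to NIfTI (+ optional FSL gradient files)."""
    img = nib.Nifti1Image(dataset.signal.astype(np.float32), dataset.affine)
    img.header.set_zooms(tuple(dataset.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    if bvec_path is not None:
        np.savetxt(bvec_path, dataset.gradients.dirs.T, fmt="%.10g")
    if bval_path is not None:
        np.savetxt(bval_path, dataset.gradients.bvals[None, :], fmt="%.10g")


def read_mask(mask_path) -> BrainMask:
    img = nib.load(str(mask_path))
    return BrainMask(mask=np.asarray(img.dataobj) > 0.5)


def write_mask(mask: BrainMask, mask_path, affine=None) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(mask_path))


def group_shells(gradients: GradientTable, tolerance: float = 100.0) -> ShellIndex:
    """Cluster volumes into b-value shells by gap thresholding.

    Sorted b-values are split wherever consecutive values differ by more
    than ``tolerance`` (s/mm²); each resulting group is one shell and its
    representative b is the member mean.  Permutation-invariant in the
    volume ordering.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    bvals = gradients.bvals
    order = np.argsort(bvals, kind="stable")
    sorted_b = bvals[order]
    breaks = np.flatnonzero(np.diff(sorted_b) > tolerance)
    bounds = np.concatenate([[0], breaks + 1, [len(bvals)]])
    shell_of_volume = np.empty(len(bvals), dtype=int)
    shell_b = []
    for s in range(len(bounds) - 1):
        members = order[bounds[s] : bounds[s + 1]]
        shell_of_volume[members] = s
        shell_b.append(float(sorted_b[bounds[s] : bounds[s + 1]].mean()))
    return ShellIndex(shell_of_volume=shell_of_volume, shell_b=np.asarray(shell_b))


def percentile_normalize(
    dataset: DWIDataset, percentile: float = 0.99, per_volume: bool = False
) -> tuple[DWIDataset, np.ndarray]:
    """Divide the signal by its joint (or per-volume) percentile intensity.

    Returns the normalised dataset and the scale factor(s) needed to invert
    the operation: scalar array of shape () for joint normalisation, (nvol,)
    for per-volume.  Voxel-to-voxel signal ratios are unchanged.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    sig = dataset.signal
    if not np.any(sig > 0):
        raise ValueError("cannot normalise an all-zero dataset")
    if per_volume:
        scale = np.quantile(sig.reshape(-1, sig.shape[3]), percentile, axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        out = sig / scale
    else:
        scale = np.asarray(np.quantile(sig, percentile))
        if scale <= 0:
            raise ValueError("percentile intensity is non-positive")
        out = sig / scale
    return replace(dataset, signal=out), scale
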