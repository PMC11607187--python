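"""Spatially referenced image volumes: containers, NIfTI I/O, resampling, normalization.

Coordinate convention (used everywhere in the package): voxel indices are
0-based, the array axes are (x, y, z) with x the fastest in-plane axis and z
the slice axis, and the physical position of voxel ``(i, j, k)`` is
``origin + (i*sx, j*sy, k*sz)`` in mm (voxel-center convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "LabelMask",
    "ProbabilityMap",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "read_probability_map",
    "write_volume",
    "resample_image",
    "resample_mask",
    "normalize_intensity",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


@dataclass
class VolumeGrid:
    """A 3D scalar field on a regular anisotropic grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar values, one per voxel.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    axes : str
        Axis-order tag; always ``"xyz"`` for grids built by this package.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "xyz"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.voxels.ndim}D with shape "
                f"{self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "VolumeGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )


@dataclass
class LabelMask(VolumeGrid):
    """Binary segmentation mask: 0 = background, 1 = foreground (prostate)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary over {{0, 1}}, found values {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def labels(self) -> np.ndarray:
        return self.voxels


@dataclass
class ProbabilityMap(VolumeGrid):
    """Per-voxel foreground probability in [0, 1]; background is 1 - p."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = self.voxels.astype(np.float64)
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"probabilities must lie in [0, 1], found range [{lo}, {hi}]")
        np.clip(self.voxels, 0.0, 1.0, out=self.voxels)

    @property
    def probs(self) -> np.ndarray:
        return self.voxels


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI volume; spacing and origin taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return VolumeGrid(data, spacing, origin)


def read_mask(path: str | Path) -> LabelMask:
    g = read_volume(path)
    return LabelMask(g.voxels, g.spacing, g.origin)


def read_probability_map(path: str | Path) -> ProbabilityMap:
    g = read_volume(path)
    return ProbabilityMap(g.voxels, g.spacing, g.origin)


def write_volume(grid: VolumeGrid, path: str | Path, description: str = "") -> Path:
    """Write a grid as NIfTI-1. Masks go out as uint8, everything else float32."""
    path = Path(path)
    if isinstance(grid, LabelMask):
        data = grid.voxels.astype(np.uint8)
    else:
        data = grid.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, path)
    return path


# ---------------------------------------------------------------------------
# Resampling and normalization


def _output_geometry(shape, spacing, target_spacing):
    target_spacing = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(shape, spacing, target_spacing)
    )
    return new_shape, target_spacing


def _sample_coords(new_shape, spacing, target_spacing):
    # output voxel center j maps to input index j * t / s on each axis
    axes = [
        np.arange(n, dtype=np.float64) * t / s
        for n, s, t in zip(new_shape, spacing, target_spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def resample_image(grid: VolumeGrid, target_spacing, order: int = 3) -> VolumeGrid:
    """Resample intensities to ``target_spacing`` with third-order spline interpolation.

    Output values are clamped to the input intensity range to suppress spline
    overshoot (keeps resampled probability maps inside [0, 1]).
    """
    new_shape, target_spacing = _output_geometry(grid.shape, grid.spacing, target_spacing)
    if target_spacing == grid.spacing:
        return VolumeGrid(grid.voxels.copy(), grid.spacing, grid.origin)
    coords = _sample_coords(new_shape, grid.spacing, target_spacing)
    out = ndimage.map_coordinates(
        grid.voxels.astype(np.float64), coords, order=order, mode="nearest"
    )
    np.clip(out, grid.voxels.min(), grid.voxels.max(), out=out)
    return VolumeGrid(out, target_spacing, grid.origin)


def resample_mask(mask: LabelMask, target_spacing) -> LabelMask:
    """Resample a binary mask: linear interpolation of the 0/1 field, then
    threshold at 0.5 with ties going to foreground."""
    new_shape, target_spacing = _output_geometry(mask.shape, mask.spacing, target_spacing)
    if target_spacing == mask.spacing:
        return LabelMask(mask.voxels.copy(), mask.spacing, mask.origin)
    coords = _sample_coords(new_shape, mask.spacing, target_spacing)
    field_ = ndimage.map_coordinates(
        mask.voxels.astype(np.float64), coords, order=1, mode="nearest"
    )
    return LabelMask((field_ >= 0.5).astype(np.uint8), target_spacing, mask.origin)


def normalize_intensity(grid: VolumeGrid) -> VolumeGrid:
    """Per-volume z-score (population SD). A constant volume maps to all zeros."""
    v = grid.voxels.astype(np.float64)
    sd = v.std()
    if sd == 0:
        return VolumeGrid(np.zeros_like(v), grid.spacing, grid.origin)
    return VolumeGrid((v - v.mean()) / sd, grid.spacing, grid.origin)
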