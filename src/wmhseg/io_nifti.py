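"""NIfTI-1 I/O and the core image containers.

The whole library works on three in-memory types:

* :class:`Grid` — shape, voxel spacing and voxel→world affine (RAS+,
  0-based voxel indices), shared by every image that may be combined;
* :class:`Volume` — a 3D scalar image (a FLAIR or T1 carrier) on a grid;
* :class:`BinaryMask` — a 3D boolean image on a grid (brain masks, lesion
  masks, regions of interest).

Grid compatibility is enforced everywhere two images are combined: shapes
must match exactly and affines to an absolute tolerance of 1e-4 per entry
(coregistered files routinely differ in the last float digits). There is no
silent resampling anywhere in the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    IncompatibleGridError,
    NanVoxelError,
    NotAMaskError,
)

AFFINE_ATOL = 1e-4

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Grid:
    """A 3D voxel grid: shape, and the 4x4 voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3D with all dims >= 1, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel size along each axis in mm (column norms of the affine)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def compatible_with(self, other: "Grid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL, rtol=0.0
        )


def ensure_same_grid(a: "Grid", b: "Grid", context: str = "") -> None:
    """Raise :class:`IncompatibleGridError` unless *a* and *b* match."""
    if not a.compatible_with(b):
        prefix = f"{context}: " if context else ""
        raise IncompatibleGridError(
            f"{prefix}incompatible grids: shape {a.shape} vs {b.shape}; "
            f"affine\n{a.affine}\nvs\n{b.affine}"
        )


@dataclass
class Volume:
    """A 3D scalar image with its grid and free-form provenance metadata."""

    data: np.ndarray
    grid: Grid
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(f"Volume data must be 3D, got shape {self.data.shape}")
        if tuple(self.data.shape) != self.grid.shape:
            raise IncompatibleGridError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine


class BinaryMask:
    """A 3D boolean image bound to a :class:`Grid`.

    The True-voxel count is computed once at construction and exposed as
    :attr:`n_voxels` (O(1) thereafter).
    """

    def __init__(self, data: np.ndarray, grid: Grid):
        data = np.asarray(data)
        if data.ndim != 3:
            raise DimensionalityError(f"mask data must be 3D, got shape {data.shape}")
        if tuple(data.shape) != grid.shape:
            raise IncompatibleGridError(
                f"mask shape {data.shape} != grid shape {grid.shape}"
            )
        self.data: np.ndarray = data.astype(bool, copy=False)
        self.grid = grid
        self._n_voxels = int(np.count_nonzero(self.data))

    @property
    def n_voxels(self) -> int:
        return self._n_voxels

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.grid.compatible_with(other.grid) and bool(
            np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        return f"BinaryMask(shape={self.grid.shape}, n_voxels={self.n_voxels})"


def _load_3d(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # squeeze trailing singleton dimensions (4D files with one frame)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {data.ndim} non-singleton dimensions"
        )
    return np.asarray(data), np.asarray(img.affine, dtype=float)


def read_volume(path: PathLike) -> Volume:
    """Read a NIfTI-1 scalar volume (.nii or .nii.gz).

    Raises :class:`NanVoxelError` (reporting the affected voxel count) if the
    file contains NaNs, and :class:`DimensionalityError` for >3 non-singleton
    dimensions.
    """
    data, affine = _load_3d(path)
    fdata = data.astype(np.float64, copy=False)
    n_nan = int(np.count_nonzero(np.isnan(fdata)))
    if n_nan:
        raise NanVoxelError(f"{path}: {n_nan} NaN voxel(s) in image")
    grid = Grid(tuple(data.shape), affine)
    return Volume(fdata, grid, meta={"source": str(path)})


def write_volume(volume: Volume, path: PathLike, dtype: Any = np.float32) -> Path:
    """Write a volume as NIfTI-1; returns the path written."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=dtype), volume.grid.affine)
    nib.save(img, str(path))
    return path


def read_mask(path: PathLike, grid: Grid | None = None) -> BinaryMask:
    """Read a binary mask from NIfTI-1.

    The file must hold at most two distinct values after rounding (0/1 and
    0/255 dialects are both accepted); values > 0.5 map to True. If *grid* is
    given the mask's grid is checked against it and
    :class:`IncompatibleGridError` raised on mismatch.
    """
    data, affine = _load_3d(path)
    fdata = data.astype(np.float64, copy=False)
    if np.any(np.isnan(fdata)):
        raise NanVoxelError(f"{path}: NaN voxels in mask")
    distinct = np.unique(np.round(fdata))
    if distinct.size > 2:
        raise NotAMaskError(
            f"{path}: {distinct.size} distinct rounded values "
            f"({distinct[:5]}...); not a binary mask"
        )
    mask_grid = Grid(tuple(fdata.shape), affine)
    if grid is not None:
        ensure_same_grid(mask_grid, grid, context=str(path))
        mask_grid = grid
    return BinaryMask(fdata > 0.5, mask_grid)


def write_mask(mask: BinaryMask, path: PathLike) -> Path:
    """Write a mask as uint8 0/1 NIfTI-1 with its grid's affine."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
    return path
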