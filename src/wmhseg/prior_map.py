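"""A priori lesion probability maps.

Across a cohort, the voxelwise average of binary lesion masks (already
resampled to one common grid — registration itself is out of scope here and
must be done with standard tools) gives the a priori probability of finding
a lesion at each location. Such maps can feed generative segmentation tools
as an extra tissue channel. An optional Gaussian smoothing post-step is
provided, since probabilistic atlas channels are conventionally smooth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, IncompatibleGridError
from .io_nifti import BinaryMask, Grid, Volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ProbabilityMap:
    """Voxelwise lesion frequency in [0, 1] over ``n_subjects`` masks."""

    data: np.ndarray
    grid: Grid
    n_subjects: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if tuple(self.data.shape) != self.grid.shape:
            raise IncompatibleGridError(
                f"map shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("probability map values must lie in [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


MaskLike = Union[BinaryMask, Volume]


def build_prior(masks: Sequence[MaskLike]) -> ProbabilityMap:
    """Voxelwise arithmetic mean of lesion masks on a shared grid.

    Binary masks average to exact count fractions (value x n_subjects is an
    integer). Resampled masks with fractional values may also be passed as
    Volumes; values are clamped to [0, 1] before averaging. Raises
    :class:`IncompatibleGridError` naming the offending index on any grid
    mismatch, and :class:`EmptyMaskError` for an empty list.
    """
    if len(masks) == 0:
        raise EmptyMaskError("build_prior: need at least one mask")
    grid = masks[0].grid
    total = np.zeros(grid.shape, dtype=np.float64)
    for i, m in enumerate(masks):
        if not grid.compatible_with(m.grid):
            raise IncompatibleGridError(
                f"build_prior: mask {i} grid (shape {m.grid.shape}) does not match "
                f"mask 0 grid (shape {grid.shape})"
            )
        values = m.data.astype(np.float64) if isinstance(m, BinaryMask) else np.clip(
            np.asarray(m.data, dtype=np.float64), 0.0, 1.0
        )
        total += values
    return ProbabilityMap(total / len(masks), grid, n_subjects=len(masks))


def smooth_prior(prior: ProbabilityMap, fwhm_mm: float) -> ProbabilityMap:
    """Gaussian-smooth the map with the given full-width-half-maximum in mm.

    The kernel width is expressed in world units, so anisotropic voxels get
    anisotropic sigmas. ``fwhm_mm=0`` is the identity; a uniform map is a
    fixed point under any width (reflective boundary handling). Values are
    clipped back to [0,1] (floating-point smoothing can overshoot by
    epsilons).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return ProbabilityMap(prior.data.copy(), prior.grid, prior.n_subjects)
    sigmas = [fwhm_mm * _FWHM_TO_SIGMA / sp for sp in prior.grid.spacing]
    smoothed = ndimage.gaussian_filter(prior.data, sigma=sigmas, mode="reflect")
    return ProbabilityMap(np.clip(smoothed, 0.0, 1.0), prior.grid, prior.n_subjects)
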