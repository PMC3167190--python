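"""Modal-intensity threshold segmentation of white matter hyperintensities.

The procedure: (a) determine the modal pixel intensity of the brain-masked
FLAIR image, (b) keep voxels brighter than a fixed multiple of the mode
(default 1.45x), (c) remove isolated voxels — here interpreted as connected
components smaller than a configurable minimum size (default 2 voxels,
26-connectivity, in 3D).

The brain mask is expected from an external tissue segmentation: GM + WM
probability maps thresholded, hole-filled, and reduced to the largest
connected component (:func:`make_brain_mask`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError, EmptyMaskError
from .intensity_stats import HistogramStats, compute_stats
from .io_nifti import BinaryMask, Volume, ensure_same_grid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class ThresholdParams:
    """Parameters of the modal-threshold segmenter.

    ``factor`` multiplies the modal in-brain intensity (default 1.45);
    ``min_cluster_voxels`` is the smallest surviving connected component;
    ``connectivity`` the 3D neighbourhood (6, 18 or 26).
    """

    factor: float = 1.45
    min_cluster_voxels: int = 2
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.factor <= 1:
            raise ValueError(f"factor must be > 1, got {self.factor}")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class SegmentationResult:
    """Output of a segmentation run: the mask, the applied intensity
    threshold, the statistics that produced it, and bookkeeping."""

    mask: BinaryMask
    threshold_used: float
    stats: HistogramStats
    n_removed_clusters: int
    params: Any
    extra: dict[str, Any] = field(default_factory=dict)


def make_brain_mask(
    gm: Volume, wm: Volume, threshold: float = 0.5
) -> BinaryMask:
    """Brain mask from GM + WM tissue probability maps.

    Voxels where gm + wm > threshold, then internal holes (ventricles) are
    filled and only the largest connected component kept.
    """
    ensure_same_grid(gm.grid, wm.grid, context="make_brain_mask")
    raw = (np.asarray(gm.data) + np.asarray(wm.data)) > threshold
    filled = ndimage.binary_fill_holes(raw)
    labeled, n = ndimage.label(filled, structure=_structure(26))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        filled = labeled == keep
    return BinaryMask(filled, gm.grid)


def apply_brain_mask(flair: Volume, brain: BinaryMask) -> Volume:
    """Zero every voxel outside the brain mask; in-mask voxels unchanged."""
    ensure_same_grid(flair.grid, brain.grid, context="apply_brain_mask")
    out = np.where(brain.data, flair.data, 0.0)
    return Volume(out, flair.grid, meta=dict(flair.meta, skull_stripped=True))


def remove_small_clusters(
    mask: BinaryMask, min_voxels: int, connectivity: int = 26
) -> tuple[BinaryMask, int]:
    """Drop connected components smaller than *min_voxels*.

    Returns the filtered mask and the number of clusters removed. No voxel
    is ever added; ``min_voxels=1`` is the identity.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if min_voxels == 1 or mask.n_voxels == 0:
        return BinaryMask(mask.data.copy(), mask.grid), 0
    labeled, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 0:
        return BinaryMask(mask.data.copy(), mask.grid), 0
    sizes = np.bincount(labeled.ravel())[1:]  # component sizes, label 1..n
    small = np.flatnonzero(sizes < min_voxels) + 1
    out = mask.data.copy()
    if small.size:
        out[np.isin(labeled, small)] = False
    return BinaryMask(out, mask.grid), int(small.size)


def segment_threshold(
    flair: Volume,
    brain: BinaryMask,
    params: ThresholdParams = ThresholdParams(),
    bin_width: float | None = None,
) -> SegmentationResult:
    """Run the full modal-threshold segmentation.

    The threshold is ``params.factor`` times the modal in-brain intensity;
    candidate voxels are in-brain voxels strictly brighter than it; small
    clusters are then removed. Deterministic.
    """
    ensure_same_grid(flair.grid, brain.grid, context="segment_threshold")
    if brain.n_voxels == 0:
        raise EmptyMaskError("segment_threshold: empty brain mask")
    stats = compute_stats(flair, brain, bin_width=bin_width)
    if stats.mode == 0:
        raise DegenerateImageError(
            "modal in-brain intensity is 0; a mode-relative threshold is undefined"
        )
    threshold = params.factor * stats.mode
    candidate = BinaryMask(brain.data & (np.asarray(flair.data) > threshold), flair.grid)
    mask, n_removed = remove_small_clusters(
        candidate, params.min_cluster_voxels, params.connectivity
    )
    return SegmentationResult(
        mask=mask,
        threshold_used=float(threshold),
        stats=stats,
        n_removed_clusters=n_removed,
        params=params,
    )
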