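"""In-mask intensity statistics: histogram mode, mean, SD.

Both segmenters are parameterized by these statistics: the threshold
segmenter anchors on the modal (most frequent) intensity of the
brain-masked FLAIR, and the fuzzy segmenter seeds at mean + k.SD. All
statistics are computed over in-mask voxels only — the zeroed background of
a skull-stripped image would otherwise dominate the histogram and make a
mode-relative threshold meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError
from .io_nifti import BinaryMask, Volume, ensure_same_grid


@dataclass(frozen=True)
class HistogramStats:
    """Mode / mean / SD of in-mask intensities.

    ``mode`` is the center of the fullest histogram bin; on a tie the
    lower-intensity bin wins (deterministic, and biases thresholds
    conservatively low). ``sd`` is the population SD of in-mask voxels.
    """

    mode: float
    mean: float
    sd: float
    bin_width: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise EmptyMaskError("statistics require at least one in-mask voxel")
        if self.sd < 0 or self.bin_width <= 0:
            raise ValueError("need sd >= 0 and bin_width > 0")


def _auto_bin_width(values: np.ndarray) -> float:
    """Bin width rule: 1 for integer-valued images; else Freedman–Diaconis,
    clamped to at least (max-min)/512 so the histogram never explodes."""
    if np.all(values == np.round(values)):
        return 1.0
    span = float(values.max() - values.min())
    if span == 0.0:
        return 1.0
    q75, q25 = np.percentile(values, [75, 25])
    fd = 2.0 * (q75 - q25) * values.size ** (-1.0 / 3.0)
    return max(fd, span / 512.0) if fd > 0 else span / 512.0


def compute_stats(
    image: Volume, mask: BinaryMask, bin_width: float | None = None
) -> HistogramStats:
    """Histogram statistics of *image* over the voxels of *mask*.

    ``bin_width=None`` selects the automatic rule (1 for integer images,
    Freedman–Diaconis otherwise). Bins are centered so that for integer data
    with unit bins the mode is an exact integer intensity. Degenerate
    constant images yield sd=0 and mode equal to the constant.
    """
    ensure_same_grid(image.grid, mask.grid, context="compute_stats")
    if mask.n_voxels == 0:
        raise EmptyMaskError("compute_stats: empty mask")
    values = np.asarray(image.data)[mask.data].astype(np.float64)
    mean = float(values.mean())
    sd = float(values.std())
    if bin_width is None:
        bin_width = _auto_bin_width(values)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return HistogramStats(mode=lo, mean=mean, sd=sd, bin_width=bin_width,
                              n_voxels=values.size)
    # bin edges offset by half a width so centers land on lo, lo+w, lo+2w, ...
    n_bins = int(np.floor((hi - lo) / bin_width + 0.5)) + 1
    edges = lo - bin_width / 2.0 + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    mode_idx = int(np.argmax(counts))  # argmax takes the first (lowest) max bin
    mode = min(lo + bin_width * mode_idx, hi)  # edge bin centers can overshoot
    return HistogramStats(mode=float(mode), mean=mean, sd=sd,
                          bin_width=float(bin_width), n_voxels=values.size)


def seed_threshold(stats: HistogramStats, k: float) -> float:
    """The seeding intensity threshold mean + k.SD (k > 0)."""
    if k <= 0:
        raise ValueError(f"SD multiplier must be > 0, got {k}")
    return stats.mean + k * stats.sd
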