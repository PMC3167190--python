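"""Validation metrics: the overlap ratio and cohort comparison tables.

The central statistic is the overlap ratio between two regions of interest,

    overlap = 100 * |ROI1 ∩ ROI2| / |ROI1 ∪ ROI2|,

i.e. the Jaccard index expressed as a percentage. It is symmetric, 100 for
identical nonempty masks and 0 for disjoint nonempty masks. When both masks
are empty the ratio is undefined as written; we adopt the convention that
two raters agreeing there are no lesions is perfect agreement (100), flag it
explicitly, and log a warning.

Cohort summaries (per-method mean, sample SD, min, max of the overlap, the
standard way segmentation validation studies tabulate agreement) are built
on pandas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_nifti import BinaryMask, ensure_same_grid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Voxel counts and the overlap percentage for one mask pair."""

    n_intersection: int
    n_union: int
    n_roi1: int
    n_roi2: int
    overlap_pct: float
    both_empty: bool = False

    def as_dict(self) -> dict:
        return {
            "n_intersection": self.n_intersection,
            "n_union": self.n_union,
            "n_roi1": self.n_roi1,
            "n_roi2": self.n_roi2,
            "overlap_pct": self.overlap_pct,
            "both_empty": self.both_empty,
        }


@dataclass
class ComparisonTable:
    """Per-subject overlap rows plus a per-method summary.

    ``rows`` has columns (subject, method, overlap_pct, ...); ``summary`` is
    indexed by method with columns n, mean, sd, min, max. SD is the sample
    (n-1) standard deviation; for n=1 it is reported as 0.0 with
    ``sd_defined`` False.
    """

    rows: pd.DataFrame
    summary: pd.DataFrame


def overlap(roi1: BinaryMask, roi2: BinaryMask) -> OverlapResult:
    """Overlap ratio (Jaccard x 100) of two masks on one grid."""
    ensure_same_grid(roi1.grid, roi2.grid, context="overlap")
    n_inter = int(np.count_nonzero(roi1.data & roi2.data))
    n_union = int(np.count_nonzero(roi1.data | roi2.data))
    if n_union == 0:
        logger.warning("overlap: both masks empty; reporting 100 by convention")
        return OverlapResult(0, 0, 0, 0, overlap_pct=100.0, both_empty=True)
    return OverlapResult(
        n_intersection=n_inter,
        n_union=n_union,
        n_roi1=roi1.n_voxels,
        n_roi2=roi2.n_voxels,
        overlap_pct=100.0 * n_inter / n_union,
    )


def summarize(rows: pd.DataFrame | Iterable[Mapping]) -> ComparisonTable:
    """Per-method summary (n, mean, sample SD, min, max) of overlap rows.

    *rows* is a DataFrame or iterable of records with at least ``method``
    and ``overlap_pct`` fields; a missing ``subject`` column is filled with
    a running index. Values are kept at full precision — rounding is for
    presentation only.
    """
    df = pd.DataFrame(rows).copy()
    if df.empty:
        raise ValueError("summarize: need at least one row")
    if "overlap_pct" not in df or "method" not in df:
        raise ValueError("rows need 'method' and 'overlap_pct' fields")
    if "subject" not in df:
        df.insert(0, "subject", range(len(df)))
    grouped = df.groupby("method")["overlap_pct"]
    summary = grouped.agg(n="count", mean="mean", sd="std", min="min", max="max")
    summary["sd_defined"] = summary["n"] > 1
    summary["sd"] = summary["sd"].fillna(0.0)
    return ComparisonTable(rows=df, summary=summary)


def rater_agreement(
    manual_a: Sequence[BinaryMask],
    manual_b: Sequence[BinaryMask],
    label: str = "rater_agreement",
) -> ComparisonTable:
    """Pairwise overlap between two raters' (or two sessions') mask series.

    The caller labels the comparison (e.g. within-rater repeat vs
    between-rater). Lists must be paired and on matched grids.
    """
    if len(manual_a) != len(manual_b):
        raise ValueError(
            f"rater_agreement: paired lists required, got {len(manual_a)} vs {len(manual_b)}"
        )
    if len(manual_a) == 0:
        raise ValueError("rater_agreement: empty pair list")
    records = []
    for i, (a, b) in enumerate(zip(manual_a, manual_b)):
        res = overlap(a, b)
        records.append(
            {"subject": i, "method": label, "overlap_pct": res.overlap_pct}
        )
    return summarize(records)
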