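"""Exception hierarchy for wmhseg.

All library-raised errors derive from :class:`WmhsegError` so callers (and the
CLI) can catch everything wmhseg-specific in one place.
"""


class WmhsegError(Exception):
    """Base class for all wmhseg errors."""


class IncompatibleGridError(WmhsegError):
    """Two images that must share a voxel grid (shape + affine) do not.

    Raised instead of silently resampling: combining masks or volumes on
    mismatched grids is always a pipeline bug upstream.
    """


class NotAMaskError(WmhsegError):
    """A file read as a binary mask contains more than two distinct values."""


class DimensionalityError(WmhsegError):
    """An image has more than three non-singleton dimensions."""


class NanVoxelError(WmhsegError):
    """An image contains NaN voxels."""


class EmptyMaskError(WmhsegError):
    """An operation requiring a nonempty mask received an empty one."""


class DegenerateImageError(WmhsegError):
    """Image statistics are degenerate for the requested operation
    (e.g. all-zero brain, or zero intensity spread where spread is required)."""


class EmptySeedError(WmhsegError):
    """Fuzzy connectivity was requested with an empty seed set."""


class PhantomSpecError(WmhsegError):
    """A phantom specification violates its invariants
    (e.g. a lesion sphere escapes the white-matter compartment)."""
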