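"""Synthetic FLAIR-like brain phantoms with known ground truth.

The phantom is three concentric ellipsoids — a CSF shell enclosing a grey
matter (GM) shell enclosing a white matter (WM) core — with spherical
hyperintense lesions painted inside the WM, optional single-voxel bright
"flow artifact" confounds inside the GM (emulating the bright blood-flow
voxels that plague intensity-threshold segmentation of real FLAIR scans),
and additive Gaussian noise. Intensities follow FLAIR contrast: CSF is
suppressed (dark), GM intermediate, WM bright-ish, lesions brighter than WM,
flow artifacts brighter still.

Every compartment's geometry is analytic, so ground truth (tissue labels,
lesion mask, brain mask) is known exactly; all randomness flows through one
seeded generator, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import PhantomSpecError
from .io_nifti import BinaryMask, Grid, Volume

# tissue label codes in the label image
LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
LABEL_LESION = 4
LABEL_FLOW = 5

#: Default compartment mean intensities (arbitrary FLAIR-like units).
#: WM sits at 100 so noise levels and lesion factors read as percentages;
#: flow artifacts are brighter than any plausible lesion.
DEFAULT_INTENSITIES: dict[str, float] = {
    "background": 0.0,
    "csf": 30.0,
    "gm": 70.0,
    "wm": 100.0,
    "flow_artifact": 220.0,
}

# ellipsoid semi-axes as fractions of the field of view (per axis, in mm)
_CSF_FRAC = 0.46
_GM_FRAC = 0.41
_WM_FRAC = 0.36


@dataclass(frozen=True)
class LesionSpec:
    """One spherical lesion: center (voxel coordinates, may be fractional),
    radius in mm, and intensity as a multiplier on the WM mean (> 1)."""

    center: tuple[float, float, float]
    radius_mm: float
    intensity_factor: float = 1.8

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise PhantomSpecError(f"lesion radius must be > 0, got {self.radius_mm}")
        if self.intensity_factor <= 1:
            raise PhantomSpecError(
                f"lesion intensity_factor must exceed 1, got {self.intensity_factor}"
            )


@dataclass
class PhantomSpec:
    """Full description of one phantom; generation is deterministic given seed."""

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES)
    )
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    n_flow_voxels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        inten = self.intensities
        for key in ("background", "csf", "gm", "wm", "flow_artifact"):
            if key not in inten:
                raise PhantomSpecError(f"intensities missing compartment '{key}'")
        if not (inten["wm"] > inten["background"] >= 0):
            raise PhantomSpecError(
                "need WM intensity > background intensity >= 0, got "
                f"wm={inten['wm']}, background={inten['background']}"
            )
        if inten["flow_artifact"] <= inten["wm"]:
            raise PhantomSpecError("flow artifact intensity must exceed WM intensity")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if self.n_flow_voxels < 0:
            raise PhantomSpecError("n_flow_voxels must be >= 0")

    def to_json(self) -> str:
        d = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "intensities": self.intensities,
            "lesions": [
                {
                    "center": list(l.center),
                    "radius_mm": l.radius_mm,
                    "intensity_factor": l.intensity_factor,
                }
                for l in self.lesions
            ],
            "noise_sd": self.noise_sd,
            "n_flow_voxels": self.n_flow_voxels,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        lesions = [
            LesionSpec(
                center=tuple(l["center"]),
                radius_mm=float(l["radius_mm"]),
                intensity_factor=float(l.get("intensity_factor", 1.8)),
            )
            for l in d.get("lesions", [])
        ]
        return cls(
            shape=tuple(d.get("shape", (64, 64, 48))),
            spacing=tuple(d.get("spacing", (1.0, 1.0, 1.0))),
            intensities=d.get("intensities", dict(DEFAULT_INTENSITIES)),
            lesions=lesions,
            noise_sd=float(d.get("noise_sd", 0.0)),
            n_flow_voxels=int(d.get("n_flow_voxels", 0)),
            seed=int(d.get("seed", 0)),
        )


def default_phantom_spec(
    seed: int = 0,
    noise_sd: float = 5.0,
    lesion_factor: float = 1.8,
    n_flow_voxels: int = 0,
    shape: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhantomSpec:
    """The standard test phantom: three well-defined WM lesions (~0.9 mL total
    at default geometry), 5% additive noise relative to the WM mean of 100.

    Lesion centers scale with the field of view so any reasonable shape works.
    """
    c = tuple((s - 1) / 2.0 for s in shape)
    sp = spacing
    lesions = [
        LesionSpec((c[0] + 10 / sp[0], c[1], c[2]), 4.0, lesion_factor),
        LesionSpec((c[0] - 8 / sp[0], c[1] + 6 / sp[1], c[2] + 2 / sp[2]), 3.0, lesion_factor),
        LesionSpec((c[0], c[1] - 9 / sp[1], c[2] - 5 / sp[2]), 3.5, lesion_factor),
    ]
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        lesions=lesions,
        noise_sd=noise_sd,
        n_flow_voxels=n_flow_voxels,
        seed=seed,
    )


def _world_offsets(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis mm offsets of each voxel center from the volume center."""
    center = [(s - 1) / 2.0 for s in spec.shape]
    axes = [
        (np.arange(spec.shape[i]) - center[i]) * spec.spacing[i] for i in range(3)
    ]
    return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]


def _ellipsoid(spec: PhantomSpec, frac: float) -> np.ndarray:
    x, y, z = _world_offsets(spec)
    semi = [frac * spec.shape[i] * spec.spacing[i] for i in range(3)]
    return (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0


def _grid_for(spec: PhantomSpec) -> Grid:
    affine = np.diag(list(spec.spacing) + [1.0])
    return Grid(tuple(spec.shape), affine)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, BinaryMask, BinaryMask, Volume]:
    """Generate one phantom.

    Returns ``(flair, brain_mask, lesion_truth, tissue_labels)``:

    * ``flair`` — compartment means, lesion overrides, flow artifacts, plus
      N(0, noise_sd) noise, clipped at 0 (magnitude images are non-negative);
    * ``brain_mask`` — the CSF ∪ GM ∪ WM region;
    * ``lesion_truth`` — exactly the voxels whose centers fall inside a
      lesion sphere;
    * ``tissue_labels`` — integer label image (background 0, CSF 1, GM 2,
      WM 3, lesion 4, flow artifact 5); every voxel has exactly one label.

    Raises :class:`PhantomSpecError`, naming the lesion, if any lesion sphere
    extends outside the WM compartment. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _grid_for(spec)

    csf_region = _ellipsoid(spec, _CSF_FRAC)
    gm_region = _ellipsoid(spec, _GM_FRAC)
    wm_region = _ellipsoid(spec, _WM_FRAC)

    labels = np.full(spec.shape, LABEL_BACKGROUND, dtype=np.int16)
    labels[csf_region] = LABEL_CSF
    labels[gm_region] = LABEL_GM
    labels[wm_region] = LABEL_WM

    # paint lesions; each sphere must sit fully inside WM
    x, y, z = _world_offsets(spec)
    intensity = np.full(spec.shape, spec.intensities["background"], dtype=np.float64)
    intensity[labels == LABEL_CSF] = spec.intensities["csf"]
    intensity[labels == LABEL_GM] = spec.intensities["gm"]
    intensity[labels == LABEL_WM] = spec.intensities["wm"]

    center_mm = [(s - 1) / 2.0 for s in spec.shape]
    for i, lesion in enumerate(spec.lesions):
        cx = (lesion.center[0] - center_mm[0]) * spec.spacing[0]
        cy = (lesion.center[1] - center_mm[1]) * spec.spacing[1]
        cz = (lesion.center[2] - center_mm[2]) * spec.spacing[2]
        sphere = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion.radius_mm**2
        outside = sphere & (labels != LABEL_WM) & (labels != LABEL_LESION)
        if np.any(outside):
            raise PhantomSpecError(
                f"lesion {i} (center {lesion.center}, r={lesion.radius_mm} mm) "
                f"escapes the WM compartment at {int(np.count_nonzero(outside))} voxel(s)"
            )
        labels[sphere] = LABEL_LESION
        intensity[sphere] = lesion.intensity_factor * spec.intensities["wm"]

    # flow artifacts: single bright voxels sampled uniformly within GM
    if spec.n_flow_voxels:
        gm_idx = np.flatnonzero(labels.ravel() == LABEL_GM)
        if gm_idx.size < spec.n_flow_voxels:
            raise PhantomSpecError(
                f"cannot place {spec.n_flow_voxels} flow voxels in "
                f"{gm_idx.size} GM voxels"
            )
        chosen = rng.choice(gm_idx, size=spec.n_flow_voxels, replace=False)
        flat_labels = labels.ravel()
        flat_labels[chosen] = LABEL_FLOW
        intensity.ravel()[chosen] = spec.intensities["flow_artifact"]

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    brain = BinaryMask(labels != LABEL_BACKGROUND, grid)
    lesion_truth = BinaryMask(labels == LABEL_LESION, grid)
    flair = Volume(intensity, grid, meta={"phantom_seed": spec.seed})
    label_vol = Volume(
        labels.astype(np.float64),
        grid,
        meta={"legend": "0=background 1=csf 2=gm 3=wm 4=lesion 5=flow"},
    )
    return flair, brain, lesion_truth, label_vol


def lesion_volume_ml(mask: BinaryMask) -> float:
    """Lesion load in mL: true-voxel count x voxel volume (mm^3) / 1000."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0
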