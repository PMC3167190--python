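# wmhseg

Automated segmentation and validation of **white matter hyperintensities
(WMHs)** — the bright lesions seen in cerebral white matter on FLAIR MRI that
accompany small-vessel disease and cognitive decline in aging. The package is
aimed at neuroimaging researchers who need reproducible, fully automated
lesion masks and honest agreement statistics for cohort studies, and at
anyone validating such segmenters without access to proprietary patient data.

## What it implements

All images are NIfTI-1 volumes (`.nii` / `.nii.gz`); masks are uint8 0/1.
Grid compatibility (shape + affine) is enforced everywhere — there is no
silent resampling.

* **Modal-intensity threshold segmentation** (`segment_threshold`): on the
  brain-masked FLAIR image, find the modal (most frequent) intensity
  *M*, keep voxels with intensity > *f·M* (default *f* = 1.45), then remove
  isolated clusters below a minimum size. The brain mask comes from external
  GM + WM tissue probability maps (`make_brain_mask`: threshold at 0.5,
  fill holes, keep the largest component).
* **Seeded fuzzy-connectedness segmentation** (`segment_fuzzy`): seed at
  in-brain voxels with intensity ≥ mean + *k*·SD (*k* = 3 by default, 2.5 as
  a permissive variant), grow each seed by max–min fuzzy connectivity

  κ(v) = max over paths seed→v of the minimum per-step affinity,
  affinity(c,d) = exp(−((I(c)+I(d))/2 − m)² / (2 σ²)),

  with m, σ estimated from the current seeds; absorb voxels with κ ≥ 0.5,
  re-detect seeds among the remaining voxels, and stop when none are left.
* **A priori lesion probability maps** (`build_prior`): the voxelwise average
  of cohort lesion masks on a common grid, with optional Gaussian smoothing —
  usable as an extra channel in atlas-based segmentation tools.
* **Validation metrics** (`overlap`, `summarize`, `rater_agreement`): the
  overlap ratio

  Overlap = 100 · |ROI₁ ∩ ROI₂| / |ROI₁ ∪ ROI₂|

  (the Jaccard index as a percentage) and per-method cohort tables
  (mean, sample SD, min, max).
* **Synthetic brain phantoms** (`generate_phantom`): concentric-ellipsoid
  CSF/GM/WM compartments with FLAIR-like contrast, spherical WM lesions of
  configurable size and brightness, optional single-voxel bright
  "flow artifact" confounds, and seeded Gaussian noise — so every algorithm
  is testable against exact ground truth with no data download.

## Worked example

```python
from wmhseg import (generate_phantom, segment_threshold, segment_fuzzy,
                    overlap, lesion_volume_ml)
from wmhseg.phantom import default_phantom_spec

# a phantom with three WM lesions at 1.8x the WM intensity, 10% noise
spec = default_phantom_spec(seed=2, noise_sd=10.0)
flair, brain, truth, labels = generate_phantom(spec)

res = segment_threshold(flair, brain)      # threshold = 1.45 x mode
print(round(res.threshold_used, 2))        # 146.79  (mode was 101.23)
print(res.mask.n_voxels)                   # 576 voxels segmented
print(round(lesion_volume_ml(res.mask), 3))# 0.576 mL lesion load
print(round(overlap(res.mask, truth).overlap_pct, 2))  # 100.0

fz = segment_fuzzy(flair, brain)           # seeds at mean + 3 SD (171.26)
print(round(overlap(fz.mask, truth).overlap_pct, 2))   # 99.31
```

The threshold segmenter recovers these well-defined lesions exactly; the
fuzzy grower misses a few low-intensity boundary voxels (99.31% overlap),
mirroring its known tendency to underselect lesion rims and small clusters.

The same pipeline from the shell:

```bash
wmhseg phantom --seed 2 --out-dir ph/
wmhseg segment-threshold --flair ph/flair.nii.gz --brain-mask ph/brain_mask.nii.gz \
    --out seg.nii.gz
wmhseg overlap --a seg.nii.gz --b ph/lesion_truth.nii.gz
```

Every command writes a JSON sidecar with the resolved parameters, so reruns
with the same seed are byte-identical.

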