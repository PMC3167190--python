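# Methods

This note documents the models and procedures wmhseg implements, the
parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical conventions that make results reproducible.

## Image model and containers

All computation happens on 3D scalar volumes with a NIfTI affine (0-based
voxel indices, RAS+ world coordinates). Two images may be combined only if
their shapes match exactly and their affines agree entrywise to an absolute
tolerance of 1e-4 — loose enough to absorb the float jitter that
coregistration tools leave in headers, tight enough to catch any real grid
difference. Violations raise `IncompatibleGridError`; the library never
resamples silently, because a resampling step hidden inside a metric or a
segmenter is a classic source of irreproducible lesion volumes.

Masks binarise at > 0.5 with no prior rounding, which handles both 0/1 and
0/255 file dialects deterministically; files with more than two distinct
rounded values are rejected as not-a-mask rather than guessed at.

## Modal-intensity threshold segmentation

The segmenter assumes FLAIR contrast: normal white matter forms the largest
tissue compartment and lesions are strictly brighter than it. The modal
(histogram-peak) intensity of the *brain-masked* image then tracks normal WM,
and a fixed multiple of it separates lesion from tissue:

1. mode *M* of in-brain intensities;
2. candidate voxels: in-brain intensity > 1.45·*M* (strict inequality —
   arbitrary but fixed, and documented so results are reproducible);
3. connected components smaller than `min_cluster_voxels` removed.

Decisions worth recording:

* **In-mask statistics only.** Computing the mode over a skull-stripped
  image including its zeroed background would let the background bin win and
  make a mode-relative threshold meaningless; all statistics here are
  restricted to mask voxels.
* **Histogram binning.** Integer-valued images use bin width 1; float images
  use the Freedman–Diaconis width clamped to at least (max−min)/512, so both
  raw-integer and rescaled-float MRI yield a stable mode. Bins are centered
  so integer data with unit bins produce integer modes. On a tie the
  lower-intensity bin wins: deterministic, and the conservative direction
  (a lower mode lowers the threshold, favouring sensitivity). Edge-bin
  centers are clamped into the observed intensity range.
* **"Isolated" clusters.** The removal step is parameterized as connected
  components below a minimum size (default 2 voxels, 26-connectivity, in 3D
  rather than per slice) — the smallest faithful reading of removing
  isolated pixels, kept configurable because reasonable implementations
  differ. At the default, single-voxel bright confounds (blood-flow voxels)
  are removed; at `min_cluster_voxels=1` they survive, and the test suite
  exercises both branches because that failure mode is characteristic of
  intensity thresholding on real FLAIR.
* **Brain mask construction.** GM + WM probability maps (from any external
  tissue segmentation — producing them is out of scope) are summed,
  thresholded at the conventional 0.5 posterior cut, hole-filled (ventricles
  lie inside the brain), and reduced to the largest connected component.

## Seeded fuzzy-connectedness segmentation

The second segmenter grows lesions from high-confidence seeds:

* **Seeding.** In-brain voxels with intensity ≥ mean + k·SD (k = 3.0
  default; 2.5 as the permissive variant). Mean and SD are global in-brain
  statistics (not slice-wise, which the method's description leaves open).
* **Affinity.** The method family is defined up to a per-step affinity; we
  use the canonical intensity-homogeneity Gaussian kernel of classical fuzzy
  connectedness, centered on the current seed mean m with width
  σ = `sigma_scale` × seed SD. When the seeds have zero spread (a single
  seed, or identical intensities) σ falls back to 10% of the seed mean —
  without a floor the kernel would degenerate to an indicator function.
* **Connectivity.** A voxel's membership is the max–min path strength from
  any seed: the best path's weakest link. It is computed by best-first
  (priority-queue) propagation, which finalizes voxels in decreasing
  strength order and is mathematically identical to exhaustive path
  enumeration; the test suite certifies the equality against a brute-force
  union-find oracle on random small grids. Because finalization order is
  monotone, propagation may stop once the frontier drops below the
  absorption cut (0.5 by default), which keeps the cost proportional to the
  grown region rather than the brain.
* **Iteration.** Voxels with connectivity ≥ the cut join the mask and are
  excluded from subsequent seed detection; seed statistics are recomputed
  over the remaining voxels each round; the loop stops when no seeds remain.
  This reading matches the stopping rule "no seeds left"; whether the
  original method rescanned raw intensities or reused connectivity output
  for its seed update is not determinable from its published summary, so the
  interpretation is documented here and the pieces (`detect_seeds`,
  `fuzzy_connectivity`) are exposed separately for anyone who prefers
  another composition. The segmented set grows strictly every round, so the
  loop terminates regardless of `max_iterations`; the cap (default 20) only
  guards pathological inputs and is reported in the result when hit.

Behaviourally, the two segmenters fail differently, and the tests pin both
modes down: lowering k from 3.0 to 2.5 can only add seeds, so the fuzzy mask
never shrinks — but when bright non-lesion voxels are present the extra
growth is mostly false positive and overlap against truth drops. Conversely
a small lesion at 1.5× the WM intensity sits above the 1.45×mode threshold
but below mean + 3 SD, so the threshold segmenter finds it and the fuzzy
segmenter returns nothing.

## A priori probability maps

Cohort lesion masks already resampled to one common grid are averaged
voxelwise; the result is the empirical lesion frequency in [0,1]
(`value × n_subjects` is an integer for binary inputs; fractional-valued
resampled masks are accepted and clamped to [0,1] first). Registration into
the common space is deliberately out of scope — it is a solved problem in
standard toolchains, and the module refuses mismatched grids rather than
hiding a resampler. Optional Gaussian smoothing (FWHM in mm, anisotropic
voxels handled in world units, reflective boundaries so a uniform map is a
fixed point) is provided because probabilistic atlas channels are
conventionally smooth; it defaults to off since whether to smooth is a
downstream modelling choice.

## Overlap validation

Agreement between two masks is the Jaccard index × 100. It is symmetric,
100 iff the nonempty masks coincide, 0 iff they are disjoint. When both
masks are empty the ratio is 0/0; we define it as 100 with an explicit
`both_empty` flag and a logged warning — two raters agreeing that there are
no lesions is perfect agreement, but the convention must be visible.
Cohort summaries report the sample (n−1) SD; an n = 1 group reports SD 0
with `sd_defined = False` rather than NaN. Overlap is computed in voxel
counts, which on an enforced-shared grid is equivalent to mm³.

## Synthetic phantoms

The phantom is three concentric ellipsoids — CSF shell ⊃ GM shell ⊃ WM
core — at semi-axes 0.46/0.41/0.36 of the field of view, defaulting to a
64×64×48 grid at 1 mm isotropic spacing. Compartment means follow FLAIR
contrast (background 0, CSF 30, GM 70, WM 100 arbitrary units) with WM the
largest compartment, so the noise-free in-brain mode equals the WM mean by
construction. Spherical lesions live strictly inside the WM core (escaping
spheres are a spec error, named per lesion); the standard test phantom
carries three lesions of radii 3–4 mm (~0.9 mL total — a scaled-down but
realistic lesion load for the scaled-down geometry). Default lesion
brightness is 1.8× WM, the "well-defined lesion" regime; default noise is
5% of the WM mean, with robustness tests run at 10%. Flow-artifact
confounds are single GM voxels set to 2.2× WM — brighter than any lesion,
as arterial flow appears on real FLAIR. All randomness flows through one
`numpy` generator seeded from the spec, so phantoms are bit-reproducible.

What the phantom does **not** emulate: Rician noise statistics, bias
fields, partial-volume boundaries, anatomical tissue geometry, or T1
contrast. Noise is additive Gaussian (clipped at zero) because the
algorithms under test consume only intensity ordering and histogram shape,
which Gaussian noise exercises adequately. Passing tests therefore
demonstrate algorithmic correctness and the documented failure modes — not
clinical-grade accuracy on patient data, where skull-stripping quality,
bias fields and partial volume dominate real error budgets.

## Problem sizes and tolerances

The test suite and the acceptance script use 64×64×48 phantoms (~80k brain
voxels), ten-phantom cohorts, 100 random ≤3×3×3 grids for the
fuzzy-connectivity oracle, and 16³ random masks for the counting oracles —
sizes at which every brute-force oracle is exact and the whole suite runs in
seconds. Oracle comparisons assert to 1e-12 (identical arithmetic up to
float ordering); recovery bounds on noisy phantoms assert overlap ≥ 80%,
comfortably below the ~99% the default conditions achieve, so they test the
mechanism rather than a tuned constant.

## Known limitations

* The affinity kernel and the seed-update rule are principled
  reconstructions of a method family, not a line-for-line port of any
  specific historical implementation; `sigma_scale`, the connectivity cut
  and the neighbourhood are exposed for calibration.
* The threshold factor 1.45 is a fixed scanner-calibrated constant; images
  whose WM mode does not dominate the brain histogram (severe atrophy,
  failed skull stripping) violate the model assumptions of both segmenters.
* No surface-distance metrics (Hausdorff/ASSD) and no statistical testing
  between methods; the validation currency is the overlap ratio and its
  cohort summaries.
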