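# Methods

This note documents the models, conventions and numerical choices behind
`nucshell`, in the order the pipeline applies them, together with what the
synthetic validation does and does not demonstrate.

## Segmentation

**Smoothing.** Each stack is smoothed with a separable Gaussian whose
standard deviations are specified in micrometres and converted per axis to
voxels (`sigma_um / spacing_um`), so anisotropic stacks are smoothed
isotropically in physical space. The default `sigma_um = (0.21, 0.10,
0.10)` — one Z step axially, two XY pixels laterally at the reference
spacing of 0.21 × 0.05 × 0.05 µm — suppresses shot noise at scales below
the ~140 nm lateral optical resolution without erasing the punctate
staining itself. Boundaries are reflective; output is float64.

**Thresholding.** The Otsu threshold maximizes the between-class variance
`w0·w1·(μ0−μ1)²` over a 256-bin histogram (first maximum on ties). The
returned threshold is the midpoint between the largest background and
smallest foreground intensity of the optimal split. This convention
matters on well-separated bimodal data: the variance curve is exactly flat
across an empty histogram gap, so the argmax alone is arbitrary within the
gap, while the midpoint is invariant to it and keeps the strict
`intensity > threshold` foreground rule unambiguous. Foreground uses
strict inequality by default (`threshold_mode="inclusive"` switches
to ≥); ties only arise on integer synthetic data.

**Threshold estimated on smoothed, applied to raw.** `segment_stack`
computes the Otsu threshold from the *smoothed* image (a stable histogram)
but binarizes the *raw* voxels. Binarizing the smoothed image instead
systematically over-segments envelope-stained nuclei: the blurred bright
rim remains above threshold roughly one smoothing sigma beyond the true
edge, which inflates `d_max` by ~10% and leaks background voxels into the
outer shells — exactly the layers this analysis cares about. On phantoms,
raw binarization recovers the true mask at Jaccard ≈ 0.998 in both the
flat-staining and rim-staining regimes, where smoothed binarization
reaches only ≈ 0.86 on rim-stained objects.

**Morphology.** The refinement sequence is configurable; the default
`[closing r=2, erosion r=1, dilation r=1]` (ball-shaped elements, radii in
voxels) closes gaps between staining puncta and removes thin noise
bridges, with zero net boundary shift. Masks are padded with background by
the element radius before each operation and cropped after; without the
padding, scipy's closing erodes objects at the array border (its final
erosion treats out-of-array as background) and loses the guarantee that
closing never removes voxels.

**Component filtering.** Connected components use face (6-neighbour)
connectivity by default — conservative against diagonal leakage through
noise; full 26-connectivity is available. Components below
`min_volume_um3 = 50 µm³` (far below any nucleus, above stain debris) are
dropped; 0 disables the filter. Surviving labels are renumbered 1..N by
decreasing volume, ties broken by original label for determinism.

**Border clearing.** Components with any voxel on the four lateral faces
(y = 0, y = max, x = 0, x = max) are removed: they are partial nuclei.
Components touching only the first/last Z plane are *kept*, because
confocal stacks routinely clip flat nuclei axially and discarding them
would bias the sample toward thin nuclei. The operation is idempotent.

## Distance transform and shell partition

The exact Euclidean distance transform (scipy's implementation) assigns
each foreground voxel its distance to the nearest *background voxel
centre* — boundary-adjacent foreground voxels therefore carry one axis
step, not zero; this convention is fixed because "distance to the
boundary" is otherwise ambiguous at the voxel level. Two metric modes:

* `physical` (default): axis steps weighted by `spacing_um`, distances in
  µm. With 0.21 µm Z steps against 0.05 µm XY pixels the anisotropy factor
  is 4.2, so this mode is the geometrically meaningful one.
* `isotropic`: unit steps, distances in voxels; provided for comparison
  and for isotropically sampled data.

Shells are equal-width distance bins computed **per nucleus**: with
`d_max` the nucleus's maximum distance and `nd = d/d_max ∈ (0, 1]`,

    layer ℓ = K + 1 − ⌈K · nd⌉,

half-open bins (lower-exclusive, upper-inclusive), so the distance-maximal
voxels land in layer 1 (nuclear centre) and boundary-adjacent voxels in
layer K. Per-nucleus normalization is what lets nuclei of different sizes
and heights contribute K comparable layers. Equal *width* (not equal
volume) is the deliberate reading of "equally spaced": the partition is a
set of concentric equidistant isosurfaces of the distance map. A nucleus
with non-positive or non-finite `d_max` raises a degenerate-object error.

Layers can be legitimately empty: layer K is unpopulated whenever
`d_max/K` falls below the smallest voxel step. Empty layers are reported
as missing (NaN mean, zero count), never imputed, and are excluded
pairwise from cross-nucleus statistics.

**Intensity statistics are computed on the raw image.** Smoothing is a
segmentation aid only; it would otherwise redistribute signal across
shells and flatten the very gradient under study.

## RO aggregation and statistics

With K = 24 and `ro_size = 4`, regions of interest RO-1 … RO-6 cover
layers 1–4 … 21–24. A nucleus's RO value is the voxel-count-weighted mean
of its layer means — identical to the plain mean over all voxels in those
layers — so the six RO values conserve the whole-nucleus mean. The
nucleus is the statistical unit: group means and SEMs (`sd/√n`, with
`sd = 0` by convention at n = 1) are taken across nuclei, and pooling
voxels across nuclei is exposed only as a diagnostic.

Two-group comparisons use the unpaired equal-variance (Student's)
two-sided t-test by default, Welch behind a flag, at α = 0.05. If both
samples are constant and equal the statistic is defined as t = 0, p = 1
(scipy returns NaN for 0/0); constant unequal samples give p = 0. A unit
with fewer than two non-missing nuclei in either group yields a NaN row
rather than aborting the comparison. No multiple-testing correction is
applied by default — per-RO tests are reported at face value — with Holm
step-down available via `holm=True`. Fold change between two ROs is the
ratio of their group means.

## Synthetic phantoms

The generator emulates super-resolution confocal stacks of NE-stained
nuclei; every phantom carries voxel-level ground truth populated *before*
noise, using the same distance transform and binning rule as the analysis,
so recovery can be scored exactly.

* **Geometry.** Ellipsoids at the reference anisotropic spacing,
  optionally perturbed by a low-order angular harmonic of the surface
  radius (`fold_amplitude`, relative to the ellipsoidal radius) to mimic
  nuclear folds and indentations. Nuclei must fit inside the grid and not
  overlap; border-touching blobs are modelled separately as distractors
  for exercising border clearing.
* **Radial profile.** Generating intensity as a function of true
  normalized depth: flat, linear, step, or a Gaussian band on a pedestal.
  The band default peaks at nd = 0.1 with width 0.3, producing a profile
  that rises progressively from the centre to a near-plateau over the
  outer layers — the shape envelope staining exhibits after optical blur —
  rather than an abrupt rim spike.
* **Puncta.** Point emitters at a configurable density per µm³ of nuclear
  volume, blurred by an anisotropic Gaussian PSF (σ = 0.17/0.06/0.06 µm,
  i.e. ~400 nm axial / ~140 nm lateral FWHM), clipped to the nucleus.
* **Noise.** Poisson on the scaled signal (`poisson_scale` photons per
  intensity unit) plus additive Gaussian read noise; both zero gives exact
  volumes for analytic tests.
* **Presets.** `mcf10a_like`: disc-shaped flat nucleus, semi-axes
  1.6 × 4.0 × 4.0 µm (Z, Y, X) on a 24 × 192 × 192 grid, regular outline,
  band profile 100 → 260. `mda231_like`: taller folded nucleus
  (2.4 × 3.6 × 3.4 µm, fold amplitude 0.15) with brighter, denser puncta
  on 32 × 176 × 176. Both jitter semi-axes by ±5% and overall staining
  brightness by a ~10% lognormal factor per nucleus, reflecting per-cell
  staining-efficiency variation; brightness scaling cancels in fold
  ratios. These nuclei are deliberately smaller than typical epithelial
  nuclei (~12–15 µm across) so that multi-phantom batches run in seconds
  per phantom on one CPU, while preserving the anisotropy ratio and the
  relation between layer thickness, voxel step and PSF width.
* **Reproducibility.** All randomness flows from one integer seed through
  numpy `SeedSequence` streams (one spawned stream per phantom in
  batches); identical config + seed gives bit-identical volumes.

## What the validation shows — and does not

The test suite and `scripts/acceptance.py` establish: exact agreement of
the distance transform with an O(n²) brute-force search (both metrics, to
1e-9); agreement of the Otsu threshold with an exhaustive per-split scan;
conservation and nesting of the shell partition and its exact match to
ground-truth layer labels; flatness of the profile on constant spheres;
border-clearing semantics and idempotence; recovery of the RO-6/RO-1 fold
within a few per mil and of the 24-layer profile shape (Spearman ρ ≈ 1.0)
through the full noisy pipeline; rotation equivariance of the shell
assignment under 90° rotations (layer means then agree to float summation
order, ~1e-15 relative); calibration of the null rejection rate near 5%;
and detection of a simulated peripheral-band suppression in RO-6 but not
RO-1 at n = 5 per group.

Phantoms idealize real data in known ways: no optical sectioning of the
whole volume (only puncta are PSF-blurred), no photobleaching or
depth-dependent attenuation, no touching nuclei (no watershed splitting is
attempted), single channel, and smooth parametric nuclear shapes. Passing
these tests therefore demonstrates correctness of the *measurement
machinery* under realistic noise and anisotropy — not that segmentation
will be as accurate on arbitrary real micrographs, where contrast,
clutter and shape irregularity are worse.

## Degenerate inputs and tie-breaks (summary)

Constant image → Otsu raises; nucleus with `d_max ≤ 0` → shell assignment
raises; empty layers → NaN, excluded pairwise; equal constant groups →
t = 0, p = 1; group with < 2 nuclei → insufficient-replicates error
(whole comparison), NaN row (single unit); volume-filter and label ties →
deterministic ordering by decreasing volume then original label; Otsu
variance ties → first maximum, midpoint mapping.
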