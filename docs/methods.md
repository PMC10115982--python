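# Methods

This note records the models, conventions and numerical choices behind
`oareval`, in the spirit of a statistics package's methods appendix: what
is computed, under which assumptions, and where the edges are.

## Geometry substrate

All computation happens on world-aligned anisotropic voxel grids in
patient-space millimetres.  Arrays are indexed `[i, j, k]` with
`world = origin + index * spacing`; the third axis is the axial (slicing)
axis; `origin` is the **center** of voxel `(0, 0, 0)`.  The default phantom
raster, 1.27 × 1.27 × 2 mm, mirrors a typical head-and-neck planning CT.
Oblique acquisitions, image intensities and DICOM-RT writing are out of
scope.

**Rasterization.**  Planar DICOM-RT contours become masks by the even-odd
voxel-center rule: a voxel is foreground iff its center lies inside an odd
number of polygons on its slice.  The scanline test is half-open
(an edge counts for `y ∈ [y_min, y_max)`, a crossing requires the center
strictly left of the intercept), so centers lying exactly on shared edges
resolve deterministically toward the lower coordinate.  Vendors differ in
their boundary conventions; this rule is this package's declared
convention, and the test suite pins it against a brute-force
point-in-polygon oracle.

**Boundaries.**  One extractor feeds every surface metric but each metric
uses the representation of its originating definition: surface Dice uses
boundary *faces* (area-weighted, centroids on half-grid positions), HD95
and the contour Dice use boundary *voxel centers*, and APL uses slice-wise
2D boundary pixels of the reference with 3D distances to the candidate
surface.  Face areas are products of the two in-plane spacings, so the
total boundary area of a rasterized box equals its analytic surface area
exactly.

**Distances.**  Nearest-neighbour distances between boundary point sets
are computed with a KD-tree in world mm.  KD-tree queries return exactly
the all-pairs minima, so the implementation agrees with the brute-force
oracle to floating precision (the suite asserts 1e-9 over hundreds of
random mask pairs); a voxel-grid distance transform is *not* used for the
metrics because face centroids sit between voxel centers, where a lattice
EDT is not exact.  Anisotropic spacing is honoured everywhere; index-space
distances are never used.

## Metric conventions

- **HD95** pools the two directed distances by taking their maximum, with
  percentiles computed by linear interpolation between order statistics —
  the most common convention where the literature leaves pooling
  unspecified.
- **APL** converts boundary-pixel counts to millimetres with the mean
  in-plane pitch (exact for isotropic in-plane grids).  It is deliberately
  asymmetric (reference-anchored): an empty candidate leaves the full
  reference path length.
- **CDC** is the Dice overlap of tolerance bands around the two boundary
  voxel-center sets; its cited lineage admits variants, and the band-Dice
  form used here is declared explicitly.
- **Specificity** depends on the grid extent through its true-negative
  count; it is computed over the shared reference grid and should be read
  as extent-dependent (clinical tables routinely show 1.0 throughout).
- Metrics on empty inputs raise typed errors rather than returning
  conventional values, because the study design this pipeline serves
  excludes structures not present in all arms *before* comparison.
  Undefined confusion quotients are NaN markers, never zeros.
- Batch comparison resamples the candidate to the reference grid (nearest
  neighbour) when grids differ, logs it, and emits the full battery —
  SDSC at τ ∈ {1, 1.5, 2, 3} mm, APL at {1, 2, 3, 5} mm, CDC at 1 mm —
  as a long-format table.

## Dosimetry

The dose grid is treated as a smooth field: when structure and dose rasters
differ, dose is trilinearly interpolated to structure voxel centers
(nearest-neighbour sampling would alias the DVH tails).  DVHs are exact
voxel samples — every foreground voxel contributes its volume at its dose —
with no histogram binning, so total DVH volume equals region volume
bit-for-bit.  D0.03cc interpolates linearly on the sorted dose-vs-
cumulative-volume profile; queries within the hottest voxel return the
hottest dose; `Dxcc` beyond the region volume is an error.

PTVs are built by isotropic *Euclidean* expansion (exact anisotropic EDT on
voxel centers) of the CTV, cropped to the body mask; the 3 mm default is
the margin conventional in this workflow.  An OAR's evaluation region is
the OAR minus the union of PTVs; when less than 0.1 cc remains the
structure is excluded from dosimetric analysis, and exclusions propagate
into the per-arm delta tables as logged skips rather than zeros.

The plan-quality template is a required configuration input: institutional
scoring templates are not portable, so the package ships an explicitly
illustrative default (serial organs scored on D0.03cc, parallel organs on
Dmean, one point each, 10 Gy linear ramp) and reads clinical templates from
YAML.  Objective scoring is binary by default with an optional linear
partial-credit ramp between a full-credit and a zero-credit threshold; the
NPQM normalizes achieved by attainable points, with objectives whose
structures are absent or excluded removed from both numerator and
denominator.  `|ΔNPQM|` uses whichever scoring the template configures;
binary is the default.

## Study statistics

Confidence intervals are `mean ± t(0.975, n−1)·s/√n`.  Paired comparisons
are two-sided paired t-tests at α = 0.05 with **no multiple-testing
correction** — matching the per-metric convention of the study design this
mirrors — but every report carries the number of tests performed.
Degenerate difference vectors are flagged, not given fabricated p-values:
identically-zero differences report p = 1 ("no-difference"); zero-variance
nonzero differences are reported as significant with a "zero-variance"
flag.  Pooled comparisons pair at the case × structure level; per-OAR
comparisons pair at the case level; the pairing unit is stated here because
published reports rarely state theirs.

Time savings are per-case relative reductions of total contouring time,
`100·(T_std − T_exp)/T_std`, summarized by mean and 95% CI, with a
one-sided one-sample t-test against a 30% margin at α = 0.025.  Cases with
zero standard time are excluded with a warning; negative savings are
legitimate values.  The a-priori power of that test uses the noncentral-t
distribution with noncentrality `(μ − margin)/(σ/√n)`.  Under the planning
assumptions often quoted for such studies (alternative 50%, SD 20%,
n = 20) this form gives 98.9% power; published planning numbers computed
under other test forms or variance assumptions will differ, and the
package reports what its own test form implies.

Presence contingency counts delivery of usable geometry: a structure
delivered with zero foreground voxels counts as *not present* for the
contingency (delivery accounting) but raises errors in geometry (metric
preconditions) — absence and emptiness are distinct states in the data
model.

## Synthetic cohort

The generator emulates the *statistical shape* of a contour-evaluation
study, not anatomy: a 42-name standardized OAR roster laid out as geometric
primitives (spheres, ellipsoids, tubes, boxes, rings) on a lattice, with
analytic volumes and centroids carried alongside every mask; CTVs with
derived PTVs; uniform, linear-ramp, or Gaussian-blob dose fields whose
Dmean/D0.03cc are analytically known for the first two; lognormal timing
records anchored on a configured true mean savings (default 76%, echoing a
workflow where ~2.3 h of manual initial contouring and ~1.1 h of revision
collapse to ~0.7 h of revision); and Bernoulli structure absence.  The
default cohort is 19 analyzable cases with a small-perturbation arm, a
slightly larger revised arm and a visibly larger manual arm.

**Perturbation model.**  Arms derive from the gold standard by operating on
a signed distance field: translation shifts it, dilation/erosion offsets
its zero level, and boundary noise adds a smooth random displacement
(white noise Gaussian-filtered at a configurable correlation length,
scaled to a target RMS amplitude), followed by slice dropout and absence
sampling.  Smooth level-set noise makes surface metrics degrade gracefully
and monotonically with amplitude, unlike i.i.d. voxel flips.  Every applied
parameter is recorded in a ground-truth table for recovery testing.

The signed distance is estimated with subvoxel accuracy: the binary
indicator is trilinearly refined 3× and thresholded at 0.5 — placing the
surface midway between differing neighbours, a mean-zero estimate of the
rasterized smooth surface — before a fine-lattice EDT.  Validated against
the true signed distance of a rasterized sphere, this estimator's mean bias
is ~0.04 mm versus ~0.33 mm for a plain center-to-center EDT.  Known
residual: level offsets that are even multiples of the fine step
(spacing/3) can land the offset surface exactly on fine-lattice centers,
inflating thin-shell volumes by several percent (e.g. a 2 mm offset on a
1 mm grid); offsets at the workflow's canonical margins (1 mm, 3 mm on a
1 mm grid) recover closed-form shell volumes to better than 1%.  Voxel-
multiple translations are exact (centroid shifts recover to 1e-9 mm).

**What passing tests do and do not show.**  The phantoms have piecewise-
smooth, convex-ish shapes, no inter-structure contact constraints, no
image-derived segmentation errors, and timing draws are independent across
cases.  Passing the recovery and calibration suites therefore demonstrates
that the *measurement pipeline* is unbiased and correctly calibrated on
known ground truth — it says nothing about the accuracy of any particular
segmentation model on real anatomy.

## Problem sizes

The test and acceptance runs use deliberately small instances: oracle
equivalence on 200 random pairs within 20³ grids; analytic recovery on
10 mm spheres over ~44³ voxels; calibration with 1000 timing replicates at
n = 19 and an arm-ordering cohort of 19 cases × 6 structures on a
48 × 48 × 24 grid.  These sizes were chosen so the full suite documents the
pipeline's properties in under a minute of compute while leaving every
assertion at full strength; all generators scale to CT-sized grids by
changing the spec.

## Known limitations

- Axis-aligned geometry only; tilted gantry/neck acquisitions must be
  resampled upstream.
- Surface metrics use raster boundaries, not marching-cubes meshes; values
  on very coarse grids carry the corresponding quantization.
- The default plan-quality template is illustrative; clinical conclusions
  require an institutional template.
- The specificity of voxel confusion is grid-extent-dependent by
  construction.
- Sub-voxel dilation margins in the synthetic perturbation carry the
  fine-lattice phase artifact described above.
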