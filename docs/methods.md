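# Methods

## Overview

`vesselcad` turns co-registered binary segmentation masks — one pancreatic
tumor, up to five named peripancreatic vessels (CA, CHA, SMA, PV, SMV) — into
per-vessel geometric features and logistic risk estimates of vascular
involvement. The pipeline is: isotropic resampling → vessel skeletonization
and branch decomposition → per-centerline radius and tumor-distance profiles
→ the 14 anatomical features plus tumor shape features → risk scores and
per-vessel logistic models → evaluation statistics.

All geometric computation assumes an isotropic grid; masks are resampled to
cubic voxels (default 1.0 mm) with nearest-neighbour interpolation on load,
so thresholds expressed in voxels coincide with millimetres. Labels are
categorical and are never interpolated linearly. Volumes are held in
(z, y, x) axis order.

## Vessel geometry

**Skeletonization.** Binary masks are thinned to a one-voxel-wide medial
skeleton (topological 3D thinning, 26-connected foreground / 6-connected
background). The skeleton voxels form a graph whose nodes are endpoints
(degree 1) and junctions (degree ≥ 3); maximal degree-2 chains between nodes
are the edges. Terminal spurs shorter than `max(5, 0.5 × local radius)`
voxels — discretization noise on digital tubes — are pruned iteratively; an
isolated edge (both ends free) is never pruned, so a clean tube always keeps
its single centerline. A pure cycle is anchored at its lexicographically
smallest voxel. Edge paths are ordered from the endpoint with the lower
lexicographic index, making the feature sequences reproducible.

**Radius.** The radius at a skeleton voxel is the Euclidean distance
transform of the vessel mask evaluated there (inscribed-sphere radius). No
cross-sections are fitted; on digital cylinders of radius 3–6 voxels this
recovers the radius within half a voxel along the central 80% of the path.
Near flat tube ends the distance transform is bounded by the end face rather
than the wall; tests therefore evaluate radius claims on the central portion.

**Branches.** Every vessel voxel is assigned to the skeleton edge containing
its nearest skeleton voxel, so branch masks partition the vessel exactly. An
optional manual label volume overrides the automatic assignment (the clinical
workflow this emulates split vessels manually). Each surface voxel is mapped
to its nearest skeleton voxel (exact ties resolved to the lexicographically
lowest candidate); this map underlies the contact-length feature.

## The 14 anatomical features

For vessels with several branches, the sequence features are computed on the
tumor-proximal branch — the edge whose minimum tumor distance is smallest
(ties by branch index) — matching the single-edge definition of the
sequences; the encasement angle and contact features use the whole vessel.

- `R_min/R_max/R_mean/R_range/R_std`: statistics of the per-voxel radius
  sequence. All standard deviations in the package use the population
  (divisor-n) convention.
- `theta_encase`: for every 2D slice perpendicular to each grid axis, the
  vessel boundary pixels (4-connectivity) form the circumference C; those
  within `contact_tau` (default 3 voxels) 3D Euclidean distance of the tumor
  form the contact arc L. The feature is max L/C over slices, reported as a
  fraction and in degrees (360 × fraction). Two robustness guards operate at
  grid resolution: slices with fewer than 8 boundary pixels are skipped, and
  so are slices with no interior pixels — a plane grazing a vessel
  tangentially produces a ribbon of "boundary" with no cross-sectional
  content, whose L/C is meaningless. The 3-voxel contact tolerance smears a
  sharp contact edge by roughly asin(tau/r) of arc on a vessel of radius r;
  at clinical vessel calibers this is a few degrees to a few tens of degrees
  and is the dominant error term in the validation phantoms.
- `D_*` and `D_ratio`: D_n = radius × tumor distance per skeleton voxel.
  The near-tumor region of interest is the set of skeleton voxels with tumor
  distance ≤ `roi_rho` (default 10 voxels; configurable — the band width is a
  design choice, recorded in run metadata). `D_ratio` = mean(D_n outside) /
  mean(D_n inside); it is undefined (missing, not zero) when either group is
  empty or the inside mean is zero, and is imputed with the neutral ratio 1.0
  only at modeling time, never in the feature table.
- `C_area`: vessel surface voxels within `contact_tau` of the tumor.
  `C_length`: distinct skeleton voxels mapped (via the surface-to-skeleton
  map) from those contact voxels. The count is restricted to contact voxels
  so that the feature measures the length of centerline in contact, which is
  its clinical reading; counting all mapped skeleton voxels would simply
  return the skeleton length.

## Tumor morphology

Volume is voxel count × voxel volume. Surface area comes from a marching-
cubes iso-surface extracted at level 0.5 after supersampling the mask 2× and
smoothing with a Gaussian of σ = 1.2 fine voxels: a raw binary mesh
overstates a digital sphere's area by ~8–10% (staircase effect), while
smoothing at the original scale shrinks small convex bodies by ~σ²/r; at the
doubled resolution both biases stay near 1% across radii 6–14 voxels.
Structures too small to cross the iso-level after smoothing fall back to the
raw binary mesh. Sphericity and compactness are computed exactly as
π^⅓·(6V)^⅔/A and A/V — compactness is deliberately the dimensioned surface-
to-volume ratio, not a dimensionless variant, for fidelity to the risk-score
definitions.

Axis lengths are 4·√λ of the physical-coordinate covariance eigenvalues
(fitted-ellipsoid convention). Flatness is major/medium axis length, a ratio
≥ 1 that grows as the tumor flattens; note this is the reciprocal orientation
of the minor/major "flatness" some radiomics tools report. The tumor-shape
score was fitted against this ≥ 1 convention and its coefficients are only
valid with it. The maximum 3D diameter is the exact largest pairwise distance
between iso-surface vertices, evaluated on the convex hull for speed (hull
extreme points contain the diameter endpoints).

A first-order intensity summary (mean, median, extrema, population variance,
skewness, Pearson kurtosis, energy, histogram entropy in bits and uniformity,
default 64 bins) stands in for high-throughput texture features; the feature
table reserves `fo_`-prefixed columns so external extractors can be merged.

## Risk scores and models

`RS_deform` (deformation: R_std, D_max, D_std, D_ratio; β₀ = −1.098,
β = 0.663, −1.086, −0.745, 2.395) operates on standardized inputs: raw
voxel-squared products would be orders of magnitude beyond the scale on which
these coefficients are plausible. The model JSON schema carries an optional
per-feature (mean, sd) reference; the built-in ships without one, and when a
feature table is scored without a reference, the table's own mean and
population sd are used and recorded. `RS_tumor` (shape: T_flat, T_sphere;
β₀ = 1.526, β = 7.093, −9.826) operates on raw scales, where its
coefficients are plausible (both features are O(1)).

Per-vessel involvement models are logistic regressions on
{θ_encase (degrees), RS_tumor} for arteries, plus RS_deform for veins — the
composition is asserted at assembly. θ_encase enters in degrees: per-unit
odds ratios near 1.01–1.02 are only meaningful per degree. RS_tumor is always
retained regardless of its Wald p-value. Feature selection utilities (Fisher
score ranking, univariable Wald screening at p < 0.05, defaults of four
deformation features and two shape features) are provided and configurable.

Fitting is maximum likelihood via iteratively reweighted least squares
(deviance tolerance 1e-8, 100 iterations max; statsmodels GLM/Binomial), with
Wald standard errors from the inverse observed information and OR confidence
intervals exp(β ± 1.96·SE). Any |β| > 15 triggers a non-fatal
complete-separation warning.

**Evaluation.** AUC is the Mann–Whitney pair statistic (ties count ½),
computed from midranks; its variance and the paired AUC test use the DeLong
placement-value construction. The operating cutoff defaults to the Youden
maximizer, with ties resolved toward the lower threshold (favouring
sensitivity). Proportions carry exact Clopper–Pearson 95% intervals. McNemar
on paired correctness uses the exact binomial test when b + c < 25 and the
continuity-corrected χ² otherwise. Hosmer–Lemeshow groups by predicted-risk
deciles with df = groups − 2, the convention for in-sample fitted
probabilities; for externally specified probabilities the caller can pass
df = groups (the statistic is then χ²(g) under the null, and the default df
would reject a calibrated external model ~11% of the time at α = 0.05).
Decision-curve net benefit is TP/n − (FP/n)·t/(1−t) against treat-all and
treat-none references.

**Nomogram.** Each feature's points at value v are
100·|β|·|v − v_ref| / max_g(|β_g|·range_g), with v_ref the range endpoint
minimizing the linear predictor, so the most influential feature spans
exactly 100 points; total points map back to probability through the
recovered linear predictor (round-trip exact to float precision).

## Phantoms: what they emulate and what they do not

Phantoms provide known geometric ground truth on a default 96³ grid at 1 mm
(the full suite runs in minutes on one CPU):

- digital tubes — straight (flat end caps, so voxel counts match πr²L),
  curved, or Y-shaped, radius constant or profiled, optional stenosis
  (radius multiplier within the tumor-proximal axial segment);
- ellipsoidal tumors, and wrap tumors: 2-voxel-thick shell sectors of
  angular width ψ at a 1-voxel gap from the vessel surface, so contact
  within the 3-voxel tolerance is guaranteed and the true encasement
  fraction ψ/360 is known by construction. Encasement validation uses a
  24-voxel-caliber vessel: the contact tolerance smears the measured sector
  edge by ≈ asin(3/r) per side, which at r = 24 keeps the total bias under
  ~14°, within the ±18° validation band. The axial span of the shell is kept
  well below the tube length so longitudinal slices cannot dominate the
  encasement maximum;
- tabular simulation: features drawn i.i.d. (T_flat ~ U(1.0, 1.6),
  T_sphere ~ U(0.4, 1.0), standard normal for standardized deformation
  features), outcomes Bernoulli on the model's logistic law. Parameter
  recovery experiments use n = 200,000, where all published coefficients are
  re-estimated within ±5%.

Every truth record re-renders its mask bit-for-bit, and a single seed fans
out to per-structure substreams, so adding a vessel never perturbs the tumor
draw.

What passing these tests does **not** show: phantoms are ideal geometry —
no segmentation error, no registration residue between contrast phases, no
anatomical curvature of real peripancreatic vessels, no CT intensity or
texture realism, and the tabular simulations assume the logistic generative
law is exactly right. Performance on real cohorts is a clinical-validation
question the phantom suite cannot answer.

## Degenerate inputs and tie-breaks

- Empty masks raise; an absent vessel yields a flagged record with missing
  features, never zeros.
- A solid ball (no tubular structure) thins to a handful of voxels with at
  most one edge rather than crashing.
- A coplanar tumor raises a degenerate-shape error from the axis
  decomposition.
- Exact ties in the surface-to-skeleton map go to the lexicographically
  lowest skeleton voxel; Youden ties to the lower threshold; features with
  equal Fisher scores order alphabetically.

## Known limitations

- The radius is an inscribed-sphere radius; for strongly non-circular lumina
  it underestimates the effective caliber. No sub-voxel centerline or spline
  smoothing is attempted.
- The surface-to-skeleton distance bound (≤ local radius + 1) holds along
  tubular bodies but not at cap rims, where thinning retracts the centerline
  endpoint inside the cap by a voxel or two.
- The encasement angle is slice-based, not a true 3D circumferential
  measure; vessels running oblique to all three axes are measured on
  foreshortened cross-sections.
- Only a first-order intensity summary is provided; the full texture
  catalogs of high-throughput radiomics tools are out of scope by design.
- The per-vessel model architecture is reproduced, but coefficients of
  clinical models must be fitted on real labeled data.
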