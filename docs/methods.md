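# Methods

This note records the models, conventions and numerical choices behind
each stage, the design decisions that were genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## Coordinate frame and distance scoring

All artifacts share one frame: 0-based pixel indices, x along columns,
y along rows, y increasing downward; the pixel at array position `[i, j]`
has center `(x, y) = (j, i)`. Spot centers may be fractional.

A spot's raw distance is the minimum Euclidean distance from its center to
the center of any positive region pixel (computed with a k-d tree, which
is exact for this metric); a spot whose own pixel is positive scores 0.
SpatialTime is the min-max rescaling of raw distances over the analyzed
spot set, so the axis always spans exactly [0, 1] and preserves rank
order. If every raw distance is equal, the axis degenerates; we map
everything to 0 with a warning rather than fail, so flat fixtures run end
to end.

Two interior conventions are provided, because the published figure style
draws the region border at a positive SpatialTime with profiles continuing
inside it:

* **unsigned** (default): interior spots all score raw 0;
* **signed** (`signed=True`, used by the simulated scene): interior spots
  score minus the distance to the region's complement, so after scaling
  the border sits at `b = −min(d) / (max(d) − min(d)) > 0`.

Distances are straight-line and in pixel units; no geodesic or physical
unit conversion is attempted.

## Region inputs

Regions arrive as single-channel label images (positive = nonzero) or as
GeoJSON polygons rasterized onto the frame: a pixel is positive iff its
center lies inside **or on the boundary of** the polygon (the boundary
rule is stated so oracles are unambiguous). Degenerate polygons (< 3
distinct vertices, self-intersecting, zero area) and empty masks are
rejected up front — every downstream distance is undefined without at
least one positive pixel.

## Spot classification and expression summaries

Prediction scores (one per cell type per spot, in [0, 1], produced
upstream by label transfer) are thresholded at 0.6; a tie counts as
positive (the published cutoff does not state strictness; inclusive is the
default and a flag flips it). Spots may be positive for several cell types
or none — no hard assignment is forced.

Counts are normalized by a standard library-size + log1p recipe: each
spot's counts are scaled to the median spot total and transformed with
log(1 + x). This is an explicit stand-in for whatever normalization the
upstream single-cell toolchain applies; group summaries are therefore
comparable in rank and pattern, not in absolute value. Spots with zero
total stay at 0 with a warning. Dot-plot summaries report, per group and
gene, the fraction of spots with any signal (count > 0) and the mean
normalized expression.

## Profiles along SpatialTime

* **Binning**: left-closed intervals of width 0.01 (the last bin also
  closed on the right, so SpatialTime 1 is counted); per bin n, mean, and
  SE = sd/√n with the n−1 denominator. A single-observation bin has
  undefined SE (NaN), and empty bins have undefined mean; both are
  excluded from downstream smoothing.
* **Smoothing**: a centered moving average over the *sequence of
  non-empty bins* (default window 5), shrinking to the available
  one-sided neighborhood at the ends. Window 1 is the identity; constants
  and interior linear trends are preserved; the smoothed curve never
  leaves the [min, max] envelope of the raw bin means. The published
  analysis says only "a smoothed line"; a moving average was chosen for
  exact reproducibility over loess/splines.
* **Trend**: Spearman correlation computed on the raw spot-level
  (value, SpatialTime) pairs, not on bin means, so the p-value reflects
  the true number of observations rather than the bin count.
* **Direction classification**: a profile is *peaked* when the smoothed
  maximum is interior, exceeds both end values by ≥ 0.1 of the smoothed
  range (prominence, configurable), **and** the rise before the peak and
  the fall after it are each significant spot-level Spearman trends at α.
  The flank requirement exists because prominence alone proved fragile:
  interior SpatialTime bins of a compact region hold very few spots (the
  area of an annulus shrinks toward the region center), and their means
  wobble by about one prominence unit, occasionally promoting a monotone
  profile to "peaked". Requiring both flanks to trend significantly is the
  same trend-significance logic applied piecewise and makes the call
  robust without touching the prominence constant. Otherwise the profile
  is increasing/decreasing per a significant overall trend, else flat.
* **Crossings**: each smoothed profile is min-max scaled to [0, 1]
  (profiles on different natural scales — a prediction score vs an
  expression level — are compared in relative terms, as in the published
  figure style), and crossings are sign changes of the difference between
  consecutive bins non-empty in both profiles, located by linear
  interpolation between bin centers. Tangential touches are not crossings;
  identical profiles yield a warning and no crossings.

## Fibril anisotropy

Per ROI, the image is smoothed with a 3×3 uniform prefilter and
differentiated by central differences; each pixel whose gradient magnitude
exceeds 1e-6 of the image intensity range contributes the unit tangent
perpendicular to its gradient, and the tensor is the *unweighted* average
of tangent outer products — the FibrilTool construction. AU = λ₁ − λ₂ of
the trace-1 tensor; orientation is the leading eigenvector's angle in
(−90°, 90°], NaN for an isotropic tensor. Derivatives are evaluated with a
3-pixel context margin around the ROI (pixels whose stencil would run off
the image are excluded) because one-sided differences at a crop boundary
inject a small isotropic artifact (~2% AU on aligned textures).

The literature describing this readout is ambiguous between the
gradient-tangent tensor and an eigen-analysis of the Hessian; both are
implemented (`method="gradient"` default, `method="hessian"` for
comparison, using the smaller-|eigenvalue| Hessian direction as the ridge
axis). Results in this package are from the gradient form unless stated.

Properties worth knowing: AU is invariant to multiplying intensities by a
positive constant (tangents are per-pixel normalized); because averaging
is unweighted over all usable pixels, any diffuse background texture
(noise) above the tiny gradient epsilon dilutes AU toward 0 — a real
property of this estimator, not a bug. Images whose texture is
fiber-dominated are read faithfully; images with large noisy background
under-read.

An image-level AU is the unweighted mean over its ROIs (1–8 accepted,
3–4 typical; overlap warns but does not fail).

## Synthetic data

The generator exists so every stage can be validated against analytic
ground truth; its defaults define the benchmark scene.

**Scene geometry.** A 45×45 spot lattice at 10-pixel pitch (2025 spots,
441×441-pixel frame) with a radius-60 disk as the marked region at the
frame center. The true SpatialTime of a spot is computed from the exact
disk geometry (center distance minus radius, signed, min-max scaled over
the spot set), giving the border position `b ≈ 0.193` analytically.

**Gradient shapes.** Mean profiles along SpatialTime are
`baseline + amplitude·exp(−st/width)` (decreasing),
`baseline + amplitude·exp(−(st − peak)²/2width²)` (peaked), or constant
(flat); amplitude 0 forces a constant.

**Counts.** Negative binomial with mean μ from the gradient and variance
μ + μ²/θ — the standard overdispersed model for sequencing counts (the
source analysis does not model counts; this choice is a documented
stand-in). Default scene genes: a decreasing Thbs1-like marker
(amplitude 60, baseline 0.5, width 0.2, θ = 20), a peaked Thbs2-like
marker (peak 0.45, width 0.12, same amplitude/θ) and 30 flat background
genes (baseline 8, θ = 10) so library sizes are realistic and
normalization has something to normalize. The markers are deliberately
strong, well-expressed genes: localizing a peak to ±0.05 on a 0.01-binned
axis requires the bin-level signal-to-noise that strong markers provide;
weak markers make the peak location statistically unidentifiable at this
spot count, which is a property of the method, not of the implementation.

**Prediction scores.** Noiseless scores are gradient profiles of the true
SpatialTime, plus Gaussian noise (sd 0.05 by default) clipped to [0, 1]
(clipping bias is accepted — profiles keep ≥ 3 sd clear of the bounds so
it is negligible). The macrophage field is inside-high (decreasing,
baseline 0.05, amplitude 0.85); the MPC field peaks beyond the border
(peak 0.55, width 0.25). The macrophage decay width is *solved* (by root
finding) so that the two min-max-scaled noiseless profiles cross exactly
at the border b — encoding the biological claim the scene emulates: the
macrophage/MPC handover happens at the anlagen border.

**Fibril images.** Fiber orientations follow a wrapped normal on the
half-circle with concentration = 1/σ² (0 = uniform, ∞ = perfectly
aligned); the ground-truth anisotropy is the nematic order parameter
|⟨e^{2iθ}⟩| of the actually sampled angles, which is exactly the AU an
ideal tensor estimator would report for equally weighted fibers. The
renderer draws each fiber as a full-frame chord with a Gaussian
cross-section (σ = 1.5 px) and composes fibers by per-pixel maximum
(occlusion, as in a projection image), 18 fibers on 384×384 by default.
These choices are what make the measurement faithful to the ground truth:
additive blending mixes gradients where fibers cross (biasing AU down),
thin anti-aliased polylines carry staircase gradients, and interior
segment endpoints add radial blobs — each was observed to cost 0.1–0.3 AU
on aligned scenes. With the occlusion renderer the measured AU tracks the
sampled-angle order parameter within ≈ 0.06 across concentrations 0–128.
Background noise defaults to 0 for the reason given above (unweighted
averaging); a noise_sd parameter exists for robustness studies.

**Determinism.** Every generator derives per-gene / per-cell-type
substreams from one integer seed via `SeedSequence([seed, crc32(name)])`,
so identical calls are byte-identical and adding a gene never perturbs
the others.

## Statistical test selection

Shapiro–Wilk per group at α (constant groups are treated as non-normal,
since the statistic is undefined and the rank test tolerates ties); any
rejection → two-sided Mann–Whitney U; otherwise Levene (median-centered,
the robust Brown–Forsythe form) at α; rejection → Welch's t, else
Student's t. All tests two-sided; the full trail of intermediate p-values
and decisions is stored on the result. Which normality/variance tests the
source analysis used is unstated; these are standard robust defaults. No
multiple-testing correction is applied by default; a Bonferroni helper
(min(1, m·p)) is available. Under the null the selected procedure holds
its nominal 5% size (the acceptance script measures ≈ 0.05 over 2000
replicates at n = 20 per group).

## Pipeline and problem sizes

One config drives simulate → distance scoring → classification →
dot-plot → profiles/features/crossings → anisotropy cohorts → group test.
All randomness flows from the single top-level seed; the JSON summary
contains a content hash of the scientific parameters and no timestamps or
absolute paths, so identical seeds give byte-identical summaries. The
benchmark sizes — 2025 spots, 32 genes, six 384² images, 50 oracle
instances, 2000 null replicates — keep a full validation run in the tens
of seconds on one CPU while leaving every estimate comfortably inside its
stated tolerance.

## Limitations

* The synthetic scene is a disk in a square lattice with isotropic,
  monotone-or-unimodal gradients and independent NB noise per gene. Real
  Visium data have hexagonal packing, segmentation-imperfect region
  annotations, spatially correlated technical noise, zero inflation and
  gene-gene correlation; passing the benchmark shows the *procedures* are
  implemented correctly, not that the biological conclusions of any real
  dataset would be recovered at these tolerances.
* Prediction scores are consumed, never computed: label-transfer quality
  is upstream and out of scope.
* The normalization is a stand-in; absolute expression values are not
  comparable to any specific toolchain's output.
* Distances are straight-line; tissue geodesics are not modeled.
* The anisotropy readout shares FibrilTool's known sensitivities:
  unweighted averaging over background-texture pixels dilutes AU, and the
  score saturates differently for very thick or strongly overlapping
  fiber bundles than for the rendered benchmark images.
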