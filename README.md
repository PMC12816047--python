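# spatialtime

Region-referenced gradient analysis for array-based spatial
transcriptomics, plus the two companion quantifications that usually
travel with it in tissue-injury studies: collagen-fiber anisotropy from
grayscale (e.g. second-harmonic-generation) images, and an automatic
parametric/non-parametric test selector for small group comparisons.

The motivating setting is heterotopic ossification (HO) — ectopic bone
that forms in soft tissue after trauma. Spatial spots are referenced to a
manually marked **anlagen** (the early bone primordium): every spot gets a
**SpatialTime** coordinate, and expression or cell-type prediction scores
are profiled along that axis to reveal, for example, a macrophage
population concentrated inside the anlagen and a mesenchymal-progenitor
(MPC) population peaking at its perimeter, with their marker genes
(*Thbs1*, *Thbs2*) following the same inverse pattern.

## The core quantities

**SpatialTime.** For spot *s* with center *p(s)* and marked region *R*
(a set of positive pixels),

    d(s)  = min_{q in R} || p(s) − q ||          (0 inside the region)
    ST(s) = (d(s) − min_t d(t)) / (max_t d(t) − min_t d(t))  in [0, 1]

An optional signed convention replaces the interior 0 with the negative
distance to the region's complement, so the axis resolves structure inside
the border as well (the region border then sits at a positive SpatialTime
*b*).

**Profiles.** Values are binned at 0.01 SpatialTime intervals (100 bins);
each bin reports n, mean and standard error (sd/√n, n−1 denominator), with
a centered moving average over non-empty bins as the smoothed curve.
Profiles are classified as increasing / decreasing / peaked / flat from
the spot-level Spearman trend and the prominence of an interior smoothed
peak, and crossings between two min-max-scaled profiles are located by
linear interpolation.

**Spot classification.** A spot is cell-type positive when its label-transfer
prediction score ≥ 0.6 (scores are inputs, produced upstream). Dot-plot
summaries report, per group and gene, the fraction of spots expressing and
the mean log-normalized expression.

**Anisotropy (AU).** For each ROI, every pixel with usable intensity
gradient contributes the unit tangent **t** (perpendicular to the
gradient); the nematic tensor `T = <t tᵀ>` has trace 1 and

    AU = λ₁ − λ₂   in [0, 1],   orientation = angle of the leading eigenvector

0 is isotropic, 1 perfectly aligned — the FibrilTool-style readout used to
compare organized vs disorganized collagen matrices.

**Statistics.** Two-group comparisons at α = 0.05 run Shapiro–Wilk on each
group; any rejection routes to a two-sided Mann–Whitney U, otherwise
Levene's test decides between Student's and Welch's t. The decision trail
is recorded in the result. One-way ANOVA covers multi-group designs.

A synthetic-data module generates complete study-like inputs — spot
lattice, disk-shaped anlagen, inside-high/perimeter-peaked score fields,
negative-binomial count gradients, fibril images with known orientation
concentration — with analytic ground truth for every downstream stage.

## Worked example

```python
from spatialtime import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(out_dir="demo", seed=1))
print(summary["profiles"]["Thbs1"]["direction"],
      round(summary["profiles"]["Thbs1"]["trend_rho"], 3))
print(summary["profiles"]["Thbs2"]["direction"],
      summary["profiles"]["Thbs2"]["peak_spatialtime"])
print([round(c, 3) for c in summary["crossings"]["macrophage_vs_mpc"]],
      round(summary["ground_truth"]["border_spatialtime"], 3))
```

prints

```
decreasing -0.805
peaked 0.455
[0.211] 0.193
```

i.e. on the default simulated scene the Thbs1-like gene falls steadily
with distance from the anlagen (Spearman ρ = −0.80), the Thbs2-like gene
peaks at SpatialTime 0.455 (ground truth 0.45), and the macrophage/MPC
score profiles cross once at 0.211, next to the true region border at
0.193. The run also writes per-stage CSVs (`spatialtime.csv`,
`labels.csv`, `dotplot.csv`, `profile_*.csv`) and a deterministic
`summary.json` into `demo/`, including an anisotropy comparison of an
aligned vs a disorganized fibril-image cohort (mean AU ≈ 0.86 vs 0.33,
Student's t p ≈ 3e-4).

The same stages are available from the shell:

```
spatialtime simulate --out-dir scene --seed 1
spatialtime score --spots scene/spots.csv --counts scene/counts.mtx \
    --genes scene/genes.txt --region scene/region_mask.png -o st.csv
spatialtime classify --scores scene/scores.csv -o labels.csv
spatialtime anisotropy --image img.tif --rois rois.csv -o au.csv
spatialtime compare groupA.csv groupB.csv
spatialtime run --config scene.yaml
```

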