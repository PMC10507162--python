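# Methods

`mitoglia` quantifies the 3D mitochondrial network of single microglia:
how connected it is (median organelle volume, organelle count, mean
sphericity, largest organelle), how much of the cell it occupies (% of cell
volume, and the same for CD68⁺ vesicles), and where it sits (distance of
each organelle from the soma, the perinuclear volume fraction, a binned
radial profile).  Cell morphology enters through Sholl analysis of filament
tracings, and the per-cell metrics are combined into a six-feature PCA
profile.  A gated statistics layer compares groups, and a ΔΔCq module
handles companion qPCR measurements.  Because the raw confocal volumes such
pipelines are normally run on are rarely shareable, the package ships a
seeded synthetic-cell generator that reproduces the statistical structure
the analysis assumes, with full ground truth.

## Geometry and measurement

Volumes are voxel grids with anisotropic spacing stored `(z, y, x)` in μm
(default emulated acquisition: 0.05 × 0.05 μm laterally, 0.15 μm axially).
Spacing is applied at measurement time; nothing is resampled.  Voxel index
`(0,0,0)` sits at physical position `spacing/2` (voxel-center convention),
which keeps centroids unbiased.

Segmentation mirrors a surface-creation wizard deterministically: the
organelle channel is zeroed outside the cell mask, optionally
Gaussian-smoothed at a physical "surface detail" scale (σ in μm, converted
per axis to voxels; conventional detail levels are 0.5 μm for the cell,
0.2 μm for mitochondria, 0.4 μm for vesicles), thresholded at an absolute
intensity (always a user input — there is no universal value), labeled with
6/18/26-connectivity (default 26: renderings connect across diagonals), and
filtered by a minimum physical volume.  Interactive splitting of fused
surfaces is deliberately not reproduced; in a batch pipeline the threshold
is the only splitting control, and the synthetic tests use non-touching
objects.

Per component: volume = voxel count × voxel volume; centroid = unweighted
mean of voxel centers; surface area from a marching-cubes triangulation of
the binary component at iso-level 0.5 with physical spacing.  The binary
field is pre-smoothed with a σ = 1 voxel Gaussian before meshing: marching
cubes on raw binary data overestimates a ball's area by roughly 8% — a
staircase bias that does not vanish with refinement — while the smoothed
isosurface converges to the true area (measured error at the acquisition
spacing: ≲0.3%).  Components too small to survive smoothing fall back to
the unsmoothed mesh; their sphericity can exceed 1 (the octahedral mesh of
a single voxel has less area than a sphere of equal volume) and such
objects should be excluded via `min_volume` rather than trusted.

Sphericity is Wadell's ψ = π^{1/3}(6V)^{2/3}/A: 1 for a ball, ~0.58 for a
10:1 prolate spheroid.

## Localization

Distances are Euclidean, from the organelle centroid to the soma spot
center (the spot marks the nucleus; a 5 μm spot plus a 10 μm radius reaches
at most ~5–7 μm past the nuclear membrane).  The perinuclear fraction is
the volume-weighted share of organelles with distance ≤ 10 μm — the
boundary is closed by convention; boundary-coincident centroids are
measure-zero in continuous data.  The radial profile bins distances as
[0, 10], (10, 20], … so the 0–10 μm bin is index 0; bin masses are
normalized to total organelle volume and sum to 1.  Empty cells yield NaN
(an explicit undefined marker), never 0 — zeros would bias group medians.

## Sholl analysis

Intersections are strict crossings of straight parent–child segments with
concentric spheres at 1 μm steps, truncated at 60 μm, counted by solving
the segment–sphere quadratic (a segment that dips through a sphere counts
twice; tangencies and endpoints exactly on a sphere count zero).  This rule
is deterministic and verifiable against a dense arc-length sampling oracle.
The Sholl index is the band sum at radii 11–20 μm divided by the whole-curve
sum (both truncated at 60 μm); the 11–20 μm band is the one a PCA of
per-cell-normalized binned curves selects as carrying the largest
first-axis loading, and `dominant_bin_by_pca` reproduces that selection on
any profile matrix (ties break toward the lower bin).  "Band over total"
was chosen over "band over curve maximum" as the single normalization; one
definition keeps results comparable.

## PCA profiles

The profile holds six metrics per cell: Sholl index, % CD68 volume, median
mitochondrial volume, mitochondrial count, % mitochondrial volume, and
perinuclear %.  Sphericity is excluded (derived from volume); the largest
organelle volume is reported separately for the hyperfusion contrast.
Features are z-scored before the eigendecomposition: the metrics mix μm³,
counts and percentages, and covariance PCA would be dominated by scale.
Loadings are unit-norm with each column's largest-magnitude entry made
positive; scores are the standardized data projected on the loadings.
Cells with any undefined metric are excluded with a logged reason.

## Statistics

Group comparisons are gated: Shapiro–Wilk per group and Levene (median-
centered) across groups, both at α = 0.05.  Two groups: Student's t (both
pass), Welch's t (normal, unequal variance), else Wilcoxon rank-sum (exact
for small samples without ties, normal approximation with continuity
correction otherwise).  Three or more: one-way ANOVA with Tukey's HSD, else
Kruskal–Wallis with Conover–Iman pairwise comparisons under Holm
adjustment.  The Conover statistic uses the pooled rank variance and the
tie-corrected H; for two groups it reduces exactly to a t-test on ranks,
which the test suite uses as an independent identity check.  All tests are
two-sided.

Sholl curves are compared with a linear mixed model:
`intersections ~ group * radius` with sum-to-zero group contrasts, a random
intercept **and a random radius slope** per cell, REML estimation, and a
type-III Wald test of the group main effect.  The random slope is not
optional: per-cell curves differ in tilt as well as level, and an
intercept-only model underestimates the group-effect standard error — on
null synthetic cohorts it rejected at ~26% instead of 5%.  Because the
group factor varies only between cells, the Wald statistic is referred to
an F distribution with between-within denominator degrees of freedom
(cells − groups) rather than the asymptotic χ²; on 200 null cohorts of
2×20 cells this gives an empirical type-I rate of ~0.10 (χ²) → ~0.095 (F),
within the nominal band.  Counts are treated as Gaussian; at very low
intersection counts the model is only approximate.

## qPCR

Primer efficiency is `((2^(−1/slope)) − 1) × 100` from a 1:4 serial-dilution
slope, with a 90–110% acceptance window.  Quantification follows the ΔΔCq
scheme with the sign convention dCq = Cq(reference) − Cq(gene of interest),
ddCq = dCq − mean control-condition dCq within the same experimental batch,
fold = 2^ddCq.  This dCq orientation is the negative of the classical Livak
ΔCt, but because ddCq differences cancel the reference terms, fold changes
still read as expression relative to the control group; the control group's
geometric-mean fold change is 1 by construction.  Purity-marker genes
(IBA1, GFAP by default) whose fold change exceeds a configurable threshold
(default 2) are flagged, never dropped — the thresholds used in practice
are study-specific.

## Synthetic cells

The generator is the package's test bed and defines the conditions every
calibration and power figure refers to.  One cell is: a stochastic branched
tree (5 primary branches, Gamma-distributed branch lengths with a 12 μm
mean, branching probability decaying with distance from the soma at
0.03 /μm, depth ≤ 4); a mitochondrial population of prolate ellipsoids
placed on the tree's arc; and a CD68-like vesicle population built the same
way.  Key knobs, with defaults:

| knob | default | meaning |
|---|---|---|
| `cell_volume` | 1500 μm³ | microglia territory volume |
| `target_content_pct` | 5% | mitochondrial volume share (per-cell lognormal, CV 0.15) |
| `n_mito_base` | 60 | mean organelle count at fragmentation 1 |
| `volume_sigma0` | 0.4 | lognormal σ of organelle volumes at fragmentation 1 |
| `fragmentation` | 1.0 | scales count (∝ f) and σ² (+1.8·ln f) at fixed content |
| `elongation` | 2.0 | ellipsoid aspect ratio (sets sphericity) |
| `perinuclear_bias` | 0.3 | probability of placement within 10 μm of the soma |
| `hyperfused_fraction` | 0.0 | probability of one dominant organelle |
| `hyperfused_volume` | 10 μm³ | dominant organelle volume |

Volumes are lognormal draws rescaled so the per-cell content target is hit
exactly.  The count/σ coupling makes the `fragmentation` knob reproduce the
injury-responsive signature as one parameter: at fragmentation 1.5 with
content ×1.3 the expected per-cell effects are count ×1.5 and median volume
×(1.3/1.5)·exp(−Δσ²/2) ≈ ×0.6.  The volume scale (60 organelles of mean
~1.2 μm³, control largest ~3–4 μm³) was chosen so that the hyperfused
dominant at 10 μm³ is an extreme of the distribution rather than a typical
draw — matching how such pipelines display per-organelle volumes on a
0–10 μm³ spectrum.  A hyperfused cell's dominant organelle is set to the
configured volume exactly (capped at 80% of content) before rescaling the
rest.

Rasterization renders the tree as a tube of spheres, organelles as analytic
prolate ellipsoids (the cell mask is the union of tube, soma, and all
organelles, so organelles always lie inside the mask), and returns
per-organelle ground-truth label grids.  With the `min_separation` flag the
placement guarantees non-touching organelles (escalating positional jitter
around the arc; placement failure raises rather than silently overlapping).

What the generator does **not** emulate: optics (no PSF, no noise, no
depth-dependent attenuation), curved tubular organelles (high-aspect
ellipsoids stand in; the sphericity ordering is preserved), fission–fusion
kinetics, and touching organelles that would need marker-based splitting.
Passing tests therefore demonstrate the correctness of the measurement and
inference machinery under the stated generative assumptions — not
robustness to imaging artifacts.

## Problem sizes

The test and acceptance runs use cohorts of 20–40 cells per group, 100
replicates for power/recovery rates, 300–400 replicates for null
calibration of the scalar tests, and 150–200 for the mixed model; the
end-to-end voxel runs use 0.2 μm isotropic spacing with compact trees
(branch length mean 8 μm, depth ≤ 2).  These sizes give binomial standard
errors of ~1–3 percentage points on the reported rates while keeping the
whole suite runnable on a laptop-class single core.

## Known limitations

* Thresholds are absolute intensities; there is no automatic threshold
  selection.
* No splitting of touching organelles — over-merged components must be
  addressed by raising the threshold upstream.
* The mixed model treats intersection counts as Gaussian; at very low
  counts a GLMM would be more faithful.
* `dominant_bin_by_pca` uses only the first principal axis.
* Distances use the soma spot center; a spot-surface convention would shift
  all distances by a constant (~2.5 μm for a 5 μm spot).
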