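# mitoglia

Per-cell 3D morphometry of mitochondrial networks in microglia.

Microglia remodel their mitochondria under stress: networks fragment (many
small, rounder organelles), gain content, and shift toward the soma; under
some conditions single cells instead hyperfuse their network into one
dominant large organelle.  Quantifying this per cell from 3D confocal data
requires a chain of steps that are usually stitched together by hand:
masked organelle segmentation, per-organelle measurement, per-cell metric
compilation, Sholl analysis of the cell's branching, multivariate
profiling, and group statistics.  `mitoglia` implements that chain as a
tested, scriptable pipeline for anyone analyzing single-cell organelle
populations in 3D — plus the ΔΔCq arithmetic for companion qPCR data and a
seeded synthetic-cell generator so the whole pipeline can be validated
without raw imaging data.

## What it computes

Per segmented organelle (volume `V`, marching-cubes surface area `A`):

* Wadell sphericity  ψ = π^⅓ (6V)^⅔ / A  (1 for a ball)
* centroid and Euclidean distance to the soma spot center

Per cell:

* **connectivity** — median organelle volume, organelle count, mean
  sphericity, largest organelle volume (hyperfusion marker)
* **content** — 100 · Σ V / V_cell for mitochondria and CD68 vesicles
* **localization** — perinuclear % (volume share at distance ≤ 10 μm) and a
  10 μm-binned radial volume profile
* **morphology** — Sholl intersections at 1 μm steps to 60 μm, and the
  Sholl index: intersections at 11–20 μm / all intersections (band chosen
  by PCA loading of normalized Sholl profiles)

Cohort level: six-metric PCA (z-scored; sphericity excluded as
volume-derived), gated two-sample/multi-group statistics
(Shapiro + Levene → t / Welch / Wilcoxon, ANOVA + Tukey or
Kruskal–Wallis + Conover–Holm), and a linear mixed model for whole Sholl
curves.  qPCR: efficiency = ((2^(−1/slope)) − 1)·100 and
fold change = 2^(ΔCq − ΔCq_control), with ΔCq = Cq_ref − Cq_gene.

## Worked example

```python
import mitoglia as mg
from mitoglia.profiles import collect_cell_features

# two synthetic cohorts: baseline vs. injury-responsive phenotype
cells, truth = mg.generate_cohort(
    {"naive": mg.naive_params(), "onc": mg.onc_params()},
    n_cells_per_group=25, seed=7,
)
feats = collect_cell_features(cells)
print(feats.groupby("group")[["median_mito_volume", "n_mito",
                              "pct_mito_volume", "perinuclear_pct"]].mean().round(2))

rep = mg.compare_metric_table(feats, "median_mito_volume")
print(rep.test_name, f"p = {rep.p_value:.2e}")

res = mg.run_pca(mg.assemble_profiles(feats.to_dict("records")), k=2)
print("explained variance:", res.explained_variance_ratio.round(2))
```

Output:

```
       median_mito_volume  n_mito  pct_mito_volume  perinuclear_pct
group
naive                1.21   60.08             5.16            51.34
onc                  0.69   85.72             5.96            67.42
student_t p = 1.61e-14
explained variance: [0.51 0.19]
```

The injury-like group shows the fragmentation signature — median organelle
volume down (~0.6×), count up (~1.5×), content up (~1.3×), perinuclear
share up — and each contrast is detected by the gated test.  The PCA
separates the two phenotypes along PC1.

A command-line interface mirrors the library
(`mitoglia simulate|segment|metrics|sholl|profile|stats|qpcr`); run
`mitoglia --help` for the subcommands.

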