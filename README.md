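# calcimorph

3D morphometry and statistical coupling analysis of vascular
calcification clusters in CT attenuation volumes.

Carotid atherosclerotic calcification is not a uniform entity: discrete
mineral deposits ("clusters") vary in size, shape and density, and those
properties are biomechanically coupled — large clusters tend to be
elongated and dense, dense clusters rounder and more compact, fragmented
multi-cluster plaques are made of smaller, more spherical deposits.
`calcimorph` is a reproducible pipeline for quantifying this structure
from CT angiography: it segments calcium, labels discrete clusters,
measures per-cluster geometry and density, and runs the rank-based
statistical analysis that relates them. A first-class synthetic phantom
generator provides cohorts with known ground truth, so every stage of
the pipeline is testable without clinical data.

Intended users: imaging researchers quantifying calcification phenotypes,
and methodologists who need a validated reference chain from voxels to
population statistics.

## Method

**Segmentation.** HU windowing (default −1024..3071, identity on
physical values), inclusive thresholding at ≥ 130 HU within an optional
anatomical ROI mask, removal of components below 1 mm³ (optional binary
opening), and 3D connected-component labelling (6/18/26-connectivity,
default 26) with deterministic size-then-lexicographic label order.

**Per-cluster descriptors.** For each cluster with voxel-centre set
*X* and spacing *s*:

- volume `V = n_voxels · ∏s` (exact);
- max/min linear dimensions from a near-minimal oriented bounding box
  (convex-hull facet orientations + rotating-calipers in-plane search +
  PCA candidate; extents padded by one mean voxel spacing), and
  aspect ratio `dim_max / dim_min`;
- eccentricity `√(λ₁/λ₃) − 1` from the eigenvalues `λ₁ ≥ λ₂ ≥ λ₃` of
  the second central moment (inertia) tensor of *X* (plus the voxel
  self-moment `s²/12`): 0 for a sphere, sensitive to lobes and surface
  asymmetry as well as overall elongation;
- compactness `A^{3/2} / (6 √π V)` with surface area *A* from a
  marching-cubes isosurface: 1 for a continuum sphere, larger for any
  other shape;
- mean attenuation μ (HU) and heterogeneity σ (sample SD, HU);
- centroid in world millimetres.

**Statistics.** Spearman correlation matrices over the six features
with Benjamini–Hochberg FDR (q < 0.05) and 1000-resample percentile
bootstrap CIs; partial Spearman correlations (rank-transform, then
residualize against covariate ranks); multivariable linear models with
restricted cubic splines (3 knots at the 10/50/90th percentiles,
Harrell normalization) with Wald χ² nonlinearity tests and influence
screening (Cook's D > 4/n, leverage > 2p/n, |DFBETAS| > 2/√n; flagged
rows excluded, one refit); Mann–Whitney U (exact enumeration for small
groups) and Kruskal–Wallis with BH-adjusted pairwise follow-ups for the
single- versus multi-cluster fragmentation phenotype.

**Phantoms.** Cohorts of plaque volumes containing 1–4 lobed-ellipsoid
clusters with a dense core / light periphery attenuation ramp, on a
soft-tissue background with Gaussian noise. Cross-cluster couplings
between volume, elongation and core attenuation are planted through a
Gaussian copula (`r = 2 sin(π ρs / 6)`), and fragmented plaques draw
their clusters from the small end of the same population.

## Worked example

```bash
python examples/04_fragmentation_analysis.py
```

```
80 plaques: 70 single-cluster, 10 multi-cluster

mean_cluster_volume_mm3      single       188.6 [81.2-457.2]  multi         45.3 [36.3-55.5]  p=0.00013 *
total_volume_mm3             single       188.6 [81.2-457.2]  multi        90.5 [72.7-119.3]  p=0.0668
mean_eccentricity            single            1.3 [0.9-1.9]  multi            0.8 [0.6-1.1]  p=0.00397 *
mean_compactness             single            1.3 [1.2-1.4]  multi            1.2 [1.2-1.2]  p=0.00397 *
mean_mu_hu                   single      407.3 [360.8-479.9]  multi      383.1 [354.7-398.7]  p=0.288
mean_sigma_hu                single        90.2 [62.5-130.4]  multi         69.2 [52.7-79.8]  p=0.127
```

Each row compares single- versus multi-cluster plaques (median [IQR]
per group, Mann–Whitney p). Individual deposits in fragmented plaques
are ~4× smaller and less eccentric, while the total calcified burden
does not differ — fragmentation redistributes mineral rather than
removing it. `examples/01–03` walk through cohort simulation, per-cluster
measurement, and recovery of the planted size–shape–density couplings
(volume–eccentricity ≈ 0.8, volume–μ ≈ 0.5, μ–compactness ≈ 0.4, all
q < 0.001 at cohort scale).

The same workflow is scriptable from a shell:

```bash
calcimorph all --seed 7 --outdir run/     # simulate → segment → features → analyze
calcimorph segment --input vol.nii.gz --threshold 130 --out labels.nii.gz
```

`run/` then contains NIfTI volumes and label maps, `features.csv`,
`plaques.csv`, `correlations.csv`, `partial_correlations.csv`,
`rcs_fits.csv`, `group_comparisons.csv` and a `manifest.json` recording
every parameter and seed; the same run repeated with the same seed is
byte-identical.

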