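# Methods

This note documents the models and numerical choices behind
`calcimorph`: what the pipeline computes, what the synthetic cohorts
emulate, which parameters matter, and where the design was genuinely
open.

## Segmentation

Calcium candidates are voxels with attenuation ≥ 130 HU — the
conventional CT calcium threshold, applied inclusively — inside an
optional user-supplied ROI mask. The ROI is the machine-readable
stand-in for anatomical constraints (bifurcation localization, bone
exclusion) that are manual steps in clinical workflows; the package
performs no automated bone/vessel discrimination.

"Normalization" is windowing only: values are clipped to
[−1024, 3071] HU, the physical CT range, so the default is the
identity. Anything that rescaled HU would corrupt the attenuation
statistics μ and σ, which are reported in HU.

Cleaning removes connected components smaller than 1 mm³. A binary
opening is available (`opening_radius_voxels`) but defaults to **off**:
at clinical voxel sizes (0.6 mm) a radius-1 ball opening erodes the
thin ends of small elongated clusters by more than 10 % of their
volume, which breaks the pipeline's volume-recovery guarantee, while
the size floor alone already removes isolated threshold-noise voxels.

Connectivity defaults to 26 (corner-touching voxels merge), treating a
cluster as a single discrete calcification; 6 and 18 are available and
oracle-tested. Labels are ordered by decreasing size with
lexicographic tie-breaks, so outputs are platform-independent.

## Shape descriptors

Clinical eccentricity and compactness values exceed the [0, 1) ranges
of the classical ellipse eccentricity and sphericity indices, so both
descriptors here are open-scale indices anchored at the sphere:

- **Eccentricity** `√(λ₁/λ₃) − 1` from the inertia tensor of all voxel
  centres (plus the `s²/12` voxel self-moment, which is the exact
  second moment of a voxel's own material and regularizes single-voxel
  and planar clusters). Because every voxel contributes, the index
  responds to lobes and local surface asymmetry, not only to the
  extremal dimensions; a 2:1:1 ellipsoid scores 1.0 (continuum moments
  `⟨x²⟩ = a²/5`).
- **Compactness** `A^{3/2} / (6√π V)`, sphere-normalized so a continuum
  sphere scores exactly 1 and every other shape more. `A` comes from a
  marching-cubes isosurface at the 0.5 level of the zero-padded
  indicator; components thinner than 2 voxels on any axis fall back to
  the summed exposed voxel-face area with a logged warning (the face
  estimator overestimates smooth areas by up to ~1.5× but is exact for
  rectangular shapes).
- **Oriented bounding box**: candidate frames are the grid axes, the
  PCA frame, and for each convex-hull facet normal the in-plane
  rotation minimizing the 2D footprint (rotating calipers: the optimal
  rectangle of a convex polygon is edge-aligned); the minimum-volume
  box wins. This is near-minimal, deterministic and rotation-stable;
  it is not the exact O'Rourke optimum. Extents are padded by one mean
  voxel spacing so degenerate clusters have positive dimensions and a
  defined aspect ratio. Note that minimal-box *dimensions* are only a
  stable measurement for objects whose minimal box is well separated
  (box-like or clearly elongated); for smooth near-spherical bodies,
  tilted boxes of nearly identical volume but different dims exist —
  an intrinsic property of the problem, not of the solver.

σ uses the n−1 denominator; single-voxel clusters report σ = 0. World
coordinates are `origin + index · spacing`, 0-based, no axis flips.

## Statistical analysis

All rank statistics use average ranks for ties and are therefore
invariant under strictly monotone transforms.

- **Correlation matrix**: Spearman ρ over all 15 unordered pairs of
  {volume, aspect ratio, eccentricity, compactness, μ, σ}; p from the
  t approximation; q-values by Benjamini–Hochberg over exactly this
  15-pair family; 95 % CIs by case-resampling percentile bootstrap
  (1000 resamples; degenerate resamples are redrawn).
- **Partial Spearman**: rank-transform every variable, residualize the
  x- and y-ranks on the covariate ranks plus intercept by least
  squares, correlate the residuals; p from t with df = n − k − 2. This
  equals the precision-matrix partial correlation of the rank
  correlation matrix (tested against it and against an independent
  implementation).
- **Restricted cubic splines**: 3 knots at the empirical 10/50/90 %
  quantiles of the exposure; two-column Harrell basis (linear +
  restricted cubic term, continuous with continuous first derivative,
  linear outside the boundary knots). Nonlinearity is judged by the
  Wald χ² `(β_nl/SE)²` on 1 df. Under an exact fit (zero residual
  variance) the Wald ratio is 0/0 noise; the implementation reports
  χ² = 0, p = 1 in that case.
- **Influence screening**: Cook's distance, hat leverage and
  standardized DFBETAS from the closed-form leave-one-out identities of
  a single OLS fit; flags at the textbook cutoffs 4/n, 2p/n, 2/√n; the
  union of flags is excluded and the model refit exactly once (no
  iteration). Under a numerically exact fit, Cook's D and DFBETAS are
  defined as 0.
- **Fragmentation**: the primary contrast dichotomizes plaques into
  single versus multi-cluster and compares six plaque-level summaries
  by Mann–Whitney U; the sensitivity analysis stratifies by exact
  cluster count (Kruskal–Wallis, BH-adjusted pairwise follow-ups only
  where KW p < 0.05). Strata with fewer than 2 plaques abort the
  primary dichotomy but are dropped (with a strict-mode override) from
  the sensitivity analysis, since a singleton 4-cluster stratum is
  expected at realistic cohort sizes.
- **Mann–Whitney**: U counts pairs with ties at half weight. The
  p-value is an exhaustive enumeration over group assignments
  (tie-valid) when min(n) ≤ 8 and the assignment count is ≤ 2·10⁴;
  otherwise the normal approximation with tie correction, without
  continuity correction — which keeps the two-group Kruskal–Wallis
  equivalence (H = z²) exact.
- Medians and IQRs use the linear-interpolation quantile convention.

Clusters are analyzed as independent rows, mirroring common practice;
within-patient/within-plaque correlation is not modelled. This is a
known limitation, not an endorsement.

## Synthetic cohorts

The generator emulates a clinical carotid CTA cohort at the level the
analysis consumes: cluster counts, marginal feature distributions, the
core–periphery attenuation gradient, and the cross-cluster rank
couplings. Defaults (all configurable through `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| plaques | 107 | clinical-cohort scale |
| cluster count probs | 0.81/0.12/0.05/0.02 over 1–4 | single-cluster predominance ~81 % |
| grid | 96³ @ 0.6 mm isotropic | isotropic clinical reconstruction; fits the largest clusters with margin |
| volume marginal | lognormal(ln 172.5, 1.687), truncated [5, 1500] mm³ | median ≈ 172 mm³, IQR ≈ 43–418; truncation by quantile rescaling is strictly monotone so planted rank couplings are untouched |
| elongation marginal | U(1.2, 3.5) | aspect-ratio median ≈ 2.3 |
| core HU marginal | N(560, 250) truncated [300, 1200] | cluster mean μ = (edge+core)/2 lands near 405 HU |
| periphery / background / noise | 250 / 60 / 20 HU | periphery well above the 130 HU threshold (no erosion of cluster extent by noise); soft-tissue background safely below it |
| lobes | 1/2/3 with probs 0.7/0.2/0.1, offset 0.35·a, scale 0.6 | surface asymmetry that raises eccentricity without much changing the bounding box |
| planted Spearman (volume, elongation, core) | 0.8 / 0.5 / 0.4 | the size–shape, size–density and shape–density couplings under study |
| multi-cluster size bias | exponent 2.5 | gives fragmented plaques a ~4.5× smaller median per-plaque mean cluster volume |

Clusters are ellipsoids with semi-axes `a = e·c, b = √(a·c), c` solved
from the sampled volume and elongation, randomly permuted onto grid
axes, optionally lobed, and placed with ≥ 2 voxels of surface
separation (bounding-sphere criterion, bounded retries). Couplings are
planted with a Gaussian copula (`r = 2 sin(π ρs / 6)`, exact for normal
margins; the implied Pearson matrix must be positive definite).

Two design points deserve emphasis:

- **Attenuation ramp.** Inside each cluster, HU rises monotonically
  with interior depth from the periphery value to the sampled core
  value — mineralized cores are denser than recent peripheral
  deposition. The ramp is the within-cluster *quantile* of Euclidean
  depth (equal-volume shells), not a linear function of raw depth: the
  raw-depth version is voxel-quantized, which makes small clusters
  read uniformly core-like and corrupts the volume–attenuation
  coupling at clinical voxel sizes. The quantile ramp fixes every
  cluster's mean at (edge+core)/2, so the attenuation readout is
  faithful across the whole size range, and it preserves the strong
  μ–σ coupling (σ ≈ (core−edge)/√12 plus noise).
- **Fragmentation by allocation, not scaling.** Multi-cluster plaques
  draw their clusters preferentially from the small-volume end of the
  *same* sampled population (selection weight `(1 − rank/n)^2.5`)
  rather than having volumes rescaled. The sampled
  (volume, elongation, core) triples are untouched, so the planted
  population couplings survive exactly, while the single/multi size
  contrast — and, through the size–shape coupling, the eccentricity
  contrast — emerges from the allocation, echoing the coalescence
  account in which large single deposits arise from merged small ones.

**What the phantoms do not emulate**: CT physics (beam hardening,
partial-volume blur beyond grid discretization, scanner noise spectra),
vessel geometry (plaques are abstract ROIs), clinical compactness
ranges (smooth lobed ellipsoids reach ~1.1–1.5; irregular clinical
clusters reach ~3), σ magnitudes (ramp + noise gives ~60–150 HU versus
~250 HU clinically), and the decoupling of aspect ratio from
eccentricity seen clinically (in smooth ellipsoid phantoms the two are
nearly collinear). Passing tests therefore demonstrate that the
measurement chain is correct and preserves planted population
structure; they do not certify accuracy on clinical morphology beyond
the emulated features.

## Numerical choices and degenerate inputs

- Spearman/Kruskal–Wallis p-values and BH adjustment delegate to
  scipy/statsmodels; constant inputs raise a degenerate-data error
  rather than returning NaN.
- |ρ| = 1 reports the limiting p = 0.
- Bootstrap resamples on which a statistic is undefined are redrawn;
  if more than half of all draws fail, the data are declared
  degenerate.
- EDT-based depth, component maxima and label ordering are all
  computed per connected component, so multi-component masks behave
  identically to per-cluster processing.
- Problem sizes in the test suite (cohort sizes, replication counts,
  bootstrap sizes) are chosen so the full chain — including a
  107-plaque end-to-end run, a 1000-replication spline-calibration
  study and a 200-replication bootstrap-coverage study — completes on
  a single CPU in a few minutes while keeping Monte-Carlo error well
  inside the asserted bands.

## Reproducibility

Every stochastic operation takes an explicit seed or Generator; the
pipeline derives all stage seeds from one run seed, echoes every
parameter into `manifest.json` together with input digests, and
produces byte-identical CSVs when re-run with the same configuration
and seed.
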