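"""Recover the planted size-shape-density couplings from a cohort.

The generator plants population Spearman correlations between cluster
volume, elongation and core attenuation.  Running the full pipeline and
correlating the EXTRACTED features shows how faithfully the chain of
thresholding, labelling and morphometry preserves that structure:
volume-eccentricity should come back near 0.8, volume-mean-attenuation
near 0.5 and attenuation-compactness near 0.4, all with q < 0.05 after
Benjamini-Hochberg correction over the 15 feature pairs.
"""

import pandas as pd

from calcimorph import (
    CohortConfig,
    compute_cluster_features,
    correlation_matrix,
    generate_cohort,
    label_components,
    morphological_clean,
    partial_spearman,
    threshold_calcium,
)

config = CohortConfig(n_plaques=60, seed=3)
volumes, truth = generate_cohort(config)

frames = []
for pid, vol in zip(truth["plaque_id"].unique(), volumes):
    labels = label_components(morphological_clean(threshold_calcium(vol)))
    frames.append(compute_cluster_features(labels, vol, plaque_id=pid))
features = pd.concat(frames, ignore_index=True)
print(f"extracted {len(features)} clusters from {len(volumes)} plaques\n")

corr = correlation_matrix(features, n_boot=500, seed=9)
show = corr[corr.q_value < 0.05].sort_values("rho", ascending=False)
print("couplings significant at q < 0.05 (Spearman, bootstrap 95% CI):")
print(show[["feature_x", "feature_y", "rho", "ci_lo", "ci_hi", "q_value"]]
      .round(3).to_string(index=False))

# adjust for the density features only: in smooth ellipsoid phantoms
# aspect ratio and compactness are nearly collinear with eccentricity
# (all three are driven by elongation), so adjusting for them would
# absorb the shape signal itself — unlike in clinical clusters, whose
# surface irregularity decouples these descriptors
res = partial_spearman(
    features["volume_mm3"], features["eccentricity"],
    features[["mu_hu", "sigma_hu"]],
    n_boot=500, seed=9,
    feature_x="volume_mm3", feature_y="eccentricity",
)
print(f"\npartial Spearman volume~eccentricity adjusting for attenuation "
      f"(mu, sigma): rho = {res.rho:.3f} [{res.ci_lo:.3f}, {res.ci_hi:.3f}], "
      f"p = {res.p_value:.2g}")
print("\nLarge clusters are systematically more elongated and denser; "
      "dense clusters have more irregular surfaces - the couplings the "
      "generator planted, read back through the full measurement chain.")
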