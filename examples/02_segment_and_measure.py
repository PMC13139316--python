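"""Segment calcium from one phantom volume and measure every cluster.

The segmentation chain is the standard calcium workflow: clip the HU
window, threshold at >= 130 HU, drop sub-millimetre noise components,
and label 26-connected components.  Morphometry then reports, per
cluster, its volume, oriented-bounding-box dimensions, aspect ratio,
eccentricity (inertia-tensor elongation, 0 = sphere), compactness
(surface irregularity, 1 = sphere) and attenuation statistics.
"""

from calcimorph import (
    CohortConfig,
    compute_cluster_features,
    generate_cohort,
    label_components,
    morphological_clean,
    normalize_intensity,
    threshold_calcium,
)

config = CohortConfig(n_plaques=3, cluster_count_probs=(0.0, 0.5, 0.5), seed=7)
volumes, truth = generate_cohort(config)

for pid, volume in zip(truth["plaque_id"].unique(), volumes):
    vol = normalize_intensity(volume)
    mask = threshold_calcium(vol, threshold=130.0)
    mask = morphological_clean(mask, min_volume_mm3=1.0)
    labels = label_components(mask, connectivity=26)
    features = compute_cluster_features(labels, vol, plaque_id=pid)
    print(f"\n{pid}: {labels.n_clusters} clusters "
          f"(ground truth {int((truth.plaque_id == pid).sum())})")
    print(features[["cluster_id", "volume_mm3", "dim_max_mm", "dim_min_mm",
                    "aspect_ratio", "eccentricity", "compactness",
                    "mu_hu", "sigma_hu"]].round(2).to_string(index=False))

print("\nEach row is one discrete calcification: mu_hu is its mean "
      "attenuation (dense clusters are bright), sigma_hu its internal "
      "heterogeneity from the core-periphery density gradient.")
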