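# Example pipeline configuration for `calcimorph all --config config.yaml`.
# Any omitted key keeps its package default.
cohort:
  n_plaques: 40
  cluster_count_probs: [0.81, 0.12, 0.05, 0.02]
  grid_shape: [96, 96, 96]
  voxel_spacing_mm: [0.6, 0.6, 0.6]
  volume_lognormal_params: [5.150, 1.687]   # log-mean, log-sd of cluster volume (mm^3)
  volume_bounds_mm3: [5.0, 1500.0]
  elongation_range: [1.2, 3.5]
  seed: 7
segmentation:
  threshold_hu: 130.0
  connectivity: 26
  min_volume_mm3: 1.0
  opening_radius_voxels: 0
analysis:
  n_boot: 1000
  seed: 7
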