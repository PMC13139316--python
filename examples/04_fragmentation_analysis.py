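"""Compare single-cluster versus fragmented multi-cluster plaques.

Fragmented (multi-cluster) calcification is a distinct phenotype: its
individual deposits are smaller and rounder than the single confluent
clusters thought to arise from their coalescence.  The generator plants
this contrast; Mann-Whitney U tests on per-plaque summaries read it
back, with a Kruskal-Wallis sensitivity analysis by exact cluster count.
"""

import pandas as pd

from calcimorph import (
    CohortConfig,
    aggregate_plaques,
    compare_fragmentation,
    compute_cluster_features,
    generate_cohort,
    label_components,
    morphological_clean,
    threshold_calcium,
)

config = CohortConfig(n_plaques=80, seed=17)
volumes, truth = generate_cohort(config)
frames = []
for pid, vol in zip(truth["plaque_id"].unique(), volumes):
    labels = label_components(morphological_clean(threshold_calcium(vol)))
    frames.append(compute_cluster_features(labels, vol, plaque_id=pid))
plaques = aggregate_plaques(pd.concat(frames, ignore_index=True))

n_multi = int(plaques.is_multi.sum())
print(f"{len(plaques)} plaques: {len(plaques) - n_multi} single-cluster, "
      f"{n_multi} multi-cluster\n")

for r in compare_fragmentation(plaques):
    if r.grouping != "single_vs_multi":
        continue
    med = {k: f"{m:.1f} [{q1:.1f}-{q3:.1f}]"
           for k, (m, q1, q3) in r.group_medians.items()}
    flag = " *" if r.p_value < 0.05 else ""
    print(f"{r.feature:28s} single {med['single']:>24s}  "
          f"multi {med['multi']:>24s}  p={r.p_value:.3g}{flag}")

print("\nValues are median [IQR] per group; * marks Mann-Whitney p < 0.05. "
      "Mean cluster volume (and, through the size-shape coupling, "
      "eccentricity) separates the phenotypes; total calcified volume "
      "does not - fragmentation redistributes mineral, it does not "
      "remove it.")
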