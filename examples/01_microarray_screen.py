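"""Stage 1: on/off candidate screening on pooled microarray profiles.

Generates a synthetic 1887-probe pooled-array experiment (Normal, KD,
+IVIG conditions) with 6 planted on/off probes and 5 planted
opposite-tendency probes, then runs the candidate screen.
"""

from exopair import (cluster_profiles, count_expressed_both,
                     generate_microarray, microarray_scenario,
                     select_onoff_candidates, select_opposite_tendency)

cmp_a, cmp_b, truth = generate_microarray(microarray_scenario(seed=1))

# Probes detected (log2 intensity > 1) in both pooled samples of each
# comparison — the well-expressed background.
for cmp in (cmp_a, cmp_b):
    print(f"expressed in both ({cmp.label_a} vs {cmp.label_b}): "
          f"{count_expressed_both(cmp)}")

# On/off: >200-fold change with one condition above log2 3.5 and the
# other below the −3 detection floor, in BOTH comparisons.
onoff = select_onoff_candidates(cmp_a, cmp_b)
# Opposite tendency: abundant (log2 > 4.5) only in KD, undetected in
# Normal and +IVIG.
opposite = select_opposite_tendency(cmp_a, cmp_b)
union = sorted(set(onoff) | set(opposite))

print(f"on/off candidates: {len(onoff)}  (planted: {len(truth.onoff_ids)})")
print(f"opposite tendency: {len(opposite)} "
      f"(planted: {len(truth.opposite_ids)})")
print(f"candidate union carried to qRT-PCR: {len(union)}")

# Clustergram structure: Ward/Euclidean dendrogram branch sizes.
_, branches = cluster_profiles(cmp_a)
print(f"top-3 dendrogram branch sizes (Normal vs KD): {branches}")
# The union is the panel a follow-up qRT-PCR screen would quantify.
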