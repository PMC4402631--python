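"""Two-stage nearest-neighbour outlier removal in PC space.

A dense core cluster of 500 samples plus 10 planted outliers at ten
times the core scale. Stage 1 keeps samples whose mean distance to
their 10 nearest neighbours is at most 0.15; stage 2 additionally
requires 9 of those 10 neighbours to be stage-1 members.
"""

from pbla import OutlierParams, mean_knn_distance, simulate_embedding, two_stage_outlier_removal

embedding, labels = simulate_embedding(
    n_core=500, n_outliers=10, core_scale=0.03, outlier_offset=0.3, seed=11
)
d = mean_knn_distance(embedding, k=10)
print(f"mean 10-NN distance: core max {d[labels == 'core'].max():.3f}, "
      f"outlier min {d[labels == 'outlier'].min():.3f} (cutoff 0.15)")

kept, diagnostics = two_stage_outlier_removal(embedding, OutlierParams())
kept = set(kept)
outlier_ids = {s for s, l in zip(embedding.sample_ids, labels) if l == "outlier"}
print(f"kept {len(kept)}/510 samples; "
      f"outliers removed: {len(outlier_ids - kept)}/10; "
      f"core removed: {510 - len(kept) - len(outlier_ids - kept)}")
print("Stage 2 trims boundary samples so only cluster-interior samples remain.")
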