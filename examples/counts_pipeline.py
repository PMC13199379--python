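"""Full pipeline from simulated UMI counts to rare cell clusters.

Simulates 1,500 cells x 5,000 genes with a ~1% minor group under the
gamma-Poisson model, preprocesses (log-normalize, HVG, scale, PCA),
runs the detector and reports the evaluation metrics.
"""

import rareq

counts, truth = rareq.simulate_counts(rareq.SplatLikeParams(seed=7))
print(f"simulated {counts.n_cells} cells x {counts.n_genes} genes; "
      f"minor group: {(truth == 'group_1').sum()} cells")

embedding = rareq.preprocess_counts(counts)
result = rareq.run_rareq(embedding)

part = rareq.LabeledPartition(predicted=result.labels, truth=truth,
                              rare_types=("group_1",))
report = rareq.evaluate_partition(part)

m = report.per_type["group_1"]
print(f"clusters: {result.assignment.n_clusters} "
      f"({len(result.rare_cluster_ids)} rare)")
print(f"minor group: TP={m['TP']} FP={m['FP']} FN={m['FN']} "
      f"f1={m['f1']:.3f} jaccard={m['jaccard']:.3f}")
print(f"global NMI: {report.nmi:.3f}")
# f1 and jaccard of 1.0 mean the ~15-cell minor group was isolated
# perfectly; NMI additionally reflects how cleanly the majority merged.
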