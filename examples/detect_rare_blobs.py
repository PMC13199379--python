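"""Detect a planted 1% rare population in a synthetic embedding.

Builds a 2,000-cell embedding with a 99/1 split (20 rare cells placed
10 within-type standard deviations away from the majority), runs the
detector, and scores the result against the planted labels.
"""

import numpy as np

import rareq

emb, truth = rareq.make_blobs(rareq.BlobSpec(
    n_cells=2_000, proportions=(0.99, 0.01), separation=10.0, seed=42))

result = rareq.run_rareq(emb)

rare = result.is_rare()
part = rareq.LabeledPartition(predicted=result.labels, truth=truth)
precision, recall, f1 = rareq.rare_prf(part, "type_1")

print(f"cells: {emb.n_cells}, planted rare cells: {(truth == 'type_1').sum()}")
print(f"clusters found: {result.assignment.n_clusters} "
      f"({len(result.rare_cluster_ids)} flagged rare, "
      f"{rare.sum()} cells in rare clusters)")
print(f"rare-type precision={precision:.3f} recall={recall:.3f} f1={f1:.3f}")
print(f"mean Q rare cells: {result.q.q[truth == 'type_1'].mean():.3f}  "
      f"majority: {result.q.q[truth == 'type_0'].mean():.3f}")
# F1 = 1 means the planted group was recovered exactly; the Q gap shows
# why: the tight rare clique saturates its neighborhood connectivity.
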