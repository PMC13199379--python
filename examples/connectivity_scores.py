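"""The connectivity scores on a toy geometry, step by step.

Ten collinear points: neighborhoods at the end of the line are more
self-contained than in the middle, and a pair of far-apart tight
cliques saturates both the per-cell and the cluster-level score.
"""

import numpy as np

import rareq

# a line of 10 points
line = rareq.EmbeddingMatrix.from_coords(np.arange(10, dtype=float)[:, None])
index = rareq.build_knn(line, k_param=10)
scores = rareq.all_q(index, k=3)
print("Q along the line (k=3):",
      np.array2string(scores.q, precision=3))
print(f"  range bound [1/k, 1] = [{scores.lower_bound():.3f}, 1]; "
      f"structural bound {scores.structural_lower_bound():.3f}")

# two tight hexagonal cliques 100 apart: every neighborhood saturates
angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
hexagon = 0.1 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
coords = np.concatenate([hexagon, hexagon + [100.0, 0.0]])
cliques = rareq.build_knn(rareq.EmbeddingMatrix.from_coords(coords), 12)
print("Q in a tight 6-clique (k=6):", rareq.cell_q(cliques, 0, 6))
print("Q_c of one clique as a cluster:",
      rareq.cluster_q(cliques, range(6)))
# both equal 1.0: all counted directed edges stay internal, the
# signature the detector uses to recognize rare populations.
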