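# Methods

## The model

Single-cell and spatial omics embeddings are summarized as a directed
k-nearest-neighbor (kNN) graph: each cell points at its `k.param − 1`
nearest other cells by Euclidean distance in the embedding (plus an
implicit self-edge), with `k.param = 20` by default. Rare populations —
cell types below roughly 1% of the dataset — tend to form small cliques
on this graph: their members' nearest neighbors are each other, with few
edges escaping the group. The detector turns that topological signature
into a per-cell score and a clustering procedure.

**Neighborhood connectivity (Q).** For a cell, let S be the cell plus
its `k − 1` nearest neighbors (`k = 6` by default; a small neighborhood
lets populations of only a handful of cells saturate it). Each member of
S contributes `k` directed edges — its self-edge plus its own `k − 1`
nearest out-edges — so exactly `k²` edges are examined, and

    Q = (# edges with both endpoints in S) / k².

Q ranges over `[1/k, 1]`. A tighter bound is structurally forced: the
center's own `k` edges all land in S by construction and every member's
self-edge is internal, so `Q ≥ (2k − 1)/k²`. Both bounds are reported;
the looser documented range is kept as the score's nominal range rather
than "corrected".

An alternative reading — testing edge membership against the full
`k.param`-capacity graph over a size-`k` window — would let the
numerator exceed the denominator; it is rejected because `k × k` is
defined as the *total* number of counted edges.

**Cluster connectivity (Q_c).** For a cluster C of n cells the
per-member edge budget is `k.param` capped by the cluster size:
`budget = n` when `n < 20`, else `20`. Then

    Q_c = (# intra-cluster edges among each member's budget edges) / (n · budget).

Since lists are built at capacity 20, a sub-20 budget simply truncates
the neighbor list. A singleton has `Q_c = 1` by construction (only its
self-edge is counted).

## The procedure

1. **Propagation.** Every cell starts as its own cluster. Each cell's
   parent is the member of its size-`k` neighborhood with the largest Q,
   *provided that Q strictly exceeds its own* (equal Q keeps the current
   label, preventing oscillation between equal-Q cells); ties among
   equally maximal neighbors break toward the smaller cell index. Cells
   that are their own parent are *waypoints* — local Q maxima. Because a
   parent always has strictly larger Q, parent pointers form a forest,
   and the fixed point of iterative label adoption is exactly the
   resolution of each cell to its waypoint root; this is computed by
   pointer doubling, with `max_propagation_iters = 100` as a safety cap
   that is never reached in practice.

2. **Voting.** Synchronous rounds of kNN majority voting over each
   cell's size-`vote_k` neighborhood (self included) smooth boundary
   misassignments; a tied vote keeps the current label. `vote_k`
   defaults to `k` and is exposed as a flag, since the cluster-level
   graph (`k.param`) is an equally defensible choice; rounds are capped
   at 10.

3. **Retention.** Clusters whose *mean member Q* strictly exceeds
   `q_threshold = 0.6` are frozen as rare populations. They are
   excluded from merging as both source and target, and are not
   re-evaluated afterwards.

4. **Merging.** The remaining clusters are merged recursively. Full
   passes visit non-rare clusters in ascending size (smaller clusters
   are the likeliest spurious fragments; ties toward the smaller id).
   For a cluster C the candidate partner C_n is the non-rare cluster
   receiving the most directed edges from C's members at full capacity
   (self-loops excluded; a tie between candidate partners goes to the
   smaller id). The merge is accepted iff

   - `Q_c(C ∪ C_n) > Q_c(C)` and `Q_c(C ∪ C_n) > Q_c(C_n)`, and
   - `edges(C → C_n) / (|C| · (k.param − 1)) > 0.2`.

   The union takes the larger constituent's id. Passes repeat until one
   completes with no merge; termination is guaranteed because each merge
   strictly reduces the cluster count.

   The strict inequalities make singletons (`Q_c = 1`) unmergeable. The
   optional `min_cluster_size` (> 1) force-assigns sub-threshold
   non-rare clusters to their most-connected neighbor, bypassing the
   acceptance conditions; the default (1) is the strict behavior.

No stage consumes randomness: the whole pipeline is a deterministic
function of the embedding and the parameters.

## Preprocessing

Raw counts are prepared with the standard chain: per-cell library-size
normalization to `scale_factor` (default 10,000; 80 is the documented
choice for low-feature spatial panels) followed by `log1p` (natural log
by default; a `log_base` flag converts, which only rescales the matrix
and is immaterial after PCA's per-gene standardization); highly variable
genes by within-bin standardized dispersion (top 2,000 by default,
`"all"` for panels under ~500 genes); per-gene z-scaling clipped at ±10
(a common convention; the clip value is exposed); PCA to 50 components
with each component's sign fixed so its largest-magnitude loading is
positive, making runs bit-identical. Numeric parity with any particular
toolchain's normalization is a non-goal — parity is judged at the level
of downstream cluster recovery. ATAC LSI and multimodal (WNN/sPCA)
embeddings are consumed precomputed, not produced here.

## kNN construction

Exact neighbor lists are computed by a chunked brute-force distance
sweep with a stable sort, which guarantees the deterministic
ascending-cell-index tie-break for equal distances. Above 50,000 cells
an approximate index (pynndescent, when available) may be used and is
recorded in a flag on the result; every result in this repository's
tests uses the exact path.

## Synthetic data

Two generators define the study conditions.

**Blobs** stand in for a preprocessed embedding: isotropic unit-variance
Gaussian clouds in 10 dimensions, type centers separated by a stated
multiple of the within-type standard deviation (default: 2,000 cells,
99/1 split — exactly 20 rare cells by largest-remainder rounding —
separation 10). They emulate a well-resolved embedding geometry only;
they have no count noise, no library-size variation and no correlated
features, so blob-based tests exercise the graph/score/propagation
machinery, not the preprocessing chain.

**Gamma-Poisson counts** follow the splatter-style group model: gene
base means ~ Gamma(0.6, rate 0.3); per group each gene is DE with
probability 0.4 and its mean is multiplied by `exp(±N(0.4, 0.8))` with
the sign equiprobable (the exact down-regulation fraction of the
reference simulator is unstated, so symmetric signing was chosen);
per-cell library sizes log-normal(11, 0.2); group expected expression
renormalized to the library size; counts ~ Poisson. Defaults are the
perturbation-benchmark setting (1,500 cells × 5,000 genes, 99/1 split,
no outlier genes — `out_prob` must be 0; nonzero values are not
implemented). This is a documented *splatter-like* model, not a numeric
clone: quantities tied to the reference simulator's RNG stream (an exact
cells-per-group split, an exact DEG count) are not reproduction targets.
What it does not emulate: zero-inflation/dropout beyond Poisson
sparsity, batch effects, outlier genes, gene-gene correlation.

On top sit the benchmark constructions: stratified down-sampling with an
exact per-rare-type quota and largest-remainder major allocation; DEG
titration (null matrix + r pre-identified DEG rows, with both the
replaced and inserted gene sets nested across r at a fixed seed so
sweeps are monotone by construction); three-fold perturbation of chosen
genes in target cells; and a multi-scale series with group sizes forced
to exactly 10 rare cells per dataset.

## Evaluation

Predicted clusters are annotated by the modal true type of their members
(ties alphabetical). For a rare type, the union of clusters annotated to
it is the positive prediction set; TP/FP/FN, precision, recall, F1 and
Jaccard follow from set overlap, with an empty positive set scoring 0 on
all of them (the undefined-precision convention). NMI is normalized by
the arithmetic mean of the two entropies (the common default in
clustering-evaluation packages; `min`, `max`, `geometric` available),
with zero-entropy inputs
scored 1 when the partitions are identical as set partitions and 0
otherwise. A cluster counts as a positive prediction only when annotated
to *that* rare type, not to any rare type.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen as the package's own
standard conditions: score oracles on 100 random instances of up to 60
cells against an independent O(n²) brute-force implementation;
planted-blob recovery over 20 seeds at 2,000 cells (median rare-type F1
must be exactly 1); the DEG-titration sweep on 1,500 cells × 2,000 genes
at levels (0, 25, 50, 100) × 10 nested repeats; the multi-scale series
at 1,000–50,000 cells with exactly 10 rare cells per dataset. Larger
scales follow the same code path via the approximate-index option.

## Known limitations

- Uniform-Q regions (e.g. perfect cliques, or exactly duplicated
  points) propagate no labels — every cell stays a waypoint. This is a
  direct consequence of the strict-inequality adoption rule.
- Q takes at most k² discrete values, so Q ties are pervasive, and
  index-based tie-breaking makes fragment boundaries (not rare-cell
  recovery) depend on cell order; full label-level permutation
  invariance holds only on tie-free instances.
- On a diffuse, structureless majority (an isotropic Gaussian) the
  merge conditions rarely fire — many small fragments each spread their
  out-edges over too many partners to clear the 0.2 ratio — so the
  majority may stay fragmented. On structured data (e.g. PCA of count
  data) fragments are fewer and larger, and merging consolidates them.
- A merged major cluster whose post-merge mean Q exceeds 0.6 is not
  re-flagged rare (retention happens once, before merging).
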