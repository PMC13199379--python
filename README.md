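# rareq

Topology-aware detection of rare cell populations in single-cell and
spatial omics data.

Rare cell types — populations below roughly 1% of a dataset — are
routinely absorbed into larger clusters by standard community-detection
clustering. On the directed k-nearest-neighbor (kNN) graph of a
low-dimensional embedding, however, rare populations leave a distinctive
signature: they form small cliques whose members' nearest neighbors are
each other. `rareq` turns that signature into a detector for
practitioners analyzing scRNA-seq, scATAC-seq (via precomputed LSI),
multimodal (WNN/sPCA) or spatial-panel embeddings.

## The method

For each cell, let **S** be the cell plus its *k* − 1 nearest neighbors
(*k* = 6 by default). Each member of S contributes *k* directed edges —
its self-edge and its own *k* − 1 nearest out-edges — and the
**neighborhood connectivity**

&nbsp;&nbsp;&nbsp;&nbsp;*Q* = |{(i → j) : i, j ∈ S}| / *k*²,&nbsp;&nbsp;&nbsp;&nbsp;*Q* ∈ [1/*k*, 1]

measures how many of them stay inside the neighborhood. Tight rare
cliques saturate *Q*; cells embedded in a diffuse majority leak edges
and score lower. Detection then proceeds in three deterministic stages:

1. **Q-guided propagation** — each cell adopts the label of the
   highest-*Q* member of its neighborhood when that *Q* strictly
   exceeds its own; local *Q* maxima ("waypoints") anchor the clusters.
2. **kNN majority voting** — synchronous vote rounds smooth boundaries.
3. **Retention and merging** — clusters with mean *Q* > 0.6 are frozen
   as rare populations; the rest are recursively merged using the
   cluster-level connectivity *Q*_c = intra-cluster edges / (*n* ·
   *k.param*) (with *k.param* = min(*n*, 20)): a cluster joins its
   most-connected neighbor only if the union's *Q*_c exceeds both
   parts' and more than 20% of its outgoing edges point at that
   neighbor.

Evaluation utilities score a predicted partition against ground truth:
majority-type cluster annotation, per-rare-type precision/recall/F1 and
Jaccard index, and normalized mutual information. A synthetic-data
module generates the benchmark inputs: Gaussian embedding blobs with a
planted rare group, splatter-style gamma-Poisson counts with group-wise
log-normal DE factors, stratified down-sampling with fixed rare quotas,
DEG titration, fold-change perturbation and multi-scale series.

## Worked example

```python
import rareq

emb, truth = rareq.make_blobs(rareq.BlobSpec(
    n_cells=2_000, proportions=(0.99, 0.01), separation=10.0, seed=42))
result = rareq.run_rareq(emb)
part = rareq.LabeledPartition(predicted=result.labels, truth=truth)
print(rareq.rare_prf(part, "type_1"))
```

Running `python examples/detect_rare_blobs.py` (the same computation
with reporting) prints:

```
cells: 2000, planted rare cells: 20
clusters found: 193 (2 flagged rare, 20 cells in rare clusters)
rare-type precision=1.000 recall=1.000 f1=1.000
mean Q rare cells: 0.633  majority: 0.468
```

All 20 planted rare cells — and no others — end up in rare-flagged
clusters (precision = recall = F1 = 1), and the mean *Q* gap (0.633 vs
0.468) shows the topological signal the detector exploits. The diffuse
isotropic majority stays fragmented (by design the merge conditions are
conservative); on count-derived embeddings the majority consolidates —
`python examples/counts_pipeline.py` simulates 1,500 cells × 5,000
genes with a 16-cell minor group and prints:

```
clusters: 2 (1 rare)
minor group: TP=16 FP=0 FN=0 f1=1.000 jaccard=1.000
global NMI: 1.000
```

The other examples walk through the connectivity scores on toy
geometries (`connectivity_scores.py`) and the DEG-titration sensitivity
sweep (`titration_sensitivity.py`).

## Command line

A thin CLI wraps the library:

```sh
rareq simulate blobs --seed 1 --n-cells 2000 --out sim/
rareq run --embedding sim/embedding.tsv --out result/
rareq evaluate --predicted result_labels.tsv --truth sim/labels.tsv --rare-types type_1
```

`rareq run` accepts either a precomputed embedding (TSV/CSV, first
column the cell id) or a count matrix (Matrix Market triplet directory
or dense delimited text), with flags `--k`, `--k-param`,
`--q-threshold`, `--merge-ratio`, `--vote-k`, `--scale-factor`,
`--n-hvg`, `--n-pcs` mirroring the library parameters; a YAML
`--config` supplies defaults that explicit flags override.

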