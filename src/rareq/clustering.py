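"""Q-guided label propagation, kNN-vote refinement and recursive merging.

The inference engine proceeds in three stages on a fixed kNN index:

1. *Propagation.*  Each cell starts as its own cluster and adopts the
   label of the highest-Q member of its size-k neighborhood whenever that
   Q strictly exceeds its own (ties toward the smaller cell index).
   Cells that are local Q maxima keep their own label and become the
   waypoints from which labels diffuse.  Because the parent always has
   strictly larger Q, parent pointers form a forest and the fixed point
   is reached by resolving each cell to its root.

2. *Voting.*  Synchronous majority-vote rounds over each cell's size-
   vote_k neighborhood smooth out boundary misassignments; a tied vote
   keeps the current label.

3. *Retention and merging.*  Clusters whose mean member Q strictly
   exceeds q_threshold (default 0.6) are frozen as rare populations.
   The remaining clusters are merged recursively: the most-connected
   neighboring cluster is a candidate partner, and a merge is accepted
   only when the union's Q_c exceeds both parts' and the edge ratio from
   the source cluster clears ratio_threshold (default 0.2).

Everything is deterministic; no stage consumes randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .knn import EmbeddingMatrix, NeighborIndex, build_knn
from .qmetric import ClusterStats, QScores, all_q, cluster_q, cluster_stats

__all__ = ["RareQParams", "ClusterAssignment", "RareQResult", "propagate",
           "vote_refine", "retain_rare", "merge_clusters", "run_rareq"]


@dataclass(frozen=True)
class RareQParams:
    """Tunable parameters of the detector.

    k : neighborhood size for Q and propagation (small so that very rare
        populations can saturate their neighborhood), default 6.
    k_param : kNN-list capacity and cluster-level edge budget, default 20.
    q_threshold : mean-Q cutoff above which a cluster is retained as a
        rare population, default 0.6 (strict inequality).
    ratio_threshold : minimum fraction of a cluster's outgoing edges that
        must point at the merge partner, default 0.2 (strict inequality).
    vote_k : neighborhood size for majority voting; None means use k.
    min_cluster_size : clusters below this size are force-assigned to
        their most-connected neighbor after merging (default 1 = never).
    """

    k: int = 6
    k_param: int = 20
    q_threshold: float = 0.6
    ratio_threshold: float = 0.2
    vote_k: int | None = None
    max_propagation_iters: int = 100
    max_vote_rounds: int = 10
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold < 1 and 0 < self.ratio_threshold < 1):
            raise ValueError("invalid params: thresholds must lie in (0, 1)")
        for name in ("k", "k_param", "max_propagation_iters",
                     "max_vote_rounds", "min_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid params: {name} must be >= 1")
        if self.vote_k is not None and self.vote_k < 1:
            raise ValueError("invalid params: vote_k must be >= 1")

    @property
    def effective_vote_k(self) -> int:
        return self.k if self.vote_k is None else self.vote_k


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell labels plus provenance of the stage that produced them."""

    labels: np.ndarray
    stage: str
    waypoints: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    iterations_used: int = 0
    converged: bool = True

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass(frozen=True)
class RareQResult:
    assignment: ClusterAssignment
    cluster_stats: list[ClusterStats]
    rare_cluster_ids: set[int]
    params: RareQParams
    q: QScores
    cell_ids: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return self.assignment.labels

    def is_rare(self) -> np.ndarray:
        """Boolean per-cell rare flag."""
        rare = np.zeros(self.assignment.n_cells, dtype=bool)
        for cid in self.rare_cluster_ids:
            rare[self.labels == cid] = True
        return rare


def _neighborhoods(index: NeighborIndex, k: int) -> np.ndarray:
    n = index.n_cells
    S = np.empty((n, k), dtype=np.int64)
    S[:, 0] = np.arange(n)
    S[:, 1:] = index.neighbors[:, : k - 1]
    return S


def propagate(index: NeighborIndex, q: QScores,
              params: RareQParams) -> ClusterAssignment:
    """Q-guided label propagation to waypoint roots.

    parent(i) is the member of i's size-k neighborhood with the largest
    Q, provided that Q strictly exceeds q_i (ties toward the smallest
    cell index); otherwise i is its own parent and hence a waypoint.
    Labels then chase parent pointers to their roots.
    """
    if q.n_cells != index.n_cells:
        raise ValueError("inconsistent inputs: index and Q sizes differ")
    if q.k != params.k:
        raise ValueError("inconsistent inputs: Q computed at a different k")
    n = index.n_cells
    S = _neighborhoods(index, params.k)
    neigh_q = q.q[S]                                   # (n, k)
    best = neigh_q.max(axis=1)
    # smallest member index among those attaining the maximum
    attains = neigh_q == best[:, None]
    masked = np.where(attains, S, n)
    parent = masked.min(axis=1)
    own = best <= q.q                                  # no strict improvement
    parent[own] = np.arange(n)[own]

    # resolve parent pointers to their waypoint roots (pointer doubling:
    # the fixed point of iterative adoption, reached in O(log depth) rounds)
    labels = parent.copy()
    iters = 0
    converged = False
    for _ in range(params.max_propagation_iters):
        iters += 1
        new = labels[labels]
        if np.array_equal(new, labels):
            converged = True
            break
        labels = new
    waypoints = np.flatnonzero(parent == np.arange(n))
    return ClusterAssignment(labels=labels, stage="propagated",
                             waypoints=waypoints, iterations_used=iters,
                             converged=converged)


def vote_refine(index: NeighborIndex, assignment: ClusterAssignment,
                params: RareQParams) -> ClusterAssignment:
    """Synchronous kNN majority voting; a tied vote keeps the current
    label."""
    if assignment.stage != "propagated":
        raise ValueError("inconsistent inputs: expected propagated labels")
    vk = params.effective_vote_k
    S = _neighborhoods(index, vk)
    labels = assignment.labels.copy()
    rounds = 0
    converged = False
    for _ in range(params.max_vote_rounds):
        rounds += 1
        neigh = labels[S]                              # (n, vk)
        # multiplicity of each slot's label within the row, fully vectorized
        counts = (neigh[:, :, None] == neigh[:, None, :]).sum(axis=1)
        top = counts.max(axis=1)
        cand = np.where(counts == top[:, None], neigh, -1)
        winner = cand.max(axis=1)
        lone = np.where(cand == -1, winner[:, None], cand).min(axis=1)
        unique_winner = winner == lone                 # single modal label
        new = np.where(unique_winner, winner, labels)
        if np.array_equal(new, labels):
            converged = True
            break
        labels = new
    return replace(assignment, labels=labels, stage="voted",
                   iterations_used=rounds, converged=converged)


def retain_rare(stats: list[ClusterStats], q_threshold: float) -> set[int]:
    """Clusters whose mean member Q strictly exceeds the threshold are
    frozen as rare populations (excluded from merging entirely)."""
    return {s.cluster_id for s in stats if s.mean_q > q_threshold}


def _cross_edges(index: NeighborIndex, labels: np.ndarray):
    """Directed inter-cluster edge counts at full capacity, self-loops
    excluded.  Returns dict {(a, b): count} for a != b."""
    src = np.repeat(labels, index.neighbors.shape[1])
    dst = labels[index.neighbors.ravel()]
    mask = src != dst
    pairs, counts = np.unique(
        np.stack([src[mask], dst[mask]], axis=1), axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(pairs, counts)}


def merge_clusters(index: NeighborIndex, assignment: ClusterAssignment,
                   rare_ids: set[int], params: RareQParams) -> ClusterAssignment:
    """Recursively merge low-quality (non-rare) clusters.

    Full passes visit non-rare clusters in ascending size (ties toward
    the smaller id).  For each cluster C the candidate partner C_n is the
    non-rare cluster receiving the most directed edges from C's members
    (full k_param capacity, self-loops excluded; ties toward the smaller
    id).  The merge is accepted iff

        Q_c(C u C_n) > Q_c(C),  Q_c(C u C_n) > Q_c(C_n),  and
        edges(C -> C_n) / (|C| * (k_param - 1)) > ratio_threshold.

    The merged cluster takes the id of the larger constituent.  Passes
    repeat until one completes without a merge.  Retained rare clusters
    are untouchable as both source and target.
    """
    if assignment.stage != "voted":
        raise ValueError("inconsistent inputs: expected voted labels")
    labels = assignment.labels.copy()
    existing = set(int(c) for c in np.unique(labels))
    if not set(rare_ids) <= existing:
        raise ValueError("invalid rare set: unknown cluster id")
    cap = index.neighbors.shape[1]  # min(k_param, n) - 1 outgoing per cell

    qc_cache: dict[int, float] = {}

    def qc_of(cid: int) -> float:
        if cid not in qc_cache:
            qc_cache[cid] = cluster_q(index, np.flatnonzero(labels == cid))
        return qc_cache[cid]

    while True:
        cross = _cross_edges(index, labels)
        sizes = {int(c): int(n) for c, n in
                 zip(*np.unique(labels, return_counts=True))}
        order = sorted((c for c in sizes if c not in rare_ids),
                       key=lambda c: (sizes[c], c))
        merged_any = False
        gone: set[int] = set()
        for c in order:
            if c in gone:
                continue
            # most-connected non-rare partner, ties toward smaller id
            best, best_edges = None, 0
            for (a, b), cnt in cross.items():
                if a != c or b in rare_ids or b in gone or b == c:
                    continue
                if cnt > best_edges or (cnt == best_edges and best is not None
                                        and b < best):
                    best, best_edges = b, cnt
            if best is None or best_edges == 0:
                continue
            ratio = best_edges / (sizes[c] * cap)
            if ratio <= params.ratio_threshold:
                continue
            union = np.flatnonzero((labels == c) | (labels == best))
            qc_union = cluster_q(index, union)
            if not (qc_union > qc_of(c) and qc_union > qc_of(best)):
                continue
            # accept: union takes the larger constituent's id
            if sizes[best] > sizes[c] or (sizes[best] == sizes[c] and best < c):
                keep, drop = best, c
            else:
                keep, drop = c, best
            labels[labels == drop] = keep
            gone.add(drop)
            sizes[keep] = sizes[keep] + sizes[drop]
            del sizes[drop]
            qc_cache.pop(keep, None)
            qc_cache.pop(drop, None)
            qc_cache[keep] = qc_union
            cross = _cross_edges(index, labels)
            merged_any = True
        if not merged_any:
            break

    if params.min_cluster_size > 1:
        labels = _force_assign_small(index, labels, rare_ids,
                                     params.min_cluster_size)

    return replace(assignment, labels=labels, stage="merged")


def _force_assign_small(index: NeighborIndex, labels: np.ndarray,
                        rare_ids: set[int], min_size: int) -> np.ndarray:
    """Optionally absorb sub-threshold non-rare clusters into their
    most-connected non-rare neighbor, bypassing the Q_c conditions."""
    labels = labels.copy()
    while True:
        cross = _cross_edges(index, labels)
        sizes = {int(c): int(n) for c, n in
                 zip(*np.unique(labels, return_counts=True))}
        small = sorted(c for c in sizes
                       if c not in rare_ids and sizes[c] < min_size)
        moved = False
        for c in small:
            best, best_edges = None, 0
            for (a, b), cnt in cross.items():
                if a != c or b in rare_ids or b == c:
                    continue
                if cnt > best_edges or (cnt == best_edges and best is not None
                                        and b < best):
                    best, best_edges = b, cnt
            if best is None:
                continue
            labels[labels == c] = best
            moved = True
            break
        if not moved:
            break
    return labels


def _finalize(index: NeighborIndex, assignment: ClusterAssignment,
              rare_ids: set[int], q: QScores, params: RareQParams,
              cell_ids: np.ndarray) -> RareQResult:
    """Relabel clusters as contiguous integers from 0 and recompute
    per-cluster statistics."""
    old = np.unique(assignment.labels)
    remap = {int(o): i for i, o in enumerate(old)}
    labels = np.array([remap[int(l)] for l in assignment.labels],
                      dtype=np.int64)
    final = replace(assignment, labels=labels, stage="final")
    stats = cluster_stats(index, labels, q)
    rare = {remap[c] for c in rare_ids if c in remap}
    return RareQResult(assignment=final, cluster_stats=stats,
                       rare_cluster_ids=rare, params=params, q=q,
                       cell_ids=cell_ids)


def run_rareq(data, params: RareQParams | None = None) -> RareQResult:
    """End-to-end detector: kNN graph -> Q -> propagation -> voting ->
    rare retention -> merging.

    ``data`` is either an :class:`EmbeddingMatrix` (or plain coordinate
    array) or a prebuilt :class:`NeighborIndex`.
    """
    params = params or RareQParams()
    if isinstance(data, NeighborIndex):
        index = data
        if index.k_param < params.k_param and index.n_cells >= params.k_param:
            raise ValueError("inconsistent inputs: index capacity below k_param")
    else:
        if not isinstance(data, EmbeddingMatrix):
            data = EmbeddingMatrix.from_coords(np.asarray(data))
        if data.n_cells < params.k:
            raise ValueError("insufficient cells: fewer cells than k")
        index = build_knn(data, params.k_param)
    if index.n_cells < params.k:
        raise ValueError("insufficient cells: fewer cells than k")
    q = all_q(index, params.k)
    prop = propagate(index, q, params)
    voted = vote_refine(index, prop, params)
    stats = cluster_stats(index, voted.labels, q)
    rare = retain_rare(stats, params.q_threshold)
    merged = merge_clusters(index, voted, rare, params)
    return _finalize(index, merged, rare, q, params, index.cell_ids)
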