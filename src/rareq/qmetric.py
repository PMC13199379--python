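"""Neighborhood connectivity Q and cluster connectivity Q_c.

Q measures the cliquishness of a cell's size-k neighborhood on the
directed kNN graph: with S the cell plus its k-1 nearest neighbors,

    Q = ( number of directed edges i -> j with i, j in S ) / k^2,

where each member i contributes its self-edge plus its own k-1 nearest
out-edges, so exactly k^2 edges are examined and Q lies in [1/k, 1].
Tightly knit rare populations score near 1; cells embedded in a diffuse
majority leak edges out of S and score lower.

Q_c is the cluster-level analogue: for a cluster C of n cells the
out-edge budget per member is k.param, capped at min(n, 20), and

    Q_c = intra-cluster edges / (n * k.param).

A structurally forced sharper lower bound on Q also holds: the center's
k in-neighborhood edges and each member's self-edge are always internal,
so Q >= (2k - 1) / k^2.  Both bounds are reported; neither is enforced by
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knn import NeighborIndex, neighborhood

__all__ = ["QScores", "ClusterStats", "cell_q", "all_q", "cluster_q",
           "cluster_stats"]


@dataclass(frozen=True)
class QScores:
    """Per-cell neighborhood connectivity and the k it was computed at."""

    q: np.ndarray
    k: int

    @property
    def n_cells(self) -> int:
        return self.q.shape[0]

    def lower_bound(self) -> float:
        """Documented range lower bound 1/k."""
        return 1.0 / self.k

    def structural_lower_bound(self) -> float:
        """Tighter bound (2k-1)/k^2 forced by self-edges plus the
        center's own out-edges."""
        return (2 * self.k - 1) / self.k**2


@dataclass(frozen=True)
class ClusterStats:
    cluster_id: int
    members: np.ndarray
    n: int
    k_param_eff: int
    q_c: float
    mean_q: float


def _effective_budget(n: int) -> int:
    """Per-member out-edge budget for cluster connectivity: the cluster
    size below 20, else 20."""
    return n if n < 20 else 20


def cell_q(index: NeighborIndex, cell: int, k: int) -> float:
    """Connectivity of one cell's size-k neighborhood."""
    S = neighborhood(index, cell, k)
    in_S = np.zeros(index.n_cells, dtype=bool)
    in_S[S] = True
    total = 0
    for i in S:
        total += int(np.count_nonzero(in_S[index.out_edges(i, k)]))
    return total / (k * k)


def all_q(index: NeighborIndex, k: int = 6) -> QScores:
    """Q for every cell in one vectorized pass.

    k defaults to 6: a neighborhood small enough that populations of only
    a handful of cells can still saturate it.
    """
    if k > index.k_param or k > index.n_cells:
        raise ValueError("neighborhood exceeds index capacity")
    n = index.n_cells
    # out[i] = targets of cell i's first k directed edges (self at rank 0)
    out = np.empty((n, k), dtype=np.int64)
    out[:, 0] = np.arange(n)
    out[:, 1:] = index.neighbors[:, : k - 1]
    q = np.empty(n, dtype=np.float64)
    chunk = max(1, 4_000_000 // (k * k * k))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        S = out[start:stop]                      # (c, k) neighborhood members
        edges = out[S]                           # (c, k, k) their edge targets
        member = edges[:, :, :, None] == S[:, None, None, :]
        q[start:stop] = member.any(axis=3).sum(axis=(1, 2)) / (k * k)
    return QScores(q=q, k=k)


def cluster_q(index: NeighborIndex, members) -> float:
    """Internal connectivity Q_c of a set of cells.

    The per-member budget is min(n, 20); for n below 20 the neighbor list
    is simply truncated at n - 1 entries.
    """
    members = np.asarray(list(members) if not isinstance(members, np.ndarray)
                         else members, dtype=np.int64)
    n = members.shape[0]
    if n == 0:
        raise ValueError("empty cluster")
    budget = _effective_budget(n)
    if budget > index.k_param and n >= 20:
        raise ValueError("cluster budget exceeds index capacity")
    in_C = np.zeros(index.n_cells, dtype=bool)
    in_C[members] = True
    # self-edges are always internal; count list hits for the other
    # budget-1 out-edges (truncated at the index capacity)
    hits = n
    if budget > 1:
        lists = index.neighbors[members, : budget - 1]
        hits += int(np.count_nonzero(in_C[lists]))
    return hits / (n * budget)


def cluster_stats(index: NeighborIndex, labels: np.ndarray,
                  q: QScores) -> list[ClusterStats]:
    """Per-cluster size, effective budget, Q_c and mean member Q."""
    labels = np.asarray(labels)
    stats = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        n = members.shape[0]
        stats.append(ClusterStats(
            cluster_id=int(cid),
            members=members,
            n=n,
            k_param_eff=_effective_budget(n),
            q_c=cluster_q(index, members),
            mean_q=float(q.q[members].mean()),
        ))
    return stats
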