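"""Directed k-nearest-neighbor graph on a low-dimensional embedding.

Every edge query in the package goes through :class:`NeighborIndex`.  The
convention throughout: a cell's neighbor list *excludes* the cell itself,
and ``out_edges(i, m)`` reintroduces the self-edge at rank 0, so an
out-edge budget of ``m`` means the cell plus its ``m - 1`` nearest other
cells.  Distances are Euclidean in the embedding space; equal distances
are broken toward the smaller cell index so that the graph — and
everything downstream — is a pure function of ``(coords, k_param)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddingMatrix", "NeighborIndex", "build_knn", "neighborhood"]

#: above this many cells an approximate index may be used when requested
EXACT_THRESHOLD = 50_000

#: cells per chunk for the brute-force distance sweep (bounds peak memory)
_CHUNK = 1024


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Cells x dimensions coordinates with ordered, unique cell ids.

    The position of a cell id defines its 0-based index, which is the
    tie-breaking order used everywhere else.
    """

    coords: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2:
            raise ValueError("invalid embedding: coords must be 2-D (cells x dims)")
        if coords.shape[0] < 2:
            raise ValueError("insufficient cells: need at least 2")
        if coords.shape[1] < 1:
            raise ValueError("invalid embedding: need at least 1 dimension")
        if not np.all(np.isfinite(coords)):
            raise ValueError("invalid embedding: non-finite coordinates")
        ids = np.asarray(self.cell_ids)
        if ids.shape[0] != coords.shape[0]:
            raise ValueError("inconsistent inputs: cell_ids length != n_cells")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("invalid embedding: duplicate cell ids")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cell_ids", ids)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_coords(cls, coords: np.ndarray, cell_ids=None) -> "EmbeddingMatrix":
        coords = np.asarray(coords, dtype=np.float64)
        if cell_ids is None:
            cell_ids = np.array([f"cell_{i}" for i in range(coords.shape[0])])
        return cls(coords=coords, cell_ids=np.asarray(cell_ids))


@dataclass(frozen=True)
class NeighborIndex:
    """Per-cell ordered nearest-neighbor lists (self excluded).

    ``neighbors[i]`` holds the ``min(k_param - 1, n_cells - 1)`` nearest
    other cells of cell ``i`` by ascending Euclidean distance;
    ``distances[i]`` matches.  ``approximate`` records whether an
    approximate search built the lists.
    """

    neighbors: np.ndarray
    distances: np.ndarray
    k_param: int
    cell_ids: np.ndarray
    approximate: bool = field(default=False)

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]

    def out_edges(self, cell: int, m: int) -> np.ndarray:
        """Targets of cell's first ``m`` directed edges: itself then its
        ``m - 1`` nearest other cells."""
        if not 1 <= m <= min(self.k_param, self.n_cells):
            raise ValueError("neighborhood exceeds index capacity")
        out = np.empty(m, dtype=np.int64)
        out[0] = cell
        out[1:] = self.neighbors[cell, : m - 1]
        return out


def _exact_lists(coords: np.ndarray, k_param: int):
    """Chunked brute-force kNN with a stable sort: ties in distance fall
    back to ascending cell index automatically."""
    n = coords.shape[0]
    n_keep = min(k_param - 1, n - 1)
    sq = np.einsum("ij,ij->i", coords, coords)
    nbr = np.empty((n, n_keep), dtype=np.int64)
    dst = np.empty((n, n_keep), dtype=np.float64)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        block = coords[start:stop]
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * block @ coords.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[rows - start, rows] = np.inf  # exclude self
        if n_keep < n - 1:
            # cheap pre-selection, then an exact stable sort of the head
            part = np.argpartition(d2, n_keep, axis=1)[:, : n_keep + 1]
        else:
            part = np.broadcast_to(np.arange(n), (stop - start, n))
        part_d = np.take_along_axis(d2, part, axis=1)
        # order candidates by (distance, index): stable sort on distance of
        # index-sorted candidates
        idx_order = np.argsort(part, axis=1, kind="stable")
        part_sorted = np.take_along_axis(part, idx_order, axis=1)
        d_sorted = np.take_along_axis(part_d, idx_order, axis=1)
        final = np.argsort(d_sorted, axis=1, kind="stable")[:, :n_keep]
        nbr[start:stop] = np.take_along_axis(part_sorted, final, axis=1)
        dst[start:stop] = np.sqrt(np.take_along_axis(d_sorted, final, axis=1))
    return nbr, dst


def _approx_lists(coords: np.ndarray, k_param: int, n: int):
    try:
        from pynndescent import NNDescent
    except ImportError:  # fall back to the exact sweep
        return _exact_lists(coords, k_param) + (False,)
    index = NNDescent(coords, n_neighbors=min(k_param + 10, n), metric="euclidean",
                      random_state=0)
    nbr, dst = index.neighbor_graph
    keep = min(k_param - 1, n - 1)
    # drop self (rank 0 in pynndescent's self-inclusive lists)
    rows = []
    drows = []
    for i in range(n):
        mask = nbr[i] != i
        rows.append(nbr[i][mask][:keep])
        drows.append(dst[i][mask][:keep])
    return np.asarray(rows, dtype=np.int64), np.asarray(drows, dtype=np.float64), True


def build_knn(embedding: EmbeddingMatrix, k_param: int = 20, *,
              exact_threshold: int = EXACT_THRESHOLD,
              method: str = "auto") -> NeighborIndex:
    """Build the directed kNN index of an embedding.

    Parameters
    ----------
    embedding
        Validated cells x dims coordinates.
    k_param
        Neighbor-list capacity (cell itself plus ``k_param - 1`` others),
        default 20.
    exact_threshold
        Exact brute-force search is used up to this many cells; above it
        an approximate index is allowed (``method="auto"``).
    method
        ``"auto"``, ``"exact"`` or ``"approx"``.

    Exact mode is bit-deterministic, with distance ties broken toward the
    smaller cell index.
    """
    if not isinstance(embedding, EmbeddingMatrix):
        embedding = EmbeddingMatrix.from_coords(np.asarray(embedding))
    if k_param < 2:
        raise ValueError("invalid k_param: must be >= 2")
    n = embedding.n_cells
    use_approx = method == "approx" or (method == "auto" and n > exact_threshold)
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    if use_approx:
        nbr, dst, ok = _approx_lists(embedding.coords, k_param, n)
        return NeighborIndex(neighbors=nbr, distances=dst, k_param=k_param,
                             cell_ids=embedding.cell_ids, approximate=ok)
    nbr, dst = _exact_lists(embedding.coords, k_param)
    return NeighborIndex(neighbors=nbr, distances=dst, k_param=k_param,
                         cell_ids=embedding.cell_ids, approximate=False)


def neighborhood(index: NeighborIndex, cell: int, k: int) -> np.ndarray:
    """The size-``k`` neighborhood of a cell: itself followed by its
    ``k - 1`` nearest other cells."""
    if k > index.k_param or k > index.n_cells:
        raise ValueError("neighborhood exceeds index capacity")
    if k < 1:
        raise ValueError("invalid neighborhood size")
    return index.out_edges(cell, k)
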