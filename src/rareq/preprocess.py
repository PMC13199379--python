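"""Raw counts to embedding: log-normalize, HVG selection, scale, PCA.

This is the standard scRNA-seq preparation chain the detector consumes:
per-cell library-size normalization to a fixed scale factor followed by
log1p, selection of highly variable genes by standardized dispersion,
per-gene z-scaling (clipped), and PCA with a deterministic sign
convention.  For low-feature spatial panels (a few hundred genes) use a
scale factor of 80 and ``n_hvg="all"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .knn import EmbeddingMatrix

__all__ = ["CountMatrix", "PreprocessParams", "lognormalize", "select_hvg",
           "pca_embed", "preprocess_counts"]


@dataclass(frozen=True)
class CountMatrix:
    """Cells x genes non-negative counts with unique ids.

    ``counts`` may be dense or scipy sparse; stored as given.
    """

    counts: object
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        counts = self.counts
        if not sp.issparse(counts):
            counts = np.asarray(counts)
            if np.any(counts < 0):
                raise ValueError("invalid counts: negative entries")
        else:
            if counts.nnz and counts.min() < 0:
                raise ValueError("invalid counts: negative entries")
        cells = np.asarray(self.cell_ids)
        genes = np.asarray(self.gene_ids)
        if counts.shape != (len(cells), len(genes)):
            raise ValueError("inconsistent inputs: shape vs id lengths")
        for ids, what in ((cells, "cell"), (genes, "gene")):
            if len(np.unique(ids)) != len(ids):
                raise ValueError(f"invalid counts: duplicate {what} ids")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "cell_ids", cells)
        object.__setattr__(self, "gene_ids", genes)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.float64)
        return np.asarray(self.counts, dtype=np.float64)


@dataclass(frozen=True)
class PreprocessParams:
    scale_factor: float = 10_000.0
    n_hvg: int | str = 2_000
    n_pcs: int = 50
    clip: float = 10.0
    log_base: float | None = None  # None = natural log

    def __post_init__(self) -> None:
        if self.scale_factor <= 0 or self.n_pcs <= 0 or self.clip <= 0:
            raise ValueError("invalid params: sizes must be positive")
        if self.n_hvg != "all" and int(self.n_hvg) <= 0:
            raise ValueError("invalid params: n_hvg must be positive or 'all'")


def lognormalize(counts: CountMatrix, scale_factor: float = 10_000.0,
                 log_base: float | None = None) -> np.ndarray:
    """Library-size normalize each cell to ``scale_factor`` total and
    apply log(1 + x).  Zero counts stay exactly zero, and scaling every
    count of a cell by a constant leaves its normalized row unchanged."""
    X = counts.dense()
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("empty cell: a cell has zero total counts")
    out = np.log1p(scale_factor * X / totals[:, None])
    if log_base is not None:
        out /= np.log(log_base)
    return out


def select_hvg(normalized: np.ndarray, n_hvg: int | str = 2_000,
               n_bins: int = 20) -> np.ndarray:
    """Indices of the most highly variable genes.

    Dispersion = variance / mean of the normalized values; genes are
    binned by mean expression and dispersions z-scored within each bin
    (mean-variance standardization), then ranked.  Ties and the final
    ordering are broken by ascending gene index.  ``"all"`` keeps every
    gene.
    """
    n_genes = normalized.shape[1]
    if n_hvg == "all" or int(n_hvg) >= n_genes:
        return np.arange(n_genes)
    n_hvg = int(n_hvg)
    mean = normalized.mean(axis=0)
    var = normalized.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # standardize dispersion within mean-expression bins
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros(n_genes)
    for b in bins:
        if b.size == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf  # constant genes rank below everything variable
    ranked = np.lexsort((np.arange(n_genes), -z))
    return np.sort(ranked[:n_hvg])


def pca_embed(normalized: np.ndarray, gene_subset: np.ndarray | None = None,
              n_pcs: int = 50, clip: float = 10.0,
              cell_ids: np.ndarray | None = None) -> EmbeddingMatrix:
    """Z-scale the selected genes (clipped at +-``clip``) and project onto
    the top principal components.

    Each component's sign is fixed so that its largest-magnitude loading
    is positive, making repeated runs bit-identical.
    """
    X = normalized if gene_subset is None else normalized[:, gene_subset]
    n_cells, n_feat = X.shape
    if n_pcs > min(n_cells, n_feat):
        raise ValueError("rank deficient: n_pcs exceeds data rank")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    solver = "full" if min(n_cells, n_feat) <= 1_000 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(Z)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(pca.components_[
        np.arange(n_pcs), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores *= flip
    if cell_ids is None:
        cell_ids = np.array([f"cell_{i}" for i in range(n_cells)])
    return EmbeddingMatrix(coords=scores, cell_ids=np.asarray(cell_ids))


def preprocess_counts(counts: CountMatrix,
                      params: PreprocessParams | None = None) -> EmbeddingMatrix:
    """The full chain: lognormalize -> HVG -> scale -> PCA."""
    params = params or PreprocessParams()
    norm = lognormalize(counts, params.scale_factor, params.log_base)
    hvg = select_hvg(norm, params.n_hvg)
    n_pcs = min(params.n_pcs, counts.n_cells - 1, hvg.shape[0])
    return pca_embed(norm, hvg, n_pcs, params.clip, cell_ids=counts.cell_ids)
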