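"""Synthetic data generators for benchmarking the detector.

Two families of inputs are produced:

* **Embedding blobs** — isotropic Gaussian clouds with controlled type
  proportions and center separation, standing in for a preprocessed
  low-dimensional embedding with a planted rare population.

* **Gamma-Poisson counts** — a splatter-style generative model of UMI
  counts: gene base means drawn from a Gamma, group-wise differential
  expression applied as log-normal fold factors with random sign,
  log-normal library sizes, Poisson sampling.  On top of it sit the
  benchmark constructions: label-stratified down-sampling with a fixed
  rare quota, DEG titration into a null matrix, fold-change perturbation
  of target cells, and a multi-scale series with a fixed number of rare
  cells.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knn import EmbeddingMatrix
from .preprocess import CountMatrix

__all__ = ["BlobSpec", "SplatLikeParams", "make_blobs", "simulate_counts",
           "downsample_by_type", "deg_titration", "perturb_upregulate",
           "multiscale_series"]


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` units proportional to
    ``proportions``: floor the quotas, then hand leftover units to the
    largest fractional remainders (ties toward the lower index)."""
    proportions = np.asarray(proportions, dtype=np.float64)
    quota = proportions / proportions.sum() * total
    counts = np.floor(quota).astype(np.int64)
    remainder = quota - counts
    short = total - counts.sum()
    order = np.lexsort((np.arange(len(quota)), -remainder))
    counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class BlobSpec:
    """Gaussian-cloud embedding with planted type proportions.

    ``separation`` is the pairwise distance between type centers in
    units of the within-type standard deviation (which is 1).
    """

    n_cells: int = 2_000
    proportions: tuple = (0.99, 0.01)
    separation: float = 10.0
    n_dims: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=np.float64)
        if np.any(props <= 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError("invalid proportions: must be positive, sum 1")
        if np.any(props * self.n_cells < 1):
            raise ValueError("rare type too small: expected count < 1")


def make_blobs(spec: BlobSpec) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Isotropic Gaussian clouds; returns (embedding, true type labels).

    Per-type counts come from largest-remainder rounding of the
    proportions, so a 1% type in 2,000 cells yields exactly 20 cells.
    """
    rng = np.random.default_rng(spec.seed)
    n_types = len(spec.proportions)
    counts = largest_remainder(np.asarray(spec.proportions), spec.n_cells)
    if spec.n_dims >= n_types:
        centers = np.zeros((n_types, spec.n_dims))
        centers[np.arange(n_types), np.arange(n_types)] = \
            spec.separation / np.sqrt(2.0)
    else:  # fall back to random directions when dims are scarce
        directions = rng.standard_normal((n_types, spec.n_dims))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        centers = directions * spec.separation / np.sqrt(2.0)
    coords = []
    labels = []
    for t, c in enumerate(counts):
        coords.append(centers[t] + rng.standard_normal((c, spec.n_dims)))
        labels.extend([f"type_{t}"] * c)
    embedding = EmbeddingMatrix.from_coords(np.concatenate(coords, axis=0))
    return embedding, np.asarray(labels)


@dataclass(frozen=True)
class SplatLikeParams:
    """Gamma-Poisson group simulation parameters.

    Defaults follow the perturbation benchmark setting: 1,500 cells,
    5,000 genes, a 99/1 major/rare split, DE probability 0.4 per group
    with log-normal fold factors exp(+-N(0.4, 0.8)), no outlier genes.
    """

    n_genes: int = 5_000
    group_prob: tuple = (0.99, 0.01)
    de_prob: tuple = (0.4, 0.4)
    de_facLoc: float = 0.4
    de_facScale: float = 0.8
    batch_cells: int = 1_500
    out_prob: float = 0.0
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.group_prob, dtype=np.float64)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("invalid params: group_prob must sum to 1")
        de = np.asarray(self.de_prob, dtype=np.float64)
        if de.shape[0] != probs.shape[0] or np.any((de < 0) | (de > 1)):
            raise ValueError("invalid params: de_prob out of range")
        if self.out_prob != 0.0:
            raise NotImplementedError("not implemented: out_prob must be 0")


def simulate_counts(params: SplatLikeParams,
                    group_sizes: np.ndarray | None = None,
                    return_details: bool = False):
    """Gamma-Poisson counts with group-wise log-normal DE factors.

    Generative model: base gene means ~ Gamma(shape, rate); per group
    each gene is DE with probability ``de_prob[g]`` and its mean is
    multiplied by exp(s * N(de_facLoc, de_facScale)) with s = +-1
    equiprobably (symmetric up/down regulation); per-cell library sizes
    are log-normal; group expected expression is renormalized to sum to
    the library size; counts ~ Poisson.  Group membership is multinomial
    unless ``group_sizes`` forces exact per-group counts.

    Returns (CountMatrix, labels); with ``return_details`` also a dict
    holding the base means and per-group DE fold factors (``de_facs``,
    genes x groups, 1.0 for non-DE genes).
    """
    rng = np.random.default_rng(params.seed)
    n_groups = len(params.group_prob)
    if group_sizes is None:
        counts_per_group = rng.multinomial(
            params.batch_cells, np.asarray(params.group_prob))
    else:
        counts_per_group = np.asarray(group_sizes, dtype=np.int64)
        if counts_per_group.shape[0] != n_groups:
            raise ValueError("invalid params: group_sizes length mismatch")
    n_cells = int(counts_per_group.sum())

    base = rng.gamma(params.mean_shape, 1.0 / params.mean_rate,
                     size=params.n_genes)
    de_facs = np.ones((params.n_genes, n_groups))
    for g in range(n_groups):
        is_de = rng.random(params.n_genes) < params.de_prob[g]
        mags = rng.normal(params.de_facLoc, params.de_facScale,
                          size=params.n_genes)
        signs = np.where(rng.random(params.n_genes) < 0.5, 1.0, -1.0)
        de_facs[is_de, g] = np.exp(signs[is_de] * mags[is_de])

    group_means = base[:, None] * de_facs              # genes x groups
    probs = group_means / group_means.sum(axis=0, keepdims=True)
    libs = rng.lognormal(params.lib_loc, params.lib_scale, size=n_cells)

    labels = np.repeat([f"group_{g}" for g in range(n_groups)],
                       counts_per_group)
    group_of = np.repeat(np.arange(n_groups), counts_per_group)
    X = rng.poisson(libs[:, None] * probs[:, group_of].T)
    cm = CountMatrix(
        counts=X.astype(np.int64),
        cell_ids=np.array([f"cell_{i}" for i in range(n_cells)]),
        gene_ids=np.array([f"gene_{j}" for j in range(params.n_genes)]))
    if return_details:
        return cm, labels, {"base_means": base, "de_facs": de_facs}
    return cm, labels


def downsample_by_type(labels: np.ndarray, major_types, rare_types,
                       total: int, rare_count: int, seed: int) -> np.ndarray:
    """Stratified down-sample: exactly ``rare_count`` cells per rare
    type, the remainder split over the major types proportionally to
    their source frequencies (largest-remainder).  Returns sorted cell
    indices, sampled without replacement."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rare_types = list(rare_types)
    major_types = list(major_types)
    n_major_total = total - rare_count * len(rare_types)
    if n_major_total < len(major_types):
        raise ValueError("cannot satisfy quota: total too small")
    major_freq = np.array([np.count_nonzero(labels == t)
                           for t in major_types], dtype=np.float64)
    if np.any(major_freq == 0):
        raise ValueError("cannot satisfy quota: missing major type")
    major_quota = largest_remainder(major_freq, n_major_total)
    chosen = []
    for t, quota in zip(rare_types + major_types,
                        [rare_count] * len(rare_types) + list(major_quota)):
        pool = np.flatnonzero(labels == t)
        if pool.shape[0] < quota:
            raise ValueError(f"cannot satisfy quota: not enough {t!r} cells")
        chosen.append(rng.choice(pool, size=quota, replace=False))
    return np.sort(np.concatenate(chosen))


def deg_titration(null_counts: CountMatrix, deg_rows: CountMatrix,
                  r: int, seed: int) -> CountMatrix:
    """Replace ``r`` randomly chosen gene rows of a null (no-DE) matrix
    with ``r`` randomly chosen pre-identified DEG rows (cells aligned).

    The replaced and inserted sets are nested across increasing ``r`` at
    a fixed seed: both pools are permuted once and prefixes taken, so a
    titration sweep adds genes monotonically.
    """
    if null_counts.n_cells != deg_rows.n_cells:
        raise ValueError("inconsistent inputs: cell dimensions differ")
    if r > deg_rows.n_genes or r > null_counts.n_genes:
        raise ValueError("titration exceeds pool")
    rng = np.random.default_rng(seed)
    targets = rng.permutation(null_counts.n_genes)[:r]
    sources = rng.permutation(deg_rows.n_genes)[:r]
    X = null_counts.dense().copy()
    genes = null_counts.gene_ids.astype(object).copy()
    deg_X = deg_rows.dense()
    X[:, targets] = deg_X[:, sources]
    genes[targets] = deg_rows.gene_ids[sources]
    # keep ids unique if a DEG id collides with a surviving null id
    seen = set()
    for j, g in enumerate(genes):
        while g in seen:
            g = f"{g}_dup"
        seen.add(g)
        genes[j] = g
    return CountMatrix(counts=X.astype(np.int64),
                       cell_ids=null_counts.cell_ids,
                       gene_ids=np.asarray(genes))


def perturb_upregulate(counts: CountMatrix, target_cells, n_genes: int,
                       fold: float = 3.0, seed: int = 0) -> CountMatrix:
    """Multiply the counts of ``n_genes`` randomly chosen genes by
    ``fold`` (rounded to the nearest integer) in the target cells only."""
    target_cells = np.asarray(list(target_cells), dtype=np.int64)
    if target_cells.size == 0:
        raise ValueError("no target cells")
    if n_genes > counts.n_genes:
        raise ValueError("invalid params: n_genes exceeds gene count")
    rng = np.random.default_rng(seed)
    genes = rng.permutation(counts.n_genes)[:n_genes]
    X = counts.dense().copy()
    X[np.ix_(target_cells, genes)] = np.rint(
        X[np.ix_(target_cells, genes)] * fold)
    return CountMatrix(counts=X.astype(np.int64), cell_ids=counts.cell_ids,
                       gene_ids=counts.gene_ids)


def multiscale_series(scales, rare_n: int = 10,
                      base_params: SplatLikeParams | None = None,
                      seed: int = 0) -> list:
    """One dataset per scale with *exactly* ``rare_n`` rare cells (group
    sizes forced, not multinomial) and the majority making up the rest.

    Returns a list of (CountMatrix, labels) tuples.
    """
    base_params = base_params or SplatLikeParams()
    out = []
    for i, scale in enumerate(scales):
        if scale <= rare_n:
            raise ValueError("invalid scale: must exceed rare_n")
        params = SplatLikeParams(
            n_genes=base_params.n_genes,
            group_prob=(1.0 - rare_n / scale, rare_n / scale),
            de_prob=base_params.de_prob,
            de_facLoc=base_params.de_facLoc,
            de_facScale=base_params.de_facScale,
            batch_cells=scale,
            out_prob=base_params.out_prob,
            mean_shape=base_params.mean_shape,
            mean_rate=base_params.mean_rate,
            lib_loc=base_params.lib_loc,
            lib_scale=base_params.lib_scale,
            seed=seed + i)
        cm, labels = simulate_counts(
            params, group_sizes=np.array([scale - rare_n, rare_n]))
        out.append((cm, labels))
    return out
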