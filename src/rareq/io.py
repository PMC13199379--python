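"""File input/output: counts, embeddings, labels, results.

On-disk conventions: counts arrive either as a Matrix Market triplet
with companion barcode/feature files (CellRanger layout, features x
cells, 1-based indices per the Matrix Market standard) or as dense
delimited text (cells x genes, first column the cell id).  Embeddings
and labels are delimited text keyed by cell id, never by position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .clustering import RareQResult
from .knn import EmbeddingMatrix, NeighborIndex
from .preprocess import CountMatrix

__all__ = ["read_counts", "write_counts", "read_embedding", "write_embedding",
           "read_labels", "write_labels", "write_result",
           "save_neighbor_index", "load_neighbor_index"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path, layout: str = "mtx-triplet") -> CountMatrix:
    """Read a count matrix.

    ``mtx-triplet``: ``path`` is a directory holding ``matrix.mtx``
    (features x cells), ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``); the matrix is transposed to cells x genes.
    ``dense-delimited``: a TSV/CSV with a header row of gene ids and the
    cell id in the first column.
    """
    path = Path(path)
    if layout == "mtx-triplet":
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists():
            features = path / "genes.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"parse error: missing {f.name}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:
            raise ValueError(f"parse error: {exc}") from exc
        cells = pd.read_csv(barcodes, header=None, sep="\t")[0].to_numpy()
        genes = pd.read_csv(features, header=None, sep="\t")[0].to_numpy()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError("inconsistent inputs: matrix shape vs id files")
        counts = sp.csr_matrix(mat.T)
        return CountMatrix(counts=counts, cell_ids=cells, gene_ids=genes)
    if layout == "dense-delimited":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        return CountMatrix(counts=df.to_numpy(),
                           cell_ids=df.index.to_numpy().astype(str),
                           gene_ids=df.columns.to_numpy().astype(str))
    raise ValueError(f"unknown layout {layout!r}")


def write_counts(counts: CountMatrix, path, layout: str = "mtx-triplet") -> None:
    path = Path(path)
    if layout == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        mat = counts.counts if sp.issparse(counts.counts) else \
            sp.csr_matrix(counts.counts)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(mat.T))
        pd.Series(counts.cell_ids).to_csv(path / "barcodes.tsv",
                                          index=False, header=False)
        pd.Series(counts.gene_ids).to_csv(path / "features.tsv",
                                          index=False, header=False)
        return
    if layout == "dense-delimited":
        df = pd.DataFrame(counts.dense(), index=counts.cell_ids,
                          columns=counts.gene_ids)
        df.to_csv(path, sep=_sep_for(path))
        return
    raise ValueError(f"unknown layout {layout!r}")


def read_embedding(path) -> EmbeddingMatrix:
    """Delimited text, rows = cells, first column the cell id; a single
    header line is detected and skipped."""
    path = Path(path)
    sep = _sep_for(path)
    first = path.open().readline().rstrip("\n").split(sep)
    has_header = False
    for tok in first[1:]:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     index_col=0)
    coords = df.to_numpy(dtype=np.float64)
    return EmbeddingMatrix(coords=coords,
                           cell_ids=df.index.to_numpy().astype(str))


def write_embedding(embedding: EmbeddingMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(embedding.coords, index=embedding.cell_ids,
                      columns=[f"dim_{i}" for i in range(embedding.n_dims)])
    df.index.name = "cell_id"
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column cell_id -> label file; returns (cell_ids, labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     comment="#")
    if df.shape[1] != 2:
        raise ValueError("parse error: expected two columns")
    if tuple(df.iloc[0]) == ("cell_id", "label"):
        df = df.iloc[1:]
    return df[0].to_numpy(), df[1].to_numpy()


def write_labels(cell_ids, labels, path) -> None:
    pd.DataFrame({0: cell_ids, 1: labels}).to_csv(
        Path(path), sep="\t", index=False, header=False)


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def write_result(result: RareQResult, outdir) -> dict:
    """Write the per-cell table, per-cluster table and run metadata.

    Returns the paths written.  Rare flags are consistent between the
    two tables by construction.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"io error: {exc}") from exc
    rare = result.is_rare()
    cells = pd.DataFrame({
        "cell_id": result.cell_ids,
        "cluster": result.labels,
        "q": result.q.q,
        "is_rare": rare.astype(int),
    })
    cell_path = outdir / "cells.tsv"
    cells.to_csv(cell_path, sep="\t", index=False)
    clusters = pd.DataFrame([{
        "cluster": s.cluster_id,
        "n": s.n,
        "mean_q": s.mean_q,
        "q_c": s.q_c,
        "is_rare": int(s.cluster_id in result.rare_cluster_ids),
    } for s in result.cluster_stats])
    cluster_path = outdir / "clusters.tsv"
    clusters.to_csv(cluster_path, sep="\t", index=False)
    meta = {
        "params": asdict(result.params),
        "n_cells": int(result.assignment.n_cells),
        "n_clusters": int(result.assignment.n_clusters),
        "n_rare_clusters": len(result.rare_cluster_ids),
        "labels_hash": _hash_array(result.labels),
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return {"cells": cell_path, "clusters": cluster_path, "metadata": meta_path}


def save_neighbor_index(index: NeighborIndex, path) -> None:
    """Binary cache of a NeighborIndex (npz)."""
    np.savez_compressed(Path(path), neighbors=index.neighbors,
                        distances=index.distances,
                        k_param=np.int64(index.k_param),
                        cell_ids=index.cell_ids.astype(str),
                        approximate=np.bool_(index.approximate))


def load_neighbor_index(path) -> NeighborIndex:
    with np.load(Path(path), allow_pickle=False) as z:
        return NeighborIndex(neighbors=z["neighbors"],
                             distances=z["distances"],
                             k_param=int(z["k_param"]),
                             cell_ids=z["cell_ids"],
                             approximate=bool(z["approximate"]))
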