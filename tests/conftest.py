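import numpy as np
import pytest

import rareq


@pytest.fixture(scope="session")
def line10_index():
    """10 collinear points at x = 0..9, capacity 4."""
    emb = rareq.EmbeddingMatrix.from_coords(
        np.arange(10, dtype=float)[:, None])
    return rareq.build_knn(emb, k_param=4)


@pytest.fixture(scope="session")
def line10_index_cap20():
    emb = rareq.EmbeddingMatrix.from_coords(
        np.arange(10, dtype=float)[:, None])
    return rareq.build_knn(emb, k_param=10)


@pytest.fixture(scope="session")
def hexpair_index():
    """Two regular hexagons of radius 0.1, centers 100 apart: two tight,
    mutually distant 6-cliques."""
    angles = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    hexagon = 0.1 * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    coords = np.concatenate([hexagon, hexagon + [100.0, 0.0]])
    emb = rareq.EmbeddingMatrix.from_coords(coords)
    return rareq.build_knn(emb, k_param=12)


@pytest.fixture(scope="session")
def planted_blobs():
    """2,000-cell embedding: 99% diffuse majority + 1% tight rare blob,
    widely separated (fixed seed)."""
    spec = rareq.BlobSpec(n_cells=2_000, proportions=(0.99, 0.01),
                          separation=10.0, n_dims=10, seed=42)
    return rareq.make_blobs(spec)


@pytest.fixture(scope="session")
def planted_result(planted_blobs):
    emb, labels = planted_blobs
    return rareq.run_rareq(emb), labels
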