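"""Shared numerics: seeding, kNN graphs, dense/sparse helpers."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Derive an independent generator for a named pipeline stage.

    All stage seeds descend from one global seed so that the whole run is
    reproducible while stages stay decoupled (adding a draw in one stage
    does not shift another stage's stream).
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def mad(x: np.ndarray) -> float:
    """Median absolute deviation, median(|x - median(x)|), unscaled."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def knn_indices(embedding: np.ndarray, k: int, include_self: bool = False):
    """k nearest neighbors in Euclidean space.

    Returns (indices, distances), each (n, k); self excluded unless asked.
    """
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    if include_self:
        return idx[:, :k], dist[:, :k]
    # self appears at most once per row; where absent (duplicate points), drop
    # the farthest neighbor instead so every row keeps exactly k entries
    keep = idx != np.arange(n)[:, None]
    keep[keep.all(axis=1), -1] = False
    return idx[keep].reshape(n, k), dist[keep].reshape(n, k)


def row_normalize(m: sp.spmatrix) -> sp.csr_matrix:
    """Scale each row of a nonnegative sparse matrix to sum to 1."""
    m = sp.csr_matrix(m, dtype=float)
    s = np.asarray(m.sum(axis=1)).ravel()
    if np.any(s <= 0):
        raise ValueError("row_normalize: zero row encountered")
    d = sp.diags(1.0 / s)
    return sp.csr_matrix(d @ m)


def as_dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def connected_components_report(adj: sp.spmatrix):
    """(n_components, labels) of the undirected graph underlying ``adj``."""
    n, labels = sp.csgraph.connected_components(adj, directed=False)
    return n, labels
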