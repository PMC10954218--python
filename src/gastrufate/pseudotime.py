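"""Diffusion transition probabilities and probabilistic-flood pseudotime.

Pseudotime is defined operationally: from a set of root cells, a
probabilistic breadth-first flood expands over the cell-cell transition
graph — at each iteration an unvisited cell becomes visited with
probability min(1, sum of transition mass arriving from already-visited
cells) — and a cell's pseudotime is the mean iteration at which it was
first visited over many floods, min-max normalized to [0, 1].  Root cells
are visited at iteration 0, hence pseudotime exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from ._utils import child_rng, knn_indices


@dataclass
class TransitionMatrix:
    """Row-stochastic sparse transition probabilities over cells."""

    T: sp.csr_matrix
    k_neighbors: int
    bandwidth: float

    def __post_init__(self):
        s = np.asarray(self.T.sum(axis=1)).ravel()
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")


def diffusion_transitions(
    embedding: np.ndarray,
    k_neighbors: int = 15,
    bandwidth: float | None = None,
) -> TransitionMatrix:
    """Gaussian-kernel diffusion transition probabilities on the kNN graph.

    The kNN distance graph is symmetrized (union of directed edges), a
    Gaussian kernel exp(-d^2 / (2 sigma^2)) applied (sigma defaults to the
    median kNN distance), the kernel density-normalized (dividing by the
    product of row sums, removing sampling-density bias) and finally
    row-normalized.  Self-transitions are excluded.  Raises on a
    disconnected graph, listing component sizes.
    """
    n = embedding.shape[0]
    idx, dist = knn_indices(embedding, k_neighbors)
    rows = np.repeat(np.arange(n), k_neighbors)
    D = sp.csr_matrix((dist.ravel(), (rows, idx.ravel())), shape=(n, n))
    # symmetrize: keep an edge if present in either direction
    D = D.maximum(D.T)

    n_comp, comp = sp.csgraph.connected_components(D, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(f"kNN graph is disconnected: {n_comp} components "
                         f"with sizes {sorted(sizes.tolist(), reverse=True)}")

    sigma = float(bandwidth) if bandwidth is not None else float(np.median(dist))
    W = D.copy()
    W.data = np.exp(-(W.data ** 2) / (2.0 * sigma ** 2))
    # density normalization (anisotropic alpha = 1)
    q = np.asarray(W.sum(axis=1)).ravel()
    Dq = sp.diags(1.0 / q)
    W = Dq @ W @ Dq
    s = np.asarray(W.sum(axis=1)).ravel()
    T = sp.csr_matrix(sp.diags(1.0 / s) @ W)
    return TransitionMatrix(T=T, k_neighbors=k_neighbors, bandwidth=sigma)


@dataclass
class PseudotimeResult:
    """Mean visiting iteration per cell, normalized to [0, 1]."""

    pseudotime: np.ndarray
    visit_iterations: np.ndarray  # floods x cells, raw iteration indices
    n_floods: int

    def as_series(self, index=None) -> pd.Series:
        return pd.Series(self.pseudotime, index=index, name="pseudotime")


def flood_pseudotime(
    tm: TransitionMatrix,
    roots: np.ndarray,
    n_floods: int = 100,
    seed: int = 0,
) -> PseudotimeResult:
    """Probabilistic breadth-first flood from root cells.

    Per flood, iteration 0 visits the roots; at iteration t each unvisited
    cell i is visited with probability min(1, sum_{j visited} T[i, j]).
    Pseudotime is the mean visiting iteration over floods, min-max scaled.
    Deterministic under ``seed``; iterations capped at 10 * n_cells.
    """
    T = tm.T
    n = T.shape[0]
    roots = np.asarray(roots)
    if roots.dtype == bool:
        roots = np.flatnonzero(roots)
    if len(roots) == 0:
        raise ValueError("root set is empty")
    rng = child_rng(seed, 5)
    cap = 10 * n
    Tc = T.tocsc()
    visits = np.empty((n_floods, n), dtype=float)
    for f in range(n_floods):
        visited = np.zeros(n, dtype=bool)
        visited[roots] = True
        it = np.zeros(n)
        # incoming transition mass from the visited set, updated incrementally
        mass = np.asarray(Tc[:, roots].sum(axis=1)).ravel()
        step = 0
        while not visited.all():
            step += 1
            if step > cap:
                raise RuntimeError("flood did not visit every cell within the cap")
            p = np.minimum(mass, 1.0)
            newly = (~visited) & (rng.random(n) < p)
            if newly.any():
                it[newly] = step
                visited |= newly
                mass += np.asarray(Tc[:, newly].sum(axis=1)).ravel()
        visits[f] = it
    mean_it = visits.mean(axis=0)
    rng_span = mean_it.max() - mean_it.min()
    pt = (mean_it - mean_it.min()) / rng_span if rng_span > 0 else np.zeros(n)
    return PseudotimeResult(pseudotime=pt, visit_iterations=visits, n_floods=n_floods)


def root_cells_by_markers(E: np.ndarray, gene_names, marker_genes,
                          n_roots: int = 20) -> np.ndarray:
    """Indices of the cells with highest mean expression of root markers."""
    gene_names = list(gene_names)
    idx = [gene_names.index(g) for g in marker_genes if g in gene_names]
    if not idx:
        raise ValueError("no root marker genes found in the matrix")
    score = np.asarray(E)[:, idx].mean(axis=1)
    return np.argsort(-score, kind="stable")[:n_roots]


def compare_pseudotime(
    pt_a: np.ndarray,
    pt_b: np.ndarray,
    labels_a: np.ndarray | None = None,
    labels_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-sample two-sided KS comparison of pseudotime distributions.

    With cell labels supplied, also compares each shared population
    separately (row per population plus the pooled "all" row).
    """
    pt_a, pt_b = np.asarray(pt_a, dtype=float), np.asarray(pt_b, dtype=float)
    if len(pt_a) < 10 or len(pt_b) < 10:
        raise ValueError("each sample needs at least 10 cells")
    rows = []

    def ks_row(name, x, y):
        res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
        rows.append({"group": name, "D": float(res.statistic),
                     "p": float(res.pvalue), "n_a": len(x), "n_b": len(y)})

    ks_row("all", pt_a, pt_b)
    if labels_a is not None and labels_b is not None:
        labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
        for pop in np.intersect1d(np.unique(labels_a), np.unique(labels_b)):
            x, y = pt_a[labels_a == pop], pt_b[labels_b == pop]
            if len(x) >= 10 and len(y) >= 10:
                ks_row(pop, x, y)
    return pd.DataFrame(rows).set_index("group")
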