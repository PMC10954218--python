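"""PCA, SNN-Louvain clustering sweep, and entropy-guided cluster-number choice.

The number of clusters is chosen from a clustering tree: Louvain labelings
at consecutive cluster counts are linked by the flow of cells from each
level-k cluster into each level-(k+1) cluster, and every child node is
scored by the Shannon entropy (bits) of its parent-origin proportions.  A
child drawn wholly from one parent has entropy 0; an even 50/50 split has
entropy 1 bit.  The chosen count is the largest level whose mean node
entropy stays below a threshold, i.e. the deepest split that is still
stable.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from ._utils import as_dense, knn_indices, mad

SNN_PRUNE = 1.0 / 15.0  # Jaccard weights below this are dropped


def variable_genes(E: np.ndarray, n_top: int = 2000) -> np.ndarray:
    """Indices of the most variable genes by binned normalized dispersion.

    Dispersion = var/mean, z-scored within 20 mean-expression bins.
    """
    E = as_dense(E).astype(float)
    mean = E.mean(axis=0)
    var = E.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean, kind="stable")
    n_bins = 20
    bin_of = np.empty(len(mean), dtype=int)
    bin_of[order] = np.minimum(np.arange(len(mean)) * n_bins // max(len(mean), 1),
                               n_bins - 1)
    z = np.zeros_like(disp)
    for b in range(n_bins):
        m = bin_of == b
        if m.sum() < 2:
            continue
        s = disp[m].std()
        z[m] = (disp[m] - disp[m].mean()) / s if s > 0 else 0.0
    n_top = min(n_top, len(mean))
    return np.sort(np.argsort(-z, kind="stable")[:n_top])


@dataclass
class PCSelection:
    """PCA restricted to the components that clear the 2-MAD variance rule."""

    loadings: np.ndarray            # genes x n_selected
    scores: np.ndarray              # cells x n_selected
    explained_variance: np.ndarray  # full computed spectrum, non-increasing
    n_selected: int


def select_pcs(E: np.ndarray, var_genes: Sequence[int] | None = None,
               n_components: int | None = None) -> PCSelection:
    """PCA on the variable-gene submatrix; keep outstanding components.

    A component is kept when its explained variance exceeds
    median + 2*MAD of the computed spectrum; when no component qualifies,
    the top component is kept with a warning.
    """
    E = as_dense(E).astype(float)
    if var_genes is not None:
        E = E[:, np.asarray(var_genes)]
    if E.shape[0] < 3 or E.shape[1] < 2:
        raise ValueError("need at least 3 cells and 2 variable genes")
    if np.allclose(E, E[0]):
        raise ValueError("constant matrix: PCA undefined")
    n_comp = n_components or min(50, min(E.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(E)
    ev = pca.explained_variance_
    cut = np.median(ev) + 2.0 * mad(ev)
    # strict exceedance up to floating noise: a flat spectrum selects nothing
    selected = (ev > cut) & ~np.isclose(ev, cut, rtol=1e-9, atol=1e-12)
    if not selected.any():
        warnings.warn("no principal component exceeds median + 2*MAD; keeping the top one")
        n_sel = 1
    else:
        # spectrum is non-increasing, so qualifying components are leading
        n_sel = int(np.flatnonzero(selected).max() + 1)
    return PCSelection(loadings=pca.components_[:n_sel].T, scores=scores[:, :n_sel],
                       explained_variance=ev, n_selected=n_sel)


def snn_graph(scores: np.ndarray, k_neighbors: int = 15,
              prune: float = SNN_PRUNE) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Two cells are connected when the Jaccard overlap of their kNN sets
    (self included) is at least ``prune``.
    """
    n = scores.shape[0]
    idx, _ = knn_indices(scores, k_neighbors)
    cols = np.hstack([idx, np.arange(n)[:, None]])  # neighbor sets include self
    data = np.ones(cols.size, dtype=np.float32)
    A = sp.csr_matrix((data, (np.repeat(np.arange(n), cols.shape[1]), cols.ravel())),
                      shape=(n, n))
    shared = sp.coo_matrix(sp.triu(A @ A.T, k=1))  # |N_i & N_j|
    k_sz = cols.shape[1]
    jacc = shared.data / (2 * k_sz - shared.data)
    m = jacc >= prune
    g = igraph.Graph(n=n, edges=list(zip(shared.row[m].tolist(), shared.col[m].tolist())))
    g.es["weight"] = jacc[m].tolist()
    return g


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first occurrence so label ids are reproducible."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels])


def _louvain(g: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    """One seeded Louvain run.

    The vertex order is permuted per run: Louvain's local-move pass scans
    vertices in order, so the permutation is the algorithm's real source of
    run-to-run variability — required for the clustering tree to measure
    split stability rather than a fixed traversal artifact.
    """
    rng = random.Random(seed)
    igraph.set_random_number_generator(rng)
    n = g.vcount()
    perm = list(range(n))
    rng.shuffle(perm)  # perm[old] = new id
    gp = g.permute_vertices(perm)
    part = np.asarray(gp.community_multilevel(weights="weight",
                                              resolution=resolution).membership)
    labels = np.empty(n, dtype=int)
    labels[np.arange(n)] = part[np.asarray(perm)]
    return _canonical(labels)


def cluster_sweep(
    pcs: PCSelection | np.ndarray,
    k_neighbors: int = 15,
    k_max: int = 10,
    seed: int = 0,
    max_resolution: float = 20.0,
    max_evals: int = 80,
) -> Dict[int, np.ndarray]:
    """Louvain labelings at each reachable cluster count in 2..k_max.

    The resolution parameter is bisected between brackets whose cluster
    counts differ until every count in range is found or brackets collapse;
    counts Louvain never produces are reported in a warning.  Raises when
    even the maximum resolution cannot reach ``k_max``.
    """
    scores = pcs.scores if isinstance(pcs, PCSelection) else np.asarray(pcs)
    if k_neighbors >= scores.shape[0]:
        raise ValueError("k_neighbors must be < n_cells")
    g = snn_graph(scores, k_neighbors)

    found: Dict[int, np.ndarray] = {}
    nearest: Dict[int, np.ndarray] = {}  # fallback: smallest k above k_max

    def run(res: float) -> int:
        # each resolution gets its own deterministic stream: the clustering
        # tree scores split stability, which requires independently
        # initialized optimizations per level rather than nested refinements
        labels = _louvain(g, res, hash((seed, round(res, 6))) % (2 ** 31))
        k = int(labels.max() + 1)
        if 2 <= k <= k_max and k not in found:
            found[k] = labels
        elif k > k_max and (not nearest or k < min(nearest)):
            nearest.clear()
            nearest[k] = labels
        return k

    lo, hi = 1e-3, max_resolution
    k_lo, k_hi = run(lo), run(hi)
    if k_hi < k_max:
        raise ValueError(
            f"k_max={k_max} unreachable at resolution {max_resolution}; "
            f"achievable range ends at {k_hi}")

    brackets = [(lo, hi, k_lo, k_hi)]
    evals = 2
    while brackets and evals < max_evals and len(found) < k_max - 1:
        a, b, ka, kb = brackets.pop()
        if kb <= ka + 1 or b - a < 1e-4:
            continue
        if ka >= k_max or kb <= 2:  # no needed count inside this bracket
            continue
        if all(k in found or not (ka < k < kb) for k in range(2, k_max + 1)):
            continue
        mid = 0.5 * (a + b)
        km = run(mid)
        evals += 1
        brackets.append((a, mid, ka, km))
        brackets.append((mid, b, km, kb))

    missing = sorted(set(range(2, k_max + 1)) - set(found))
    if missing:
        warnings.warn(f"cluster counts never produced by Louvain: {missing}")
    if not found and nearest:
        # resolution cliff: no count in range was ever produced; fall back
        # to the smallest achievable clustering above the range
        warnings.warn(f"no cluster count within 2..{k_max} reachable; "
                      f"falling back to k={min(nearest)}")
        return dict(nearest)
    return dict(sorted(found.items()))


def cluster_sweep_replicates(
    pcs: PCSelection | np.ndarray,
    k_neighbors: int = 15,
    k_max: int = 10,
    seed: int = 0,
    n_replicates: int = 3,
    **kwargs,
):
    """Independently initialized sweeps for stability scoring.

    Returns ``(labelings, replicates)``: the first sweep's labelings plus
    the remaining ``n_replicates - 1`` sweeps, each run with its own
    deterministic seed stream.
    """
    sweeps = [cluster_sweep(pcs, k_neighbors=k_neighbors, k_max=k_max,
                            seed=seed + 104729 * r, **kwargs)
              for r in range(n_replicates)]
    return sweeps[0], sweeps[1:]


@dataclass
class ClusterTree:
    """Clustering tree: labelings per level, cell-flow edges, node entropies.

    ``node_entropy`` scores each node against the previous level's clusters
    (the tree view); ``stability``, present when the sweep was run with
    replicates, scores each node of the first replicate against the other
    replicates' labelings at the same level — the statistic used for
    cluster-number selection (a split that cannot be reproduced across
    independently initialized runs is not a real population boundary).
    """

    levels: Dict[int, np.ndarray]
    edges: pd.DataFrame         # parent_level, parent, child_level, child, proportion
    node_entropy: pd.DataFrame  # level, node, entropy_bits
    stability: pd.DataFrame | None = None  # level, node, replicate, entropy_bits

    def mean_entropy(self) -> pd.Series:
        """Mean node entropy (bits) per level; the first level scores 0."""
        levels = sorted(self.levels)
        out = {levels[0]: 0.0}
        for lv in levels[1:]:
            sub = self.node_entropy[self.node_entropy["level"] == lv]
            out[lv] = float(sub["entropy_bits"].mean())
        return pd.Series(out).sort_index()

    def stability_curve(self) -> pd.Series:
        """Worst (max) cross-replicate node entropy per level, in bits."""
        if self.stability is None:
            raise ValueError("tree was built without replicate labelings")
        return self.stability.groupby("level")["entropy_bits"].max().sort_index()


def shannon_entropy_bits(proportions: np.ndarray) -> float:
    """H = -sum p log2 p over nonzero proportions."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _origin_entropies(reference: np.ndarray, labels: np.ndarray):
    """Per cluster of ``labels``: Shannon entropy of its origin proportions
    over ``reference``'s clusters."""
    out = {}
    for c in np.unique(labels):
        _, counts = np.unique(reference[labels == c], return_counts=True)
        out[int(c)] = shannon_entropy_bits(counts / counts.sum())
    return out


def build_cluster_tree(
    labelings: Dict[int, np.ndarray],
    replicates: Sequence[Dict[int, np.ndarray]] | None = None,
) -> ClusterTree:
    """Link consecutive labelings by parent-origin proportions.

    For each cluster ("child") at a level, the proportions of its cells
    coming from each cluster ("parent") of the previous level sum to 1; the
    child's Shannon entropy over those proportions measures where the tree
    mixes.  When ``replicates`` (labelings from independently initialized
    sweeps) are given, each node is additionally scored by the same entropy
    against each replicate's labeling at the same level.
    """
    if not labelings:
        raise ValueError("no labelings supplied")
    ks = sorted(labelings)
    edge_rows, ent_rows = [], []
    for k_par, k_chi in zip(ks[:-1], ks[1:]):
        par, chi = labelings[k_par], labelings[k_chi]
        for c in np.unique(chi):
            cells = chi == c
            parents, counts = np.unique(par[cells], return_counts=True)
            props = counts / counts.sum()
            for pnode, pr in zip(parents, props):
                edge_rows.append({"parent_level": k_par, "parent": int(pnode),
                                  "child_level": k_chi, "child": int(c),
                                  "proportion": float(pr)})
            ent_rows.append({"level": k_chi, "node": int(c),
                             "entropy_bits": shannon_entropy_bits(props)})

    stab = None
    if replicates:
        rows = []
        for k in ks:
            for r, rep in enumerate(replicates):
                if k not in rep:
                    continue
                for node, h in _origin_entropies(rep[k], labelings[k]).items():
                    rows.append({"level": k, "node": node, "replicate": r,
                                 "entropy_bits": h})
        stab = pd.DataFrame(rows)
    return ClusterTree(levels=dict(labelings),
                       edges=pd.DataFrame(edge_rows),
                       node_entropy=pd.DataFrame(ent_rows),
                       stability=stab)


def select_cluster_number(
    tree: ClusterTree,
    epsilon_bits: float = 0.2,
    stability_epsilon_bits: float = 0.05,
) -> tuple[int, pd.Series]:
    """Largest level that is still a stable clustering.

    With replicate labelings present, a level qualifies when its worst
    cross-replicate node entropy is at most ``stability_epsilon_bits`` —
    every cluster must be reproducible across independently initialized
    optimizations.  Without replicates, the fallback is the tree rule:
    mean consecutive-level node entropy at most ``epsilon_bits``.  When no
    level qualifies, the level minimizing the curve is returned.  Returns
    (K*, the entropy-vs-K curve used).
    """
    if tree.stability is not None:
        curve = tree.stability_curve()
        eps = stability_epsilon_bits
    else:
        curve = tree.mean_entropy()
        eps = epsilon_bits
    ok = curve[curve <= eps]
    k_star = int(ok.index.max()) if len(ok) else int(curve.idxmin())
    return k_star, curve
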