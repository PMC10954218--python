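"""RNA velocity, velocity-directed transitions, fate absorption, drivers.

Velocity per gene is the steady-state residual v = u - gamma_hat * s on
kNN-smoothed spliced (s) and unspliced (u) counts, with gamma_hat the
degradation/splicing ratio fitted by least squares through the origin on
the cells in the extreme quantiles of s.  A positive residual means the
gene is being induced (unspliced excess), a negative one repressed.

Transitions follow the velocity field: the probability of stepping from
cell i to neighbor j grows with the cosine similarity between i's velocity
vector and the displacement to j in expression space.  Declared terminal
clusters are made absorbing, and each transient cell's fate probabilities
are the absorption probabilities of the resulting chain, computed exactly
by a sparse linear solve ((I - Q) B = R) and cross-checkable against a
seeded random-walk estimator ("fraction of walks ending in each fate").
Genes whose expression correlates with a fate's absorption probability
(Spearman rho beyond +-0.25) are classified as that fate's drivers or
antidrivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.stats import rankdata

from ._utils import as_dense, child_rng, knn_indices
from .pseudotime import TransitionMatrix

DRIVER_RHO = 0.25


@dataclass
class VelocityModel:
    """Per-gene steady-state ratio and per-cell velocity on smoothed counts."""

    gamma: np.ndarray          # fitted genes only
    velocity: np.ndarray       # cells x fitted genes
    smoothed_spliced: np.ndarray
    smoothed_unspliced: np.ndarray
    fitted_genes: np.ndarray   # column indices into the input layers
    gene_names: np.ndarray | None = None


def knn_smooth(X: np.ndarray, embedding: np.ndarray, k_smooth: int = 30) -> np.ndarray:
    """Average expression over each cell's k nearest neighbors (self included)."""
    X = as_dense(X).astype(float)
    n = X.shape[0]
    k = min(k_smooth, n - 1)
    idx, _ = knn_indices(embedding, k)
    idx_full = np.hstack([np.arange(n)[:, None], idx])
    return X[idx_full].mean(axis=1)


def estimate_velocity(
    spliced: np.ndarray,
    unspliced: np.ndarray,
    embedding: np.ndarray,
    k_smooth: int = 30,
    extreme_quantile: float = 0.05,
    min_cells: int = 10,
    gene_names: Sequence[str] | None = None,
) -> VelocityModel:
    """Steady-state velocity v = u - gamma_hat * s on smoothed counts.

    gamma_hat is fitted per gene by least squares through the origin using
    only cells in the top and bottom ``extreme_quantile`` of smoothed s —
    the cells most likely near their steady states.  Genes detected in
    fewer than ``min_cells`` cells in either layer are excluded.
    """
    S = as_dense(spliced).astype(float)
    U = as_dense(unspliced).astype(float)
    if S.shape != U.shape:
        raise ValueError("spliced and unspliced layers must have the same shape")
    ok = ((S > 0).sum(axis=0) >= min_cells) & ((U > 0).sum(axis=0) >= min_cells)
    fitted = np.flatnonzero(ok)
    if len(fitted) == 0:
        raise ValueError("no gene has enough nonzero cells in both layers")

    Ms = knn_smooth(S[:, fitted], embedding, k_smooth)
    Mu = knn_smooth(U[:, fitted], embedding, k_smooth)

    n = Ms.shape[0]
    n_ext = max(1, int(np.ceil(extreme_quantile * n)))
    order = np.argsort(Ms, axis=0, kind="stable")
    ext_rows = np.vstack([order[:n_ext], order[-n_ext:]])  # 2*n_ext x genes
    cols = np.arange(Ms.shape[1])
    s_ext = Ms[ext_rows, cols]
    u_ext = Mu[ext_rows, cols]
    denom = (s_ext ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(denom > 0, (u_ext * s_ext).sum(axis=0) / denom, np.nan)
    good = np.isfinite(gamma) & (gamma > 0)
    if not good.all():
        fitted = fitted[good]
        Ms, Mu, gamma = Ms[:, good], Mu[:, good], gamma[good]

    v = Mu - gamma[None, :] * Ms
    names = np.asarray(gene_names)[fitted] if gene_names is not None else None
    return VelocityModel(gamma=gamma, velocity=v, smoothed_spliced=Ms,
                         smoothed_unspliced=Mu, fitted_genes=fitted,
                         gene_names=names)


def velocity_transition_matrix(
    model: VelocityModel,
    embedding: np.ndarray,
    k_neighbors: int = 15,
    kernel_scale: float = 0.1,
) -> TransitionMatrix:
    """Transitions directed by the velocity field.

    Neighbors come from the kNN graph of ``embedding``; for each edge
    (i, j) the score is the cosine similarity between v_i and the
    displacement x_j - x_i in smoothed-spliced space (fitted genes), and row
    probabilities are softmax(score / kernel_scale).  Cells with zero
    velocity get uniform transitions over their neighbors.
    """
    n = embedding.shape[0]
    idx, _ = knn_indices(embedding, k_neighbors)
    n_comp, _ = sp.csgraph.connected_components(
        sp.csr_matrix((np.ones(idx.size),
                       (np.repeat(np.arange(n), k_neighbors), idx.ravel())),
                      shape=(n, n)), directed=False)
    if n_comp > 1:
        raise ValueError(f"kNN graph is disconnected ({n_comp} components)")

    X = model.smoothed_spliced
    V = model.velocity
    probs = np.empty((n, k_neighbors))
    vnorm = np.linalg.norm(V, axis=1)
    zero_v = vnorm == 0
    if zero_v.any():
        warnings.warn(f"{int(zero_v.sum())} cells have zero velocity; "
                      "their transitions are uniform")
    for i in range(n):
        if zero_v[i]:
            probs[i] = 1.0 / k_neighbors
            continue
        disp = X[idx[i]] - X[i]
        dnorm = np.linalg.norm(disp, axis=1)
        cos = np.where(dnorm > 0, disp @ V[i] / (dnorm * vnorm[i] + 1e-300), 0.0)
        if np.all(cos == 0):
            probs[i] = 1.0 / k_neighbors
            continue
        z = np.exp((cos - cos.max()) / kernel_scale)
        probs[i] = z / z.sum()
    T = sp.csr_matrix((probs.ravel(),
                       (np.repeat(np.arange(n), k_neighbors), idx.ravel())),
                      shape=(n, n))
    return TransitionMatrix(T=T, k_neighbors=k_neighbors, bandwidth=kernel_scale)


def fate_transition_matrix(
    model: VelocityModel,
    embedding: np.ndarray,
    k_neighbors: int = 15,
    kernel_scale: float = 0.2,
    velocity_weight: float = 0.15,
) -> TransitionMatrix:
    """Velocity kernel mixed with an undirected connectivity kernel.

    Absorption probabilities computed on a purely velocity-directed kernel
    show winner-take-all amplification: walks trapped in the progenitor pool
    preferentially exit through the denser branch, overstating the majority
    fate.  Mixing in a connectivity (diffusion) kernel lets walks sample the
    branch frontier ergodically, and with a small ``velocity_weight`` the
    mean absorption probability over progenitor cells tracks the underlying
    branch proportions while the velocity component still breaks the
    time-reversal symmetry.
    """
    from .pseudotime import diffusion_transitions

    if not 0.0 <= velocity_weight <= 1.0:
        raise ValueError("velocity_weight must be in [0, 1]")
    tv = velocity_transition_matrix(model, embedding, k_neighbors, kernel_scale)
    tc = diffusion_transitions(embedding, k_neighbors)
    T = (velocity_weight * tv.T + (1.0 - velocity_weight) * tc.T).tocsr()
    s = np.asarray(T.sum(axis=1)).ravel()
    T = sp.csr_matrix(sp.diags(1.0 / s) @ T)
    return TransitionMatrix(T=T, k_neighbors=k_neighbors, bandwidth=kernel_scale)


@dataclass
class FateProbabilities:
    """Cells x terminal-fate absorption probabilities; rows sum to 1."""

    B: np.ndarray
    fates: tuple
    terminal_mask: np.ndarray

    def __post_init__(self):
        s = self.B.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-8):
            raise ValueError("fate probability rows must sum to 1")

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.B, columns=list(self.fates), index=index)


def _terminal_arrays(terminal_labels: np.ndarray):
    """Split per-cell labels into (absorbing mask, fate names, fate index)."""
    lab = np.asarray(terminal_labels, dtype=object)
    mask = np.array([l is not None and l == l and l != "" for l in lab])
    fates = tuple(sorted({str(l) for l in lab[mask]}))
    if not fates:
        raise ValueError("at least one terminal fate must be declared")
    fate_idx = np.full(len(lab), -1)
    pos = {f: i for i, f in enumerate(fates)}
    fate_idx[mask] = [pos[str(l)] for l in lab[mask]]
    return mask, fates, fate_idx


def absorption_probabilities(
    tm: TransitionMatrix,
    terminal_labels: np.ndarray,
) -> FateProbabilities:
    """Exact absorption probabilities of the chain with terminal states absorbing.

    ``terminal_labels`` assigns a fate name to each terminal cell and
    None/NaN/"" to transient cells.  With Q the transient-to-transient block
    and R the transient-to-fate mass, solves (I - Q) B = R by sparse LU.
    Terminal rows are their own fate's indicator.  Raises when some
    transient cell cannot reach any terminal cell.
    """
    T = tm.T
    n = T.shape[0]
    mask, fates, fate_idx = _terminal_arrays(terminal_labels)

    # reachability: propagate "can reach a terminal cell" backwards
    reach = mask.copy()
    Tb = T.astype(bool).tocsc()
    for _ in range(n):
        new = np.asarray(Tb[:, reach].sum(axis=1)).ravel() > 0
        new = new & ~reach
        if not new.any():
            break
        reach |= new
    stranded = np.flatnonzero(~reach)
    if len(stranded):
        raise ValueError(f"{len(stranded)} transient cells cannot reach any "
                         f"terminal state, e.g. {stranded[:10].tolist()}")

    trans = np.flatnonzero(~mask)
    B = np.zeros((n, len(fates)))
    B[mask, fate_idx[mask]] = 1.0
    if len(trans):
        Q = T[np.ix_(trans, trans)].tocsc()
        # R aggregated by fate: transient -> absorbing mass per fate
        Rf = np.zeros((len(trans), len(fates)))
        Tt = T[trans].tocsc()
        for fi in range(len(fates)):
            cols = np.flatnonzero(mask & (fate_idx == fi))
            Rf[:, fi] = np.asarray(Tt[:, cols].sum(axis=1)).ravel()
        A = sp.identity(len(trans), format="csc") - Q
        lu = splu(A)
        B[trans] = lu.solve(Rf)
    B = np.clip(B, 0.0, 1.0)
    B /= B.sum(axis=1, keepdims=True)
    return FateProbabilities(B=B, fates=fates, terminal_mask=mask)


def random_walk_oracle(
    tm: TransitionMatrix,
    terminal_labels: np.ndarray,
    n_walks: int = 1000,
    max_steps: int | None = None,
    seed: int = 0,
) -> FateProbabilities:
    """Monte-Carlo fate probabilities: fraction of walks absorbed per fate.

    Simulates ``n_walks`` seeded random walks from every transient cell
    until absorption (or ``max_steps``, default 50 * n_cells; censored walks
    are excluded from the fractions and warned about above 1%).
    """
    T = tm.T.tocsr()
    n = T.shape[0]
    mask, fates, fate_idx = _terminal_arrays(terminal_labels)
    max_steps = max_steps or 50 * n
    rng = child_rng(seed, 6)

    # padded per-row neighbor lists and cumulative probabilities
    max_k = int(np.diff(T.indptr).max())
    nbr = np.zeros((n, max_k), dtype=np.int64)
    cum = np.ones((n, max_k))
    for i in range(n):
        lo, hi = T.indptr[i], T.indptr[i + 1]
        k = hi - lo
        nbr[i, :k] = T.indices[lo:hi]
        cum[i, :k] = np.cumsum(T.data[lo:hi])
        cum[i, k - 1:] = 1.0 + 1e-12
        nbr[i, k:] = nbr[i, k - 1]

    trans = np.flatnonzero(~mask)
    state = np.repeat(trans, n_walks)
    start = state.copy()
    active = np.ones(len(state), dtype=bool)
    absorbed_fate = np.full(len(state), -1)
    for _ in range(max_steps):
        if not active.any():
            break
        s = state[active]
        r = rng.random(len(s))
        col = (r[:, None] >= cum[s]).sum(axis=1)
        nxt = nbr[s, col]
        state[active] = nxt
        hit = mask[nxt]
        ai = np.flatnonzero(active)
        absorbed_fate[ai[hit]] = fate_idx[nxt[hit]]
        active[ai[hit]] = False

    censored = active.sum() / max(len(state), 1)
    if censored > 0.01:
        warnings.warn(f"{censored:.1%} of walks censored at max_steps")

    B = np.zeros((n, len(fates)))
    B[mask, fate_idx[mask]] = 1.0
    for i in trans:
        w = absorbed_fate[(start == i) & (absorbed_fate >= 0)]
        if len(w) == 0:
            raise ValueError(f"all walks from cell {i} were censored")
        B[i] = np.bincount(w, minlength=len(fates)) / len(w)
    return FateProbabilities(B=B, fates=fates, terminal_mask=mask)


def lineage_drivers(
    fate_probs: FateProbabilities,
    E: np.ndarray,
    fate: str,
    subset: np.ndarray | None = None,
    gene_names: Sequence[str] | None = None,
    rho_threshold: float = DRIVER_RHO,
) -> pd.DataFrame:
    """Spearman correlation of each gene with one fate's absorption probability.

    Computed over ``subset`` (boolean mask or indices; the cells on the
    relevant lineage — off-lineage populations should be excluded by the
    caller).  Genes with rho above +0.25 are drivers, below -0.25
    antidrivers; constant genes get rho = NaN and class "neither".
    """
    E = as_dense(E).astype(float)
    fi = list(fate_probs.fates).index(fate)
    p = fate_probs.B[:, fi]
    if subset is not None:
        subset = np.asarray(subset)
        E = E[subset]
        p = p[subset]
    names = np.asarray(gene_names if gene_names is not None
                       else [f"g{i}" for i in range(E.shape[1])])

    rp = rankdata(p)
    rE = rankdata(E, axis=0)
    rp_c = rp - rp.mean()
    rE_c = rE - rE.mean(axis=0)
    denom = np.sqrt((rp_c ** 2).sum()) * np.sqrt((rE_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, rE_c.T @ rp_c / np.where(denom == 0, 1, denom), np.nan)
    constant = (rE_c ** 2).sum(axis=0) == 0
    rho[constant] = np.nan

    cls = np.full(len(names), "neither", dtype=object)
    cls[np.nan_to_num(rho) > rho_threshold] = "driver"
    cls[np.nan_to_num(rho) < -rho_threshold] = "antidriver"
    return pd.DataFrame({"gene": names, "rho": rho, "class": cls,
                         "constant": constant}).set_index("gene")


def branching_signature(
    drivers_of_a: pd.DataFrame,
    antidrivers_of_b: pd.DataFrame,
) -> dict:
    """Shared genes that drive fate A while antagonizing sibling fate B.

    Returns the intersection of A's drivers with B's antidrivers, the Venn
    counts, and the overlap percentage relative to the antidriver set.
    """
    if not drivers_of_a.index.equals(antidrivers_of_b.index):
        if set(drivers_of_a.index) != set(antidrivers_of_b.index):
            raise ValueError("driver tables must share the same gene universe")
    da = set(drivers_of_a.index[drivers_of_a["class"] == "driver"])
    ab = set(antidrivers_of_b.index[antidrivers_of_b["class"] == "antidriver"])
    shared = sorted(da & ab)
    pct = 100.0 * len(shared) / len(ab) if ab else 0.0
    return {
        "signature": shared,
        "n_drivers_a": len(da),
        "n_antidrivers_b": len(ab),
        "n_shared": len(shared),
        "pct_of_antidrivers": pct,
    }
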