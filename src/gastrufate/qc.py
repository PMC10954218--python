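"""Cell-level QC, depth equalization, normalization, cell-cycle phases.

QC follows a robust-outlier rule: within each stage group, a cell is
removed when any of three metrics (mitochondrial fraction, detected genes,
total transcripts) exceeds k median absolute deviations (default k = 3)
from the group median.  Library depth is equalized across samples of a
stage by binomial thinning to the smallest sample total.  Within-cell
normalization produces clipped negative-binomial Pearson residuals with a
dispersion regularized against gene mean, a documented simplification of
regularized-NB regression that keeps the same depth-invariance contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import as_dense, child_rng, mad

IQR_TO_SIGMA = 1.349  # normal-consistency constant for the zero-MAD fallback


def compute_cell_qc(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC metrics from raw counts.

    Returns a frame indexed like ``adata.obs`` with columns ``pct_mito``
    (fraction of counts on mitochondrial genes, 0 for empty cells),
    ``n_genes`` (genes with at least one transcript) and ``n_counts``.
    """
    if "mito" not in adata.var:
        raise ValueError("gene metadata must flag mitochondrial genes in var['mito']")
    X = sp.csr_matrix(adata.X)
    n_counts = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito = adata.var["mito"].to_numpy(dtype=bool)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_counts > 0, mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {"pct_mito": pct, "n_genes": n_genes, "n_counts": n_counts},
        index=adata.obs_names,
    )


@dataclass(frozen=True)
class QCThresholds:
    """MAD multiplier and per-metric sidedness for outlier removal.

    The mitochondrial fraction is filtered on the upper side only; the two
    library-size metrics two-sided, catching both near-empty droplets and
    doublets.
    """

    k_mad: float = 3.0
    sidedness: Dict[str, str] = field(default_factory=lambda: {
        "pct_mito": "upper", "n_genes": "both", "n_counts": "both"})

    def __post_init__(self):
        if self.k_mad <= 0:
            raise ValueError("k_mad must be > 0")


def _robust_scale(x: np.ndarray) -> float:
    """MAD, falling back to IQR/1.349, then to 0 (meaning: any deviation exceeds)."""
    s = mad(x)
    if s == 0:
        q75, q25 = np.percentile(x, [75, 25])
        s = (q75 - q25) / IQR_TO_SIGMA
    return float(s)


def mad_filter(
    metrics: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    stage_group: Sequence | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag cells whose metrics exceed k MADs within their stage group.

    Returns ``(keep, report)``: a boolean Series (True = kept) and a
    per-group report of medians, scales, bounds and removal counts per
    criterion.  Thresholds are computed once from the input metrics
    (frozen), so a second pass over the kept cells with the *same* report
    bounds removes nothing further.

    When a metric's MAD is zero the interquartile range (scaled by 1.349)
    substitutes; when that is also zero, any value different from the
    median counts as exceeding.  A group with no variation on any metric is
    reported with a warning and loses no cells.
    """
    thresholds = thresholds or QCThresholds()
    groups = pd.Series(
        stage_group if stage_group is not None else ["all"] * len(metrics),
        index=metrics.index,
    )
    keep = pd.Series(True, index=metrics.index)
    rows = []
    for g, sub in metrics.groupby(groups, sort=False):
        if len(sub) < 10:
            raise ValueError(f"stage group {g!r} has fewer than 10 cells")
        if all(_robust_scale(sub[m].to_numpy(dtype=float)) == 0
               and (sub[m] == sub[m].median()).all() for m in sub.columns):
            warnings.warn(f"stage group {g!r}: all QC metrics degenerate; no cell removed")
        removed_any = pd.Series(False, index=sub.index)
        for m in sub.columns:
            x = sub[m].to_numpy(dtype=float)
            med = float(np.median(x))
            scale = _robust_scale(x)
            side = thresholds.sidedness.get(m, "both")
            lo = med - thresholds.k_mad * scale if side in ("both", "lower") else -np.inf
            hi = med + thresholds.k_mad * scale if side in ("both", "upper") else np.inf
            if scale == 0:
                # final fallback: any deviation from the median exceeds
                bad = x != med if side == "both" else (
                    x > med if side == "upper" else x < med)
            else:
                bad = (x < lo) | (x > hi)
            removed_any |= pd.Series(bad, index=sub.index)
            rows.append({"group": g, "metric": m, "median": med, "scale": scale,
                         "lower": lo, "upper": hi, "n_removed": int(bad.sum())})
        keep.loc[removed_any.index[removed_any]] = False
    report = pd.DataFrame(rows)
    return keep, report


def subsample_depth(
    adata: ad.AnnData,
    sample_key: str = "sample",
    seed: int = 0,
    stage_key: str | None = "stage",
) -> ad.AnnData:
    """Equalize sample library depth by binomial thinning.

    Within each stage, every count entry of a sample with total T is kept
    with probability T_min / T, so each sample's expected total equals the
    smallest sample total of its stage.  Zeros stay zero; deterministic
    under ``seed``.
    """
    rng = child_rng(seed, 3)
    out = adata.copy()
    X = sp.coo_matrix(out.X).astype(np.int64)
    samples = out.obs[sample_key].to_numpy()
    stages = (out.obs[stage_key].to_numpy() if stage_key and stage_key in out.obs
              else np.full(out.n_obs, "all"))

    keep_p = np.ones(out.n_obs)  # per-cell thinning probability (same per sample)
    cell_tot = np.zeros(out.n_obs)
    np.add.at(cell_tot, X.row, X.data)
    for stg in pd.unique(stages):
        stage_samples = pd.unique(samples[stages == stg])
        if len(stage_samples) < 2:
            continue
        totals = {s: cell_tot[samples == s].sum() for s in stage_samples}
        t_min = min(totals.values())
        for s in stage_samples:
            if totals[s] > t_min:
                keep_p[samples == s] = t_min / totals[s]

    thinned = np.where(keep_p[X.row] < 1.0,
                       rng.binomial(X.data, keep_p[X.row]), X.data)
    Xt = sp.coo_matrix((thinned, (X.row, X.col)), shape=X.shape).tocsr()
    Xt.eliminate_zeros()
    out.X = Xt
    return out


def normalize(adata: ad.AnnData, clip: float | None = None) -> ad.AnnData:
    """Clipped NB Pearson residuals with mean-regularized dispersion.

    The expected count of gene g in cell c is mu = (cell total x gene
    total) / grand total; per-gene method-of-moments dispersions are
    smoothed against gene mean (lowess in log space) and the residual
    (x - mu) / sqrt(mu + mu^2/theta) is clipped at +-sqrt(n_cells).
    Residuals land in ``layers['pearson']``; genes with zero total count get
    all-zero residuals and are flagged in ``var['zero_gene']``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    X = as_dense(adata.X).astype(float)
    n_cells, n_genes = X.shape
    cell_tot = X.sum(axis=1)
    gene_tot = X.sum(axis=0)
    grand = X.sum()
    if grand == 0:
        raise ValueError("all-zero count matrix")
    mu = np.outer(cell_tot, gene_tot) / grand

    gene_mean = X.mean(axis=0)
    gene_var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    expressed = gene_tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_mom = np.where(gene_var > gene_mean,
                             gene_mean ** 2 / (gene_var - gene_mean), 1e6)
    theta_mom = np.clip(theta_mom, 1e-2, 1e6)
    theta = np.full(n_genes, 100.0)
    if expressed.sum() >= 10:
        lx = np.log10(gene_mean[expressed])
        ly = np.log10(theta_mom[expressed])
        sm = lowess(ly, lx, frac=0.5, return_sorted=False)
        theta[expressed] = 10 ** sm
    else:
        theta[expressed] = theta_mom[expressed]
    theta = np.clip(theta, 1e-2, 1e6)

    denom = np.sqrt(mu + mu ** 2 / theta[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = np.where(denom > 0, (X - mu) / denom, 0.0)
    bound = clip if clip is not None else np.sqrt(n_cells)
    res = np.clip(res, -bound, bound)
    res[:, ~expressed] = 0.0

    out = adata.copy()
    out.layers["pearson"] = res.astype(np.float32)
    out.var["zero_gene"] = ~expressed
    out.var["theta"] = theta
    return out


def log_normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-scaled log1p counts in ``layers['lognorm']`` (CP10K dialect)."""
    X = sp.csr_matrix(adata.X).astype(float)
    tot = np.asarray(X.sum(axis=1)).ravel()
    scale = np.where(tot > 0, target_sum / np.maximum(tot, 1), 0.0)
    Xn = sp.csr_matrix(sp.diags(scale) @ X)
    Xn.data = np.log1p(Xn.data)
    out = adata.copy()
    out.layers["lognorm"] = Xn
    return out


def assign_cell_cycle(
    adata: ad.AnnData,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    layer: str = "lognorm",
    n_bins: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Score S and G2M marker programs and call a phase per cell.

    Each score is the mean marker expression minus the mean of a
    size-matched control gene set drawn (seeded) from expression-matched
    bins.  A cell expressing neither program (both scores <= 0) is G1;
    otherwise the phase with the larger score wins.
    """
    s_genes = [g for g in s_genes if g in adata.var_names]
    g2m_genes = [g for g in g2m_genes if g in adata.var_names]
    if not s_genes or not g2m_genes:
        raise ValueError("both marker sets must be non-empty and present in the matrix")
    if set(s_genes) & set(g2m_genes):
        raise ValueError("S and G2M marker sets overlap")
    rng = child_rng(seed, 4)
    E = as_dense(adata.layers[layer] if layer in adata.layers else adata.X).astype(float)
    n_genes_total = adata.n_vars
    gene_mean = E.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    bin_of = np.empty(n_genes_total, dtype=int)
    bin_of[order] = np.minimum(
        np.arange(n_genes_total) * n_bins // max(n_genes_total, 1), n_bins - 1)
    marker_idx = {adata.var_names.get_loc(g) for g in (*s_genes, *g2m_genes)}

    non_marker = np.array([p for p in range(n_genes_total) if p not in marker_idx])
    if len(non_marker) == 0:
        raise ValueError("no non-marker genes available for control sets")

    def score(markers):
        m_idx = np.array([adata.var_names.get_loc(g) for g in markers])
        ctrl = []
        for gi in m_idx:
            pool = non_marker[bin_of[non_marker] == bin_of[gi]]
            if len(pool) == 0:
                # marker-only bin: take the expression-nearest non-markers
                near = non_marker[np.argsort(np.abs(gene_mean[non_marker]
                                                    - gene_mean[gi]))[:5]]
                pool = near
            ctrl.append(rng.choice(pool))
        return E[:, m_idx].mean(axis=1) - E[:, np.array(ctrl)].mean(axis=1)

    s_score = score(s_genes)
    g2m_score = score(g2m_genes)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0), "G1",
        np.where(s_score >= g2m_score, "S", "G2M"))
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=adata.obs_names)
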