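"""Cross-study DEG concordance, TSS-window peak annotation, ORA and GSEA.

Concordance between two differential-expression studies is measured
direction-stratified: the percentage of this study's up- (down-)regulated
genes that are also up- (down-)regulated in the external study, a one-sided
binomial test against the external DEG density in the shared universe, and
an ordinary least-squares regression of the two studies' log2 fold changes.

Promoter-proximal binding sites are called by intersecting peak intervals
(BED half-open, 0-based) with the closed +-250 nt window around each gene's
strand-aware TSS.  Gene-set overrepresentation uses the one-sided Fisher
exact test (hypergeometric tail) with Bonferroni control; ranked GSEA uses
the weighted Kolmogorov-Smirnov enrichment score with a seeded gene-label
permutation null and Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_rng

TSS_WINDOW_NT = 250


# ---------------------------------------------------------------------------
# DEG concordance


def deg_overlap(
    self_degs: Mapping[str, str],
    external_degs: Mapping[str, str],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Direction-stratified DEG overlap with one-sided binomial tests.

    ``self_degs`` / ``external_degs`` map gene -> direction ("up"/"down");
    both are restricted to ``universe``.  For each direction, the success
    probability of the binomial null is the external DEG density of that
    direction in the universe, and the test asks whether the observed
    overlap count is larger than chance.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    self_d = {g: d for g, d in self_degs.items() if g in uni}
    ext_d = {g: d for g, d in external_degs.items() if g in uni}
    rows = []
    for direction in ("up", "down"):
        mine = [g for g, d in self_d.items() if d == direction]
        theirs = {g for g, d in ext_d.items() if d == direction}
        n_overlap = sum(g in theirs for g in mine)
        n_self = len(mine)
        p_null = len(theirs) / len(universe)
        pct = 100.0 * n_overlap / n_self if n_self else np.nan
        p = (float(stats.binom.sf(n_overlap - 1, n_self, p_null))
             if n_self else np.nan)
        rows.append({"direction": direction, "n_self": n_self,
                     "n_external": len(theirs), "n_overlap": n_overlap,
                     "percent": pct, "p_null": p_null, "binomial_p": p})
    return pd.DataFrame(rows).set_index("direction")


def foldchange_regression(
    self_lfc: Mapping[str, float],
    external_lfc: Mapping[str, float],
) -> dict:
    """OLS of this study's log2 fold changes on the external study's.

    Fitted over the genes present in both mappings; raises when fewer than
    3 genes are shared or the external fold changes are constant.
    """
    shared = sorted(set(self_lfc) & set(external_lfc))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    x = np.array([external_lfc[g] for g in shared], dtype=float)
    y = np.array([self_lfc[g] for g in shared], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("external fold changes have zero variance")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "p": float(res.pvalue), "n": len(shared)}


# ---------------------------------------------------------------------------
# TSS-window peak annotation


def annotate_tss_peaks(
    gene_models: pd.DataFrame,
    peaks: pd.DataFrame,
    window_nt: int = TSS_WINDOW_NT,
) -> pd.DataFrame:
    """Flag genes with a peak within the closed +-window around their TSS.

    ``gene_models`` needs columns chromosome, strand, start, end (or a
    precomputed ``tss``); the TSS is ``start`` on the + strand and
    ``end - 1`` on the - strand (BED half-open convention).  ``peaks`` needs
    chromosome, start, end as half-open 0-based intervals.  A gene has a
    site when any same-chromosome peak interval intersects
    [TSS - window, TSS + window] (closed).
    """
    gm = gene_models.copy()
    if "tss" not in gm.columns:
        gm["tss"] = np.where(gm["strand"] == "+", gm["start"], gm["end"] - 1)
    extra = set(peaks["chromosome"]) - set(gm["chromosome"])
    if extra:
        n_extra = int(peaks["chromosome"].isin(extra).sum())
        warnings.warn(f"{n_extra} peaks on {len(extra)} chromosomes absent "
                      f"from the gene models")

    has_site = np.zeros(len(gm), dtype=bool)
    n_sites = np.zeros(len(gm), dtype=int)
    for chrom, pk in peaks.groupby("chromosome"):
        rows = np.flatnonzero((gm["chromosome"] == chrom).to_numpy())
        if len(rows) == 0:
            continue
        tss = gm["tss"].to_numpy()[rows]
        lo = tss - window_nt        # closed window [lo, hi]
        hi = tss + window_nt
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()  # half-open: last covered base is end-1
        # peak [s, e) intersects [lo, hi] iff s <= hi and e - 1 >= lo
        inter = (starts[None, :] <= hi[:, None]) & (ends[None, :] - 1 >= lo[:, None])
        n_sites[rows] = inter.sum(axis=1)
        has_site[rows] = n_sites[rows] > 0
    out = pd.DataFrame({"has_site": has_site, "n_sites": n_sites},
                       index=gm.index)
    out.attrs["window_nt"] = window_nt
    return out


def fisher_one_sided(table: np.ndarray) -> tuple[float, float]:
    """Sample odds ratio and one-sided (greater) Fisher exact p for a 2x2 table.

    The p-value is the hypergeometric upper tail of table[0, 0] given the
    margins.
    """
    t = np.asarray(table, dtype=np.int64)
    a, b = t[0]
    c, d = t[1]
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("2x2 table has a zero margin; p set to 1")
        return np.nan, 1.0
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))
    return float(odds), p


def binding_site_enrichment(
    deg_flags: Mapping[str, bool],
    annotation: pd.DataFrame,
    universe: Sequence[str],
) -> dict:
    """Fisher enrichment of promoter binding sites among DEGs.

    Builds the 2x2 table (DEG vs non-DEG) x (site vs no site) over the
    annotated universe and tests one-sided for enrichment of sites in DEGs.
    """
    uni = [g for g in dict.fromkeys(universe) if g in annotation.index]
    if not uni:
        raise ValueError("universe shares no genes with the annotation")
    site = annotation.loc[uni, "has_site"].to_numpy(dtype=bool)
    deg = np.array([bool(deg_flags.get(g, False)) for g in uni])
    a = int((deg & site).sum())
    b = int((deg & ~site).sum())
    c = int((~deg & site).sum())
    d = int((~deg & ~site).sum())
    odds, p = fisher_one_sided(np.array([[a, b], [c, d]]))
    return {"table": [[a, b], [c, d]], "odds_ratio": odds, "p": p}


# ---------------------------------------------------------------------------
# gene-set ORA and GSEA


def ora(
    genes_of_interest: Sequence[str],
    gene_sets: Dict[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation per gene set, Bonferroni corrected.

    Gene sets are intersected with the universe first; empty intersections
    are skipped (noted in ``attrs['skipped']``).  The overrepresentation
    score is log2((observed + 0.5) / (expected + 0.5)).
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty gene universe")
    uni_set = set(uni)
    goi = set(g for g in genes_of_interest if g in uni_set)
    rows, skipped = [], []
    for name, members in gene_sets.items():
        mem = set(members) & uni_set
        if not mem:
            skipped.append(name)
            continue
        a = len(goi & mem)
        b = len(goi - mem)
        c = len(mem - goi)
        d = len(uni_set) - a - b - c
        odds, p = fisher_one_sided(np.array([[a, b], [c, d]]))
        expected = len(goi) * len(mem) / len(uni_set)
        score = float(np.log2((a + 0.5) / (expected + 0.5)))
        rows.append({"gene_set": name, "n_set": len(mem), "n_overlap": a,
                     "expected": expected, "odds_ratio": odds, "p": p,
                     "score": score})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["Q"] = np.minimum(1.0, out["p"] * len(out))
    out.attrs["skipped"] = skipped
    return out


def _enrichment_score(order_idx: np.ndarray, weights: np.ndarray,
                      member: np.ndarray) -> float:
    """Signed max deviation of the weighted KS running sum."""
    in_set = member[order_idx]
    w = weights[order_idx]
    hit = np.where(in_set, w, 0.0)
    hit_sum = hit.sum()
    if hit_sum == 0:
        return 0.0
    miss = np.where(in_set, 0.0, 1.0)
    run = np.cumsum(hit / hit_sum - miss / max(miss.sum(), 1.0))
    return float(run[np.argmax(np.abs(run))])


def gsea(
    stat: Mapping[str, float],
    gene_sets: Dict[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    Genes are ranked by ``stat`` (descending); the enrichment score is the
    extreme of the weighted KS running sum (weights |stat|^exponent); the
    null redistributes set membership over genes ``n_perm`` times (seeded).
    NES = ES / mean |null ES| of the matching sign; Q is Benjamini-Hochberg
    across sets.  Sets smaller than ``min_size`` after intersection are
    skipped.
    """
    genes = np.array(list(stat.keys()))
    values = np.array([stat[g] for g in genes], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("ranking statistic must be finite for all genes")
    order = np.argsort(-values, kind="stable")
    weights = np.abs(values) ** weight_exponent
    pos = {g: i for i, g in enumerate(genes)}
    rng = child_rng(seed, 7)

    rows = []
    for name, members in gene_sets.items():
        member = np.zeros(len(genes), dtype=bool)
        hits = [pos[g] for g in members if g in pos]
        if len(hits) < min_size:
            continue
        member[hits] = True
        es = _enrichment_score(order, weights, member)
        size = len(hits)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=size, replace=False)] = True
            null[b] = _enrichment_score(order, weights, perm)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        # p is conditional on the observed sign, as in permutation GSEA
        n_extreme = (np.abs(same_sign) >= abs(es)).sum() if es != 0 else n_perm
        p = (n_extreme + 1) / (len(same_sign) + 1) if es != 0 else 1.0
        rows.append({"gene_set": name, "size": size, "ES": es, "NES": nes,
                     "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["size", "ES", "NES", "p", "Q"],
                            index=pd.Index([], name="gene_set"))
    out = pd.DataFrame(rows).set_index("gene_set")
    out["Q"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
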