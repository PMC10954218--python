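"""Differential expression, composition tests, driver-direction chi-square.

Differential expression between cell groups is the two-sided Mann-Whitney U
test on normalized expression, Bonferroni-corrected over the genes actually
tested (Q = min(1, p*m)); genes detected in fewer than ``min_frac`` of the
cells of both groups are excluded before testing and before the correction
denominator.  Composition differences between genotypes are Welch t tests
on per-sample population proportions.  The driver-direction chi-square asks
whether significantly misexpressed driver genes skew toward under- or
overexpression against a 50/50 null.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_dense

FOLD_PSEUDO = 1e-9


def mann_whitney_dgea(
    E: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_names: Sequence[str] | None = None,
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene between two cell groups.

    ``E`` is cells x genes log-normalized expression; ``group_a``/``group_b``
    are boolean masks or index arrays.  Exact p-values are used for small
    tie-free groups (min group size <= 8), otherwise the tie-corrected
    normal approximation.  Returns one row per *tested* gene with means,
    fold change (on expm1 of mean log expression, pseudocount 1e-9), U, p,
    Bonferroni Q and direction; ``attrs['n_tested']`` records the correction
    denominator.
    """
    E = as_dense(E).astype(float)
    A = E[np.asarray(group_a)] if np.asarray(group_a).dtype == bool else E[group_a]
    B = E[np.asarray(group_b)] if np.asarray(group_b).dtype == bool else E[group_b]
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty group")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("each group needs at least 3 cells")
    names = np.asarray(gene_names if gene_names is not None
                       else [f"g{i}" for i in range(E.shape[1])])

    frac_a = (A > 0).mean(axis=0)
    frac_b = (B > 0).mean(axis=0)
    tested = (frac_a >= min_frac) | (frac_b >= min_frac)
    m = int(tested.sum())
    if m == 0:
        raise ValueError("no gene passes the expression filter")
    At, Bt = A[:, tested], B[:, tested]

    small = min(A.shape[0], B.shape[0]) <= 8
    res = stats.mannwhitneyu(At, Bt, axis=0, alternative="two-sided",
                             method="auto" if small else "asymptotic")
    mean_a, mean_b = At.mean(axis=0), Bt.mean(axis=0)
    fc = (np.expm1(mean_a) + FOLD_PSEUDO) / (np.expm1(mean_b) + FOLD_PSEUDO)
    q = np.minimum(1.0, res.pvalue * m)
    out = pd.DataFrame({
        "gene": names[tested],
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_change": fc,
        "U": res.statistic,
        "p": res.pvalue,
        "Q": q,
        "direction": np.where(fc >= 1.0, "up", "down"),
    }).set_index("gene")
    out.attrs["n_tested"] = m
    return out


def one_vs_rest_dgea(E: np.ndarray, labels: np.ndarray,
                     gene_names: Sequence[str] | None = None,
                     min_frac: float = 0.1) -> dict:
    """Mann-Whitney DGEA of each cluster against all remaining cells."""
    labels = np.asarray(labels)
    return {
        c: mann_whitney_dgea(E, labels == c, labels != c,
                             gene_names=gene_names, min_frac=min_frac)
        for c in np.unique(labels)
    }


def composition_test(
    labels: np.ndarray,
    samples: np.ndarray,
    genotypes: np.ndarray,
    denominator: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample population proportions and per-population Welch t tests.

    Proportions use each sample's cell total within ``denominator`` (all
    cells by default); populations absent from a sample contribute 0, not
    missing.  The t test compares the two genotypes' sample-proportion
    vectors, two-sided with unequal variances.
    """
    labels = np.asarray(labels)
    samples = np.asarray(samples)
    genotypes = np.asarray(genotypes)
    keep = np.ones(len(labels), dtype=bool) if denominator is None \
        else np.asarray(denominator, dtype=bool)
    labels, samples, genotypes = labels[keep], samples[keep], genotypes[keep]

    sample_ids = pd.unique(samples)
    geno_of = {s: genotypes[samples == s][0] for s in sample_ids}
    gts = pd.unique(genotypes)
    if len(gts) != 2:
        raise ValueError("composition test expects exactly two genotypes")
    for g in gts:
        if sum(geno_of[s] == g for s in sample_ids) < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 samples")

    pops = pd.unique(labels)
    prop = pd.DataFrame(0.0, index=sample_ids, columns=pops)
    for s in sample_ids:
        sub = labels[samples == s]
        vc = pd.Series(sub).value_counts(normalize=True)
        prop.loc[s, vc.index] = vc.values
    prop["genotype"] = [geno_of[s] for s in sample_ids]

    rows = []
    for p in pops:
        x = prop.loc[prop["genotype"] == gts[0], p].to_numpy(dtype=float)
        y = prop.loc[prop["genotype"] == gts[1], p].to_numpy(dtype=float)
        if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
            t_stat, pval = 0.0, 1.0
        else:
            t_stat, pval = stats.ttest_ind(x, y, equal_var=False)
        rows.append({
            "population": p,
            f"mean_{gts[0]}": x.mean(), f"sem_{gts[0]}": stats.sem(x) if len(x) > 1 else 0.0,
            f"mean_{gts[1]}": y.mean(), f"sem_{gts[1]}": stats.sem(y) if len(y) > 1 else 0.0,
            "t": float(t_stat), "p": float(pval),
        })
    return prop, pd.DataFrame(rows).set_index("population")


def driver_direction_chisq(n_under: int, n_over: int) -> dict:
    """1-df chi-square of (under, over) driver counts against a 50/50 null."""
    n = n_under + n_over
    if n == 0:
        warnings.warn("no significantly misexpressed driver genes; returning NA")
        return {"n_under": 0, "n_over": 0, "expected": np.nan,
                "statistic": np.nan, "p": np.nan}
    e = n / 2.0
    statistic = (n_under - e) ** 2 / e + (n_over - e) ** 2 / e
    return {"n_under": int(n_under), "n_over": int(n_over), "expected": e,
            "statistic": float(statistic), "p": float(stats.chi2.sf(statistic, df=1))}


def driver_direction_from_dgea(dgea_table: pd.DataFrame,
                               driver_genes: Sequence[str],
                               alpha: float = 0.05) -> dict:
    """Chi-square on significantly misexpressed members of a driver set.

    Restricts the DGEA table to Q < alpha genes in ``driver_genes`` and
    counts under- vs overexpression directions.
    """
    sub = dgea_table[(dgea_table["Q"] < alpha)
                     & dgea_table.index.isin(set(driver_genes))]
    n_under = int((sub["direction"] == "down").sum())
    n_over = int((sub["direction"] == "up").sum())
    return driver_direction_chisq(n_under, n_over)


def positional_expression_profile(
    E: np.ndarray,
    gene_names: Sequence[str],
    ordered_genes: Sequence[str],
    groups: np.ndarray,
) -> pd.DataFrame:
    """Group mean +- SEM per gene, preserving the supplied gene order.

    Suited to chromosomally ordered gene clusters whose activation timing is
    compared across stages or groups.  Genes absent from the matrix appear
    in the output with ``present = False`` (and a warning) rather than being
    dropped.
    """
    if len(ordered_genes) == 0:
        raise ValueError("ordered gene list is empty")
    E = as_dense(E).astype(float)
    name_pos = {g: i for i, g in enumerate(gene_names)}
    groups = np.asarray(groups)
    missing = [g for g in ordered_genes if g not in name_pos]
    if missing:
        warnings.warn(f"{len(missing)} genes missing from the matrix: {missing[:10]}")
    rows = []
    for rank, g in enumerate(ordered_genes):
        for grp in pd.unique(groups):
            if g in name_pos:
                x = E[groups == grp, name_pos[g]]
                rows.append({"gene": g, "order": rank, "group": grp,
                             "mean": float(x.mean()),
                             "sem": float(stats.sem(x)) if len(x) > 1 else 0.0,
                             "present": True})
            else:
                rows.append({"gene": g, "order": rank, "group": grp,
                             "mean": np.nan, "sem": np.nan, "present": False})
    return pd.DataFrame(rows)
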