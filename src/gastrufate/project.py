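"""Anchor-based label projection between genotypes, with a reverse control.

Cells of a query dataset (e.g. the mutant genotype) are assigned to the
reference dataset's clusters through anchors: mutual nearest-neighbor pairs
across the two datasets in a joint PCA of the per-dataset-scaled shared
variable genes.  Each anchor is scored by the Jaccard overlap of the two
cells' joint neighborhoods, and every query cell is labeled by an
anchor-score-weighted vote of its nearest anchors, so projection is
exhaustive by construction.

The reverse-projection control swaps the roles of the datasets: if
composition differences between genotypes were projection artifacts, the
deltas measured under forward and reverse projection would disagree;
concordant signs support a real composition shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._utils import as_dense


@dataclass
class AnchorSet:
    """Mutual-NN anchor pairs plus the joint embedding they live in."""

    pairs: pd.DataFrame          # columns: ref, query, score in [0, 1]
    ref_embedding: np.ndarray
    query_embedding: np.ndarray


def _scale_columns(E: np.ndarray) -> np.ndarray:
    """Per-dataset gene scaling (no centering: the joint PCA centers the
    concatenated matrix, so a query covering only part of the reference's
    populations is not artificially shifted onto the reference centroid)."""
    sd = E.std(axis=0)
    sd[sd == 0] = 1.0
    return E / sd


def find_anchors(
    ref: np.ndarray,
    query: np.ndarray,
    k_anchor: int = 5,
    n_pcs: int = 30,
    k_score: int = 30,
) -> AnchorSet:
    """Mutual cross-dataset nearest-neighbor pairs in a joint PCA.

    Each dataset's shared-gene matrix is gene-scaled independently (so a
    global expression shift between datasets does not break pairing), the
    two are concatenated and jointly embedded, and anchors are the pairs
    (r, q) where q is among r's k nearest query cells and r among q's k
    nearest reference cells.  Scores are the Jaccard overlap of the cells'
    ``k_score``-neighborhoods in the joint space.
    """
    ref = as_dense(ref).astype(float)
    query = as_dense(query).astype(float)
    if ref.shape[0] < k_anchor or query.shape[0] < k_anchor:
        raise ValueError("need at least k_anchor cells in each dataset")
    if ref.shape[1] != query.shape[1]:
        raise ValueError("reference and query must share the gene space")

    joint = np.vstack([_scale_columns(ref), _scale_columns(query)])
    n_comp = min(n_pcs, min(joint.shape) - 1)
    Z = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(joint)
    Zr, Zq = Z[: ref.shape[0]], Z[ref.shape[0]:]

    nn_q = NearestNeighbors(n_neighbors=k_anchor).fit(Zq)
    _, r2q = nn_q.kneighbors(Zr)          # per ref cell: k nearest query cells
    nn_r = NearestNeighbors(n_neighbors=k_anchor).fit(Zr)
    _, q2r = nn_r.kneighbors(Zq)          # per query cell: k nearest ref cells

    q_sets = [set(row) for row in q2r]
    pairs = [(r, q) for r in range(ref.shape[0]) for q in r2q[r] if r in q_sets[q]]
    if not pairs:
        raise ValueError("no anchors found: datasets appear disjoint in the joint space")

    # neighborhood overlap score in the joint space; neighborhoods are
    # tie-complete (all points within the k-th neighbor distance) and the
    # pair's own members are excluded, so the score is deterministic even
    # with duplicated points
    k_eff = min(k_score, Z.shape[0] - 1)
    nn_all = NearestNeighbors(n_neighbors=k_eff + 1).fit(Z)
    kdist, _ = nn_all.kneighbors(Z)
    hood_sets = [
        set(nn_all.radius_neighbors(Z[i:i + 1], radius=kdist[i, -1] * (1 + 1e-9),
                                    return_distance=False)[0].tolist())
        for i in range(Z.shape[0])]
    rows = []
    n_ref = ref.shape[0]
    for r, q in pairs:
        drop = {r, n_ref + q}
        a = hood_sets[r] - drop
        b = hood_sets[n_ref + q] - drop
        score = len(a & b) / max(len(a | b), 1)
        rows.append({"ref": int(r), "query": int(q), "score": score})
    df = pd.DataFrame(rows)
    if df["score"].max() > 0:
        df["score"] = df["score"] / df["score"].max()  # rescale to [0, 1]
    return AnchorSet(pairs=df, ref_embedding=Zr, query_embedding=Zq)


def transfer_labels(
    anchors: AnchorSet,
    ref_labels: np.ndarray,
    k_vote: int = 10,
) -> pd.DataFrame:
    """Label every query cell by a weighted vote of its nearest anchors.

    For each query cell the ``k_vote`` anchors whose query-side cells are
    nearest in the joint embedding vote with weight score/(1 + distance);
    ties break by larger total anchor score, then smaller label index.
    Cells with no direct anchor of their own are flagged ``indirect``.
    """
    if len(anchors.pairs) == 0:
        raise ValueError("anchor set is empty")
    ref_labels = np.asarray(ref_labels)
    Zq = anchors.query_embedding
    n_query = Zq.shape[0]
    aq = anchors.pairs["query"].to_numpy()
    ar = anchors.pairs["ref"].to_numpy()
    ascore = anchors.pairs["score"].to_numpy()

    k = min(k_vote, len(anchors.pairs))
    nn = NearestNeighbors(n_neighbors=k).fit(Zq[aq])
    dist, idx = nn.kneighbors(Zq)

    anchored = np.zeros(n_query, dtype=bool)
    anchored[aq] = True
    labels_all = np.unique(ref_labels)
    label_pos = {l: i for i, l in enumerate(labels_all)}

    out_label = np.empty(n_query, dtype=object)
    out_score = np.zeros(n_query)
    for q in range(n_query):
        w = ascore[idx[q]] / (1.0 + dist[q])
        votes = np.zeros(len(labels_all))
        raw = np.zeros(len(labels_all))
        for j, wj in zip(idx[q], w):
            li = label_pos[ref_labels[ar[j]]]
            votes[li] += wj
            raw[li] += ascore[j]
        best = np.flatnonzero(votes == votes.max())
        if len(best) > 1:  # tie: larger total anchor score, then smaller index
            best = best[raw[best] == raw[best].max()]
        win = int(best.min())
        out_label[q] = labels_all[win]
        tot = votes.sum()
        out_score[q] = votes[win] / tot if tot > 0 else 0.0
    return pd.DataFrame({
        "label": out_label,
        "score": out_score,
        "direct_anchor": anchored,
    })


def composition_delta(
    ref_labels: np.ndarray,
    query_labels: np.ndarray,
    populations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-population proportion difference, query minus reference."""
    ref_labels = np.asarray(ref_labels)
    query_labels = np.asarray(query_labels)
    pops = populations if populations is not None else np.unique(
        np.concatenate([ref_labels, query_labels]))
    rows = []
    for p in pops:
        pr = (ref_labels == p).mean()
        pq = (query_labels == p).mean()
        rows.append({"population": p, "prop_ref": pr, "prop_query": pq,
                     "delta": pq - pr})
    return pd.DataFrame(rows).set_index("population")


def reverse_projection_check(
    ref: np.ndarray,
    ref_labels: np.ndarray,
    query: np.ndarray,
    query_labels: np.ndarray,
    k_anchor: int = 5,
) -> dict:
    """Forward vs reverse projection concordance of composition deltas.

    ``ref_labels`` and ``query_labels`` are each genotype's *own* cluster
    annotations in a shared population namespace.  Forward projection maps
    query cells onto reference labels; reverse projection maps reference
    cells onto query labels.  For each population the (query - reference)
    proportion delta is computed both ways; concordant signs argue that the
    measured composition shift is not a projection artifact.
    """
    fwd_anchors = find_anchors(ref, query, k_anchor=k_anchor)
    fwd = transfer_labels(fwd_anchors, np.asarray(ref_labels))
    rev_anchors = find_anchors(query, ref, k_anchor=k_anchor)
    rev = transfer_labels(rev_anchors, np.asarray(query_labels))

    pops = np.unique(np.concatenate([np.asarray(ref_labels), np.asarray(query_labels)]))
    d_fwd = composition_delta(ref_labels, fwd["label"].to_numpy(), pops)["delta"]
    d_rev = composition_delta(rev["label"].to_numpy(), query_labels, pops)["delta"]

    table = pd.DataFrame({"delta_forward": d_fwd, "delta_reverse": d_rev})
    nonzero = (table["delta_forward"] != 0) & (table["delta_reverse"] != 0)
    table["sign_agree"] = np.sign(table["delta_forward"]) == np.sign(table["delta_reverse"])
    corr = (np.corrcoef(table["delta_forward"], table["delta_reverse"])[0, 1]
            if len(table) > 1 else np.nan)
    return {
        "table": table,
        "sign_agreement": float(table.loc[nonzero, "sign_agree"].mean())
        if nonzero.any() else 1.0,
        "delta_correlation": float(corr),
        "forward_labels": fwd,
        "reverse_labels": rev,
    }
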