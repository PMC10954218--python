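"""Parameter-recovery and calibration studies on the synthetic cohorts.

Each study regenerates its inputs from a seed, runs the relevant pipeline
components, and reports the recovered quantity next to the generative
truth.  They are the package's own validation experiments, shared by the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ks_2samp, spearmanr

from . import cluster as cl
from . import dgea as dg
from . import project as pj
from . import pseudotime as pt
from . import qc as qcm
from . import velocity as vl
from ._utils import as_dense, child_rng
from .pipeline import (
    PipelineConfig,
    declare_terminal_states,
    fate_bias_recovery,
    genotype_fate_map,
    lineage_subset,
    root_marker_genes,
)
from .simdata import (
    SimConfig,
    TERMINAL_FATES,
    simulate_branching_lineage,
    well_separated_config,
)


def absorption_oracle_study(seed: int = 0, n_cells: int = 300,
                            n_walks: int = 5000) -> dict:
    """Exact absorption solve vs seeded random-walk estimate on one cohort.

    Builds a velocity-directed fate kernel over ``n_cells`` wild-type cells
    with the three terminal fates declared, solves the absorbing chain
    exactly, and re-estimates every transient cell's fate probabilities
    from ``n_walks`` walks; reports the largest absolute disagreement and
    the row-sum defects of both matrices.
    """
    cfg = SimConfig(n_samples_per_genotype=1, n_cells_per_sample=n_cells,
                    seed=seed)
    out = simulate_branching_lineage(cfg)
    adata = qcm.log_normalize(out.adata)
    wt = adata[(adata.obs["genotype"] == "wt").to_numpy()].copy()
    E = as_dense(wt.layers["lognorm"])
    pcs = cl.select_pcs(E, cl.variable_genes(E, 2000))
    model = vl.estimate_velocity(
        as_dense(wt.layers["spliced"]), as_dense(wt.layers["unspliced"]),
        pcs.scores, gene_names=wt.var_names)
    # the purely velocity-directed kernel: walks follow the velocity field
    tm = vl.velocity_transition_matrix(model, pcs.scores, k_neighbors=15,
                                       kernel_scale=0.1)
    tt = wt.obs["truth_time"].to_numpy()
    terminal = declare_terminal_states(E, wt.var_names, tt,
                                       fates=TERMINAL_FATES,
                                       pt_min=0.85, n_per_fate=20)
    exact = vl.absorption_probabilities(tm, terminal)
    mc = vl.random_walk_oracle(tm, terminal, n_walks=n_walks, seed=seed)
    return {
        "max_abs_difference": float(np.abs(exact.B - mc.B).max()),
        "row_sum_defect_exact": float(np.abs(exact.B.sum(axis=1) - 1).max()),
        "row_sum_defect_mc": float(np.abs(mc.B.sum(axis=1) - 1).max()),
        "n_cells": int(wt.n_obs),
    }


def gamblers_ruin_check() -> dict:
    """Closed-form absorption on the hand-built 4-state chain."""
    import scipy.sparse as sp

    from .pseudotime import TransitionMatrix

    T = np.array([[1, 0, 0, 0],
                  [0.5, 0, 0.5, 0],
                  [0, 0.5, 0, 0.5],
                  [0, 0, 0, 1.0]])
    tm = TransitionMatrix(T=sp.csr_matrix(T), k_neighbors=1, bandwidth=1.0)
    labels = np.array(["A", None, None, "B"], dtype=object)
    fate = vl.absorption_probabilities(tm, labels)
    return {
        "prob_state1": fate.B[1].tolist(),      # expected (2/3, 1/3)
        "error": float(np.abs(fate.B[1] - [2 / 3, 1 / 3]).max()),
    }


def driver_recovery_study(seed: int = 11) -> dict:
    """Sensitivity/specificity of the rho = +-0.25 driver rule.

    Runs the wild-type fate map at cohort scale and classifies genes per
    fate; the constructed up-regulated genes (pure drivers + bifunctional)
    define sensitivity, neutral housekeeping decoys define specificity, and
    the branching signature (cardiac drivers that are also paraxial
    antidrivers) is compared with the constructed bifunctional set.
    """
    cfg = SimConfig(seed=seed)
    out = simulate_branching_lineage(cfg)
    adata = qcm.log_normalize(out.adata)
    wt = adata[(adata.obs["genotype"] == "wt").to_numpy()].copy()
    fate, _, _, _ = genotype_fate_map(wt, PipelineConfig(seed=seed))
    E = as_dense(wt.layers["lognorm"])
    lab = wt.obs["truth_label"].to_numpy()
    genes = wt.var_names.to_numpy()
    drv_f = vl.lineage_drivers(fate, E, "FHF",
                               subset=lineage_subset(lab, "FHF"),
                               gene_names=genes)
    drv_p = vl.lineage_drivers(fate, E, "PM",
                               subset=lineage_subset(lab, "PM"),
                               gene_names=genes)
    truth_up = out.truth_drivers["FHF"]["up"]
    decoys = [g for g in genes
              if out.adata.var.loc[g, "gene_class"] == "housekeeping"]
    sens = float((drv_f.loc[truth_up, "class"] == "driver").mean())
    spec = float((drv_f.loc[decoys, "class"] == "neither").mean())
    sig = vl.branching_signature(drv_f, drv_p)
    bif = set(out.truth_drivers["bifunctional"]["up"])
    bif_frac = (sum(g in bif for g in sig["signature"])
                / max(sig["n_shared"], 1))
    return {"sensitivity": sens, "decoy_specificity": spec,
            "signature_size": sig["n_shared"],
            "signature_bifunctional_fraction": float(bif_frac),
            "n_cells": int(wt.n_obs)}


def cluster_number_study(seed: int = 0, k_max: int = 10) -> dict:
    """K selection and labeling accuracy on 7 well-separated populations."""
    from sklearn.metrics import adjusted_rand_score

    out = simulate_branching_lineage(well_separated_config(seed=seed))
    wt = out.adata[(out.adata.obs["genotype"] == "wt").to_numpy()].copy()
    wt = qcm.normalize(qcm.log_normalize(wt))
    E = as_dense(wt.layers["pearson"])
    pcs = cl.select_pcs(E, cl.variable_genes(E, 2000))
    labelings, reps = cl.cluster_sweep_replicates(pcs, k_max=k_max, seed=seed)
    tree = cl.build_cluster_tree(labelings, replicates=reps)
    k_star, _ = cl.select_cluster_number(tree)
    truth = wt.obs["truth_label"].to_numpy()
    ari = (adjusted_rand_score(truth, labelings[7]) if 7 in labelings
           else float("nan"))
    return {"k_star": int(k_star), "ari_at_7": float(ari),
            "n_pcs": pcs.n_selected}


def projection_study(seed: int = 0) -> dict:
    """Label-transfer accuracy plus the forward/reverse composition control.

    Uses the well-separated cohort with the genotype fate bias enabled, so
    the cardiac populations genuinely shrink in the mutant; reports the
    transfer accuracy against truth and the per-population sign agreement
    of forward vs reverse composition deltas.
    """
    cfg = well_separated_config(seed=seed, branch_prob_mut=0.45)
    out = simulate_branching_lineage(cfg)
    adata = qcm.normalize(qcm.log_normalize(out.adata))
    is_wt = (adata.obs["genotype"] == "wt").to_numpy()
    E = as_dense(adata.layers["pearson"])
    truth = adata.obs["truth_label"].to_numpy()
    vg = cl.variable_genes(E[is_wt], 2000)
    ref, qry = E[is_wt][:, vg], E[~is_wt][:, vg]
    anchors = pj.find_anchors(ref, qry)
    res = pj.transfer_labels(anchors, truth[is_wt])
    accuracy = float((res["label"].to_numpy() == truth[~is_wt]).mean())
    rev = pj.reverse_projection_check(ref, truth[is_wt], qry, truth[~is_wt])
    return {"transfer_accuracy": accuracy,
            "sign_agreement": rev["sign_agreement"],
            "delta_correlation": rev["delta_correlation"]}


def shuffled_projection_control(seed: int = 0) -> dict:
    """Genotype-shuffled negative control for the reverse projection."""
    rng = child_rng(seed, 9)
    cfg = well_separated_config(seed=seed, branch_prob_mut=0.60)
    out = simulate_branching_lineage(cfg)
    adata = qcm.normalize(qcm.log_normalize(out.adata))
    E = as_dense(adata.layers["pearson"])
    truth = adata.obs["truth_label"].to_numpy()
    perm = rng.permutation(adata.n_obs)
    half = adata.n_obs // 2
    a, b = perm[:half], perm[half:]
    vg = cl.variable_genes(E[a], 2000)
    rep = pj.reverse_projection_check(E[a][:, vg], truth[a],
                                      E[b][:, vg], truth[b])
    return {"max_abs_delta": float(rep["table"]["delta_forward"].abs().max()),
            "sign_agreement": rep["sign_agreement"]}


def dgea_null_study(seed: int = 0, n_replicates: int = 200,
                    n_genes: int = 2000, n_per_group: int = 30) -> dict:
    """Family-wise error of Bonferroni-corrected Mann-Whitney DGEA.

    Both groups are drawn from the same negative binomial; a replicate
    counts as a family-wise error when any gene reaches Q < 0.05.
    """
    rng = child_rng(seed, 10)
    errors = 0
    for _ in range(n_replicates):
        lam = rng.gamma(shape=10.0, scale=0.3, size=(2 * n_per_group, n_genes))
        X = rng.poisson(lam).astype(float)
        table = dg.mann_whitney_dgea(np.log1p(X), np.arange(n_per_group),
                                     np.arange(n_per_group, 2 * n_per_group),
                                     min_frac=0.0)
        errors += bool((table["Q"] < 0.05).any())
    return {"fwer": errors / n_replicates, "n_replicates": n_replicates}


def pseudotime_recovery_study(seed: int = 13) -> dict:
    """Latent-time recovery and stage ordering by flood pseudotime."""
    cfg = SimConfig(n_samples_per_genotype=3, n_cells_per_sample=500,
                    seed=seed)
    adata = qcm.log_normalize(simulate_branching_lineage(cfg).adata)
    E = as_dense(adata.layers["lognorm"])
    pcs = cl.select_pcs(E, cl.variable_genes(E, 2000))
    tm = pt.diffusion_transitions(pcs.scores, k_neighbors=15)
    roots = pt.root_cells_by_markers(E, adata.var_names,
                                     root_marker_genes(adata), n_roots=30)
    res = pt.flood_pseudotime(tm, roots, n_floods=30, seed=seed)
    rho = spearmanr(res.pseudotime, adata.obs["truth_time"].to_numpy()).statistic

    staged = SimConfig(
        n_samples_per_genotype=3, n_cells_per_sample=500, seed=seed + 100,
        stages=("EB", "LB", "EHF"),
        stage_time_windows={"EB": (0.0, 0.45), "LB": (0.25, 0.7),
                            "EHF": (0.5, 1.0)})
    sdata = qcm.log_normalize(simulate_branching_lineage(staged).adata)
    Es = as_dense(sdata.layers["lognorm"])
    pcs_s = cl.select_pcs(Es, cl.variable_genes(Es, 2000))
    tms = pt.diffusion_transitions(pcs_s.scores, k_neighbors=15)
    roots_s = pt.root_cells_by_markers(Es, sdata.var_names,
                                       root_marker_genes(sdata), n_roots=30)
    res_s = pt.flood_pseudotime(tms, roots_s, n_floods=30, seed=seed)
    stage = sdata.obs["stage"].to_numpy()
    med = {s: float(np.median(res_s.pseudotime[stage == s]))
           for s in ("EB", "LB", "EHF")}
    return {"spearman_truth_time": float(rho),
            "stage_medians": med,
            "stages_ordered": med["EB"] < med["LB"] < med["EHF"]}


def ks_calibration_study(seed: int = 0, n_power: int = 100,
                         n_null: int = 200) -> dict:
    """Power (0.2-unit shift, n = 1000/side) and size of the KS comparison."""
    rng = child_rng(seed, 11)
    power_hits = 0
    for _ in range(n_power):
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(0.2, 1.2, 1000)
        power_hits += ks_2samp(a, b).pvalue < 0.05
    null_hits = 0
    for _ in range(n_null):
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(0, 1, 1000)
        null_hits += ks_2samp(a, b).pvalue < 0.05
    return {"power": power_hits / n_power, "type_one_error": null_hits / n_null}


def fate_bias_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Generative branch-bias recovery across seeded replicate cohorts."""
    reductions = []
    for s in range(n_seeds):
        r = fate_bias_recovery(seed=base_seed + s)
        reductions.append(r["relative_reduction"])
    reductions = np.asarray(reductions)
    return {
        "n_seeds": n_seeds,
        "n_mutant_lower": int((reductions > 0).sum()),
        "mean_relative_reduction": float(reductions.mean()),
        "generative_relative_reduction": 0.25,
    }
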