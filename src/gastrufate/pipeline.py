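"""End-to-end orchestration of the simulated study.

``run_pipeline`` executes simulate -> QC -> cluster -> project -> DGEA /
composition -> pseudotime -> velocity fate -> drivers -> concordance /
enrichment from one config, writing TSV/MTX outputs per stage plus a run
manifest with content hashes.  Stages are cached by config hash: re-running
with an identical config skips stages whose outputs already exist with
matching hashes, and every random stage derives its seed from the global
seed, so deterministic stages reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import concordance as cc
from . import dgea as dg
from . import io as gio
from . import project as pj
from . import pseudotime as pt
from . import qc as qcm
from . import simdata as sd
from . import velocity as vl
from ._utils import as_dense, child_rng


@dataclass
class PipelineConfig:
    """All pipeline parameters; every stage seed derives from ``seed``."""

    outdir: str = "gastrufate_run"
    seed: int = 0
    # simulation
    n_samples_per_genotype: int = 3
    n_cells_per_sample: int = 500
    n_genes: int = 200
    branch_prob_wt: float = 0.60
    branch_prob_mut: float = 0.45
    population_gap: float = 0.15
    outlier_fraction: float = 0.02
    doublet_fraction: float = 0.02
    # qc
    k_mad: float = 3.0
    # clustering
    k_neighbors: int = 15
    k_max: int = 8
    epsilon_bits: float = 0.2
    stability_epsilon_bits: float = 0.05
    n_variable_genes: int = 2000
    # projection
    k_anchor: int = 5
    # pseudotime
    n_floods: int = 50
    n_roots: int = 20
    # fate
    k_smooth: int = 30
    kernel_scale: float = 0.2
    velocity_weight: float = 0.15
    driver_rho: float = 0.25
    # stats
    alpha: float = 0.05
    window_nt: int = 250
    stages: tuple = ("simulate", "qc", "cluster", "project", "dgea",
                     "pseudotime", "fate", "concordance")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Per-stage parameters, output hashes and wall-clock times."""

    config_hash: str
    stages: Dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outdir: Path, t0: float) -> None:
        files = sorted(p for p in outdir.rglob("*") if p.is_file())
        self.stages[stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
            "wall_seconds": round(time.time() - t0, 3),
        }

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages},
                      fh, indent=1, sort_keys=True)


#: populations on each terminal fate's lineage path; driver correlations are
#: computed within a fate's own lineage, off-lineage populations excluded
LINEAGE_POPULATIONS = {
    "FHF": ("NMP", "CMP", "FHF"),
    "SHF": ("NMP", "CMP", "SHF"),
    "PM": ("NMP", "MMP", "PMP", "PM"),
}


def lineage_subset(labels: np.ndarray, fate: str) -> np.ndarray:
    """Boolean mask of cells on ``fate``'s lineage path."""
    allowed = set(LINEAGE_POPULATIONS[fate])
    return np.array([l in allowed for l in np.asarray(labels)])


def connected_neighbors(builder, k_start: int, max_k: int = 120):
    """Call ``builder(k)`` with growing k until the kNN graph connects.

    Separated populations can disconnect a small-k graph; doubling the
    neighborhood until the graph connects keeps the trajectory analyses
    defined.  Returns (result, k_used).
    """
    k = k_start
    while True:
        try:
            return builder(k), k
        except ValueError as err:
            if "disconnected" not in str(err) or 2 * k > max_k:
                raise
            k *= 2


def root_marker_genes(adata) -> list:
    """Genes of the early root program (pseudotime origin)."""
    if "root_marker" in adata.var:
        return list(adata.var_names[adata.var["root_marker"].to_numpy(dtype=bool)])
    return [g for g in adata.var_names if str(g).startswith("MkNMP")]


def declare_terminal_states(
    E: np.ndarray,
    var_names,
    pseudotime_values: np.ndarray,
    fates=("FHF", "SHF", "PM"),
    pt_min: float = 0.6,
    n_per_fate: int = 25,
) -> np.ndarray:
    """Explicit terminal-state declaration from marker programs.

    Among cells past ``pt_min`` pseudotime, the ``n_per_fate`` strongest
    scorers of each terminal fate's marker program are declared terminal for
    that fate (ties to the higher-scoring fate).  Returns a per-cell object
    array: fate name or None.
    """
    import re

    n = E.shape[0]
    late = pseudotime_values >= pt_min
    if not late.any():
        raise ValueError("no cells past the pseudotime threshold")
    scores = {}
    for f in fates:
        gi = [i for i, g in enumerate(var_names)
              if re.fullmatch(rf"Mk{re.escape(f)}\d+", str(g))]
        if not gi:
            raise ValueError(f"no marker genes found for fate {f}")
        scores[f] = np.asarray(E)[:, gi].mean(axis=1)
    terminal = np.full(n, None, dtype=object)
    best_score = np.full(n, -np.inf)
    for f in fates:
        s = np.where(late, scores[f], -np.inf)
        top = np.argsort(-s, kind="stable")[:n_per_fate]
        for c in top:
            if np.isfinite(s[c]) and s[c] > best_score[c]:
                terminal[c] = f
                best_score[c] = s[c]
    return terminal


# marker programs used to annotate clusters with population names
def _annotate_clusters(E: np.ndarray, labels: np.ndarray,
                       var_names, populations) -> dict:
    """Name each cluster after the population whose marker program tops it."""
    import re

    names = {}
    marker_idx = {
        p.name: [i for i, g in enumerate(var_names)
                 if re.fullmatch(rf"Mk{re.escape(p.name)}\d+", str(g))]
        for p in populations
    }
    for c in np.unique(labels):
        rows = labels == c
        scores = {p: E[rows][:, gi].mean() for p, gi in marker_idx.items() if gi}
        names[int(c)] = max(scores, key=scores.get)
    return names


def run_pipeline(config: PipelineConfig, resume: bool = True) -> RunManifest:
    """Run all enabled stages in dependency order; returns the manifest.

    A stage whose output directory already carries a manifest entry with the
    current config hash is skipped when ``resume``.  Failures abort with the
    stage name and a reproduction hint.
    """
    out_root = Path(config.outdir)
    out_root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_root / "config.yaml")
    manifest = RunManifest(config_hash=config.hash())
    manifest_path = out_root / "manifest.json"
    prior = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == manifest.config_hash:
            prior = old.get("stages", {})

    state: dict = {}
    for stage in config.stages:
        stage_dir = out_root / stage
        t0 = time.time()
        runner = _STAGES[stage]
        try:
            cached = stage in prior and stage_dir.exists()
            state = runner(config, state, stage_dir, recompute=not cached)
            if cached:
                manifest.stages[stage] = dict(prior[stage], cached=True)
            else:
                manifest.record(stage, stage_dir, t0)
        except Exception as err:
            raise RuntimeError(
                f"stage {stage!r} failed ({err}); reproduce with "
                f"`gastrufate run-all --config {out_root / 'config.yaml'}`"
            ) from err
        manifest.save(manifest_path)
    return manifest


# --------------------------------------------------------------------------
# stages; each takes and returns the shared in-memory state


def _sim_config(config: PipelineConfig) -> sd.SimConfig:
    return sd.SimConfig(
        n_samples_per_genotype=config.n_samples_per_genotype,
        n_cells_per_sample=config.n_cells_per_sample,
        n_genes=config.n_genes,
        branch_prob_wt=config.branch_prob_wt,
        branch_prob_mut=config.branch_prob_mut,
        population_gap=config.population_gap,
        outlier_fraction=config.outlier_fraction,
        doublet_fraction=config.doublet_fraction,
        seed=config.seed,
    )


def _stage_simulate(config, state, outdir: Path, recompute=True):
    scfg = _sim_config(config)
    out = sd.inject_qc_artifacts(sd.simulate_branching_lineage(scfg), scfg)
    state["sim"] = out
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_mtx_layers(out.adata, outdir / "counts")
        out.adata.obs.to_csv(outdir / "truth_cells.tsv", sep="\t")
        out.adata.var.to_csv(outdir / "truth_genes.tsv", sep="\t")
        pd.DataFrame(out.adata.obsm["truth_fate_prob"],
                     columns=list(sd.TERMINAL_FATES),
                     index=out.adata.obs_names).to_csv(
            outdir / "truth_fate_prob.tsv", sep="\t")
    return state


def _stage_qc(config, state, outdir: Path, recompute=True):
    adata = state["sim"].adata
    metrics = qcm.compute_cell_qc(adata)
    keep, report = qcm.mad_filter(
        metrics, qcm.QCThresholds(k_mad=config.k_mad),
        stage_group=adata.obs["stage"].to_numpy())
    kept = adata[keep.to_numpy()].copy()
    kept = qcm.subsample_depth(kept, seed=config.seed)
    kept = qcm.normalize(kept)
    kept = qcm.log_normalize(kept)
    state["adata"] = kept
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        pd.Series(kept.obs_names, name="barcode").to_csv(
            outdir / "kept_barcodes.tsv", sep="\t", index=False)
    return state


def _stage_cluster(config, state, outdir: Path, recompute=True):
    adata = state["adata"]
    wt = adata[adata.obs["genotype"] == "wt"].copy()
    E = as_dense(wt.layers["pearson"])
    vg = cl.variable_genes(E, config.n_variable_genes)
    pcs = cl.select_pcs(E, vg)
    labelings, reps = cl.cluster_sweep_replicates(
        pcs, k_neighbors=config.k_neighbors, k_max=config.k_max,
        seed=config.seed)
    tree = cl.build_cluster_tree(labelings, replicates=reps)
    k_star, curve = cl.select_cluster_number(
        tree, config.epsilon_bits, config.stability_epsilon_bits)
    labels = labelings[k_star]
    names = _annotate_clusters(E, labels, wt.var_names,
                               sd.DEFAULT_POPULATIONS)
    wt_named = np.array([names[int(c)] for c in labels], dtype=object)
    state.update(wt=wt, wt_pcs=pcs, wt_var_genes=vg, wt_labels=labels,
                 wt_named_labels=wt_named, k_star=k_star, tree=tree)
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        lab_df = pd.DataFrame({f"k{k}": v for k, v in labelings.items()},
                              index=wt.obs_names)
        lab_df["chosen"] = labels
        lab_df["population"] = wt_named
        lab_df.to_csv(outdir / "labelings.tsv", sep="\t")
        tree.edges.to_csv(outdir / "tree_edges.tsv", sep="\t", index=False)
        curve.rename("mean_entropy_bits").to_csv(outdir / "entropy_curve.tsv", sep="\t")
        with open(outdir / "k_star.txt", "w") as fh:
            fh.write(str(k_star) + "\n")
    return state


def _stage_project(config, state, outdir: Path, recompute=True):
    adata = state["adata"]
    wt = state["wt"]
    mut = adata[adata.obs["genotype"] == "mut"].copy()
    vg = state["wt_var_genes"]
    ref_E = as_dense(wt.layers["pearson"])[:, vg]
    qry_E = as_dense(mut.layers["pearson"])[:, vg]
    anchors = pj.find_anchors(ref_E, qry_E, k_anchor=config.k_anchor)
    transfer = pj.transfer_labels(anchors, state["wt_named_labels"])
    mut_labels = transfer["label"].to_numpy()

    # reverse control: cluster the mutant independently, project wt onto it
    mut_pcs = cl.select_pcs(as_dense(mut.layers["pearson"]), vg)
    mut_sweep, mut_reps = cl.cluster_sweep_replicates(
        mut_pcs, k_neighbors=config.k_neighbors, k_max=config.k_max,
        seed=config.seed + 1)
    mut_tree = cl.build_cluster_tree(mut_sweep, replicates=mut_reps)
    mut_k, _ = cl.select_cluster_number(
        mut_tree, config.epsilon_bits, config.stability_epsilon_bits)
    mut_own = mut_sweep[mut_k]
    mut_names = _annotate_clusters(as_dense(mut.layers["pearson"]), mut_own,
                                   mut.var_names, sd.DEFAULT_POPULATIONS)
    mut_named = np.array([mut_names[int(c)] for c in mut_own], dtype=object)
    reverse = pj.reverse_projection_check(
        ref_E, state["wt_named_labels"], qry_E, mut_named,
        k_anchor=config.k_anchor)

    state.update(mut=mut, mut_labels=mut_labels, mut_own_labels=mut_named,
                 anchors=anchors, reverse=reverse)
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        anchors.pairs.to_csv(outdir / "anchors.tsv", sep="\t", index=False)
        transfer.assign(barcode=mut.obs_names).to_csv(
            outdir / "transferred_labels.tsv", sep="\t", index=False)
        reverse["table"].to_csv(outdir / "forward_reverse_deltas.tsv", sep="\t")
    return state


def _stage_dgea(config, state, outdir: Path, recompute=True):
    adata = state["adata"]
    wt, mut = state["wt"], state["mut"]
    E_wt = as_dense(wt.layers["lognorm"])
    E_mut = as_dense(mut.layers["lognorm"])
    E = np.vstack([E_wt, E_mut])
    is_wt = np.arange(E.shape[0]) < E_wt.shape[0]
    genes = wt.var_names.to_numpy()
    table = dg.mann_whitney_dgea(E, ~is_wt, is_wt, gene_names=genes)

    labels = np.concatenate([state["wt_named_labels"], state["mut_labels"]])
    samples = np.concatenate([wt.obs["sample"].to_numpy(), mut.obs["sample"].to_numpy()])
    genotypes = np.concatenate([wt.obs["genotype"].to_numpy(), mut.obs["genotype"].to_numpy()])
    prop, tests = dg.composition_test(labels, samples, genotypes)

    state.update(dgea_genotype=table, composition=(prop, tests))
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "dgea_mut_vs_wt.tsv", sep="\t")
        prop.to_csv(outdir / "composition_proportions.tsv", sep="\t")
        tests.to_csv(outdir / "composition_tests.tsv", sep="\t")
    return state


def _stage_pseudotime(config, state, outdir: Path, recompute=True):
    adata = state["adata"]
    vg = state["wt_var_genes"]
    E = as_dense(adata.layers["pearson"])
    pcs = cl.select_pcs(E, vg)
    tm, _ = connected_neighbors(
        lambda k: pt.diffusion_transitions(pcs.scores, k_neighbors=k),
        config.k_neighbors)
    roots = pt.root_cells_by_markers(
        as_dense(adata.layers["lognorm"]), adata.var_names,
        root_marker_genes(adata), n_roots=config.n_roots)
    res = pt.flood_pseudotime(tm, roots, n_floods=config.n_floods,
                              seed=config.seed)
    is_wt = (adata.obs["genotype"] == "wt").to_numpy()
    ks = pt.compare_pseudotime(res.pseudotime[is_wt], res.pseudotime[~is_wt])
    state.update(pt_embedding=pcs.scores, pseudotime=res, pt_ks=ks)
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        res.as_series(adata.obs_names).to_csv(outdir / "pseudotime.tsv", sep="\t")
        ks.to_csv(outdir / "ks_genotype.tsv", sep="\t")
    return state


def genotype_fate_map(adata, config: PipelineConfig):
    """Velocity, mixed transition kernel and fate probabilities for one genotype.

    Returns (fate, embedding, velocity model, terminal labels).  Terminal
    states are declared explicitly: the strongest scorers of each terminal
    fate's marker program among late cells (latent ordering proxied by the
    first diffusion flood when pseudotime is not supplied).
    """
    E = as_dense(adata.layers["lognorm"])
    vg = cl.variable_genes(E, config.n_variable_genes)
    pcs = cl.select_pcs(E, vg)
    model = vl.estimate_velocity(
        as_dense(adata.layers["spliced"]), as_dense(adata.layers["unspliced"]),
        pcs.scores, k_smooth=config.k_smooth, gene_names=adata.var_names)
    tm, _ = connected_neighbors(
        lambda k: vl.fate_transition_matrix(
            model, pcs.scores, k_neighbors=k,
            kernel_scale=config.kernel_scale,
            velocity_weight=config.velocity_weight),
        config.k_neighbors)
    dt, _ = connected_neighbors(
        lambda k: pt.diffusion_transitions(pcs.scores, k_neighbors=k),
        config.k_neighbors)
    roots = pt.root_cells_by_markers(E, adata.var_names,
                                     root_marker_genes(adata),
                                     n_roots=config.n_roots)
    ptime = pt.flood_pseudotime(dt, roots, n_floods=max(10, config.n_floods // 5),
                                seed=config.seed).pseudotime
    score_layer = ("pearson" if "pearson" in adata.layers else "lognorm")
    terminal = declare_terminal_states(
        as_dense(adata.layers[score_layer]), adata.var_names, ptime,
        fates=sd.TERMINAL_FATES)
    fate = vl.absorption_probabilities(tm, terminal)
    return fate, pcs.scores, model, terminal


def _stage_fate(config, state, outdir: Path, recompute=True):
    adata = state["adata"]
    genes = adata.var_names.to_numpy()
    is_wt = (adata.obs["genotype"] == "wt").to_numpy()

    # fate maps are computed per genotype: walks must not mix genotypes,
    # since the branch bias is encoded in each genotype's own cell density
    fates, embeddings = {}, {}
    for gt, mask in (("wt", is_wt), ("mut", ~is_wt)):
        sub = adata[mask].copy()
        fate, emb, model, terminal = genotype_fate_map(sub, config)
        fates[gt], embeddings[gt] = fate, emb
        if gt == "wt":
            wt_model = model

    # genotype comparison of progenitor fate probabilities (cardiac = FHF+SHF)
    pt_vals = state["pseudotime"].pseudotime

    def cardiac_mean(gt, mask):
        fate = fates[gt]
        sub_labels = (state["wt_named_labels"] if gt == "wt"
                      else state["mut_labels"])
        pre = np.asarray([l == "NMP" for l in sub_labels])
        if not pre.any():
            # no cluster annotated as the progenitor pool: fall back to the
            # earliest quartile of pseudotime within this genotype
            sub_pt = pt_vals[mask]
            pre = sub_pt <= np.quantile(sub_pt, 0.25)
        cols = [list(fate.fates).index(f) for f in ("FHF", "SHF")
                if f in fate.fates]
        return float(fate.B[pre][:, cols].sum(axis=1).mean())

    card_wt = cardiac_mean("wt", is_wt)
    card_mut = cardiac_mean("mut", ~is_wt)
    bias = {"cardiac_prob_wt": card_wt, "cardiac_prob_mut": card_mut,
            "relative_reduction": (card_wt - card_mut) / card_wt}

    # drivers are defined on the wild-type fate map, per lineage subset;
    # genotype misexpression of those drivers is then tested separately
    E_wt = as_dense(adata[is_wt].layers["lognorm"])
    wt_fate = fates["wt"]
    drv = {f: vl.lineage_drivers(
               wt_fate, E_wt, f,
               subset=lineage_subset(state["wt_named_labels"], f),
               gene_names=genes, rho_threshold=config.driver_rho)
           for f in wt_fate.fates}
    sig = vl.branching_signature(drv["FHF"], drv["PM"])
    chi = dg.driver_direction_from_dgea(
        state["dgea_genotype"],
        drv["FHF"].index[drv["FHF"]["class"] == "driver"],
        alpha=config.alpha)

    state.update(velocity=wt_model, fates=fates, fate=wt_fate, drivers=drv,
                 signature=sig, driver_chisq=chi, fate_bias=bias)
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        for gt, mask in (("wt", is_wt), ("mut", ~is_wt)):
            fates[gt].to_frame(adata.obs_names[mask]).to_csv(
                outdir / f"fate_probabilities_{gt}.tsv", sep="\t")
        for f, t in drv.items():
            t.to_csv(outdir / f"drivers_{f}.tsv", sep="\t")
        with open(outdir / "fate_bias.json", "w") as fh:
            json.dump(bias, fh, indent=1)
        with open(outdir / "branching_signature.json", "w") as fh:
            json.dump(sig, fh, indent=1)
        with open(outdir / "driver_chisq.json", "w") as fh:
            json.dump(chi, fh, indent=1)
    return state


def _stage_concordance(config, state, outdir: Path, recompute=True):
    """Concordance/enrichment on synthetic external-study doubles."""
    rng = child_rng(config.seed, 8)
    table = state["dgea_genotype"]
    universe = list(table.index)
    self_deg = {g: r["direction"] for g, r in table.iterrows()
                if r["Q"] < config.alpha}
    self_lfc = {g: float(np.log2(r["fold_change"])) for g, r in table.iterrows()}

    # synthetic external study: attenuated effects (slope 0.8) + noise,
    # sharing a fraction of DEGs — a test double, not real external data
    ext_lfc = {g: 0.8 * v + rng.normal(0, 0.1) for g, v in self_lfc.items()}
    ext_deg = {g: ("up" if ext_lfc[g] > 0 else "down")
               for g in self_deg if rng.random() < 0.7}

    overlap = cc.deg_overlap(self_deg, ext_deg, universe)
    reg = cc.foldchange_regression(self_lfc, ext_lfc)

    # synthetic promoter peaks enriched at DEG TSSs
    var = state["adata"].var
    gm = pd.DataFrame({"chromosome": var["chromosome"],
                       "strand": var["strand"], "tss": var["tss"]},
                      index=var.index)
    peak_rows = []
    for g in universe:
        p_peak = 0.6 if g in self_deg else 0.2
        if rng.random() < p_peak:
            t = int(gm.loc[g, "tss"]) + int(rng.integers(-200, 200))
            peak_rows.append({"chromosome": gm.loc[g, "chromosome"],
                              "start": max(t - 50, 0), "end": t + 50})
    peaks = pd.DataFrame(peak_rows)
    annot = cc.annotate_tss_peaks(gm, peaks, window_nt=config.window_nt)
    enrich = cc.binding_site_enrichment(
        {g: g in self_deg for g in universe}, annot, universe)

    gene_sets = {f: state["sim"].truth_drivers[f]["up"]
                 for f in sd.TERMINAL_FATES}
    ora_res = cc.ora(list(self_deg), gene_sets, universe)
    stat = {g: self_lfc[g] for g in universe}
    gsea_res = cc.gsea(stat, gene_sets, n_perm=200, seed=config.seed)

    state.update(concordance=overlap, fc_regression=reg,
                 site_enrichment=enrich, ora=ora_res, gsea=gsea_res)
    if recompute:
        outdir.mkdir(parents=True, exist_ok=True)
        overlap.to_csv(outdir / "deg_overlap.tsv", sep="\t")
        with open(outdir / "fc_regression.json", "w") as fh:
            json.dump(reg, fh, indent=1)
        with open(outdir / "site_enrichment.json", "w") as fh:
            json.dump(enrich, fh, indent=1)
        ora_res.to_csv(outdir / "ora.tsv", sep="\t")
        gsea_res.to_csv(outdir / "gsea.tsv", sep="\t")
    return state


def fate_bias_recovery(seed: int, config: PipelineConfig | None = None,
                       sim_config: "sd.SimConfig | None" = None) -> dict:
    """Parameter-recovery study: generative branch bias vs measured fate bias.

    Simulates the full two-genotype cohort, builds each genotype's fate map,
    and compares the mean cardiac (FHF+SHF) absorption probability among
    progenitor cells between genotypes.  Returns the per-genotype means, the
    measured relative reduction, and the generative one.
    """
    config = config or PipelineConfig(seed=seed)
    scfg = sim_config or sd.SimConfig(seed=seed)
    out = sd.simulate_branching_lineage(scfg)
    adata = qcm.log_normalize(out.adata)
    res = {}
    for gt in ("wt", "mut"):
        sub = adata[(adata.obs["genotype"] == gt).to_numpy()].copy()
        fate, _, _, _ = genotype_fate_map(sub, config)
        pre = (sub.obs["truth_time"] < scfg.branch_time).to_numpy()
        cols = [list(fate.fates).index(f) for f in ("FHF", "SHF")
                if f in fate.fates]
        res[gt] = float(fate.B[pre][:, cols].sum(axis=1).mean())
    gen_rel = 1.0 - scfg.branch_prob_mut / scfg.branch_prob_wt
    return {"cardiac_prob_wt": res["wt"], "cardiac_prob_mut": res["mut"],
            "relative_reduction": (res["wt"] - res["mut"]) / res["wt"],
            "generative_relative_reduction": gen_rel}


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "project": _stage_project,
    "dgea": _stage_dgea,
    "pseudotime": _stage_pseudotime,
    "fate": _stage_fate,
    "concordance": _stage_concordance,
}
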