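"""Synthetic branching-lineage scRNA-seq generator with full ground truth.

The generator emulates a gastrulation-stage study design: two genotypes
("wt" and a heterozygous "mut" expressing one gene at ~50% of wt level),
several embryo samples per genotype, and a mesodermal lineage that starts
from a bipotent progenitor pool (NMP-like), branches into a cardiac and a
paraxial trajectory, with the cardiac trajectory splitting once more into
two terminal heart-field fates.  The branch choice at the cardiac/paraxial
decision is genotype-dependent, which is the fate bias the downstream fate
mapping must recover.

Per-gene expression follows simple splicing kinetics: transcription rate
alpha(t) (piecewise linear in latent time, branch-dependent), splicing rate
beta and degradation rate gamma.  The unspliced moiety is kept at its fast
equilibrium u(t) = alpha(t)/beta, and the spliced moiety follows
ds/dt = beta*u - gamma*s, integrated exactly per grid interval with alpha
frozen at the interval midpoint.  Counts are negative-binomial draws around
library-size-scaled expectations, so a kNN-smoothed u - gamma_hat*s velocity
signal points "uphill" in latent time wherever alpha is still changing.

Ground truth recorded per cell: population label, latent time, committed
branch, generative terminal-fate probabilities, cycle phase, artifact flag.
Ground truth per gene: functional class (markers, fate drivers/antidrivers,
bifunctional branch genes, a persistent-regulator gene, a chromosomally
ordered positional cluster, mitochondrial and cycle markers, neutral
housekeeping decoys).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import anndata as ad
import numpy as np
import scipy.sparse as sp

from ._utils import child_rng

TERMINAL_FATES = ("FHF", "SHF", "PM")

#: latent-time grid resolution for the kinetic integrator
N_GRID = 200


@dataclass(frozen=True)
class Population:
    """One population: a latent-time window on one branch segment.

    ``branch`` is one of "root" (pre-branch), "A" (cardiac, pre-subsplit),
    "A1"/"A2" (terminal heart fields), "B" (paraxial).
    """

    name: str
    branch: str
    t_lo: float
    t_hi: float


DEFAULT_POPULATIONS: Tuple[Population, ...] = (
    Population("NMP", "root", 0.00, 0.40),
    Population("CMP", "A", 0.40, 0.70),
    Population("FHF", "A1", 0.70, 1.00),
    Population("SHF", "A2", 0.70, 1.00),
    Population("MMP", "B", 0.40, 0.70),
    Population("PMP", "B", 0.70, 0.85),
    Population("PM", "B", 0.85, 1.00),
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and kinetic parameters of the generator.

    Defaults mirror the emulated study at desk scale: 6 embryos per
    genotype, ~1000 cells per embryo, a 200-gene panel, wt cardiac branch
    probability 0.60 reduced to 0.45 in the mutant, and a regulator gene
    that decays along latent time in wt but persists in the mutant.
    """

    n_samples_per_genotype: int = 6
    n_cells_per_sample: int = 1000
    n_genes: int = 200
    populations: Tuple[Population, ...] = DEFAULT_POPULATIONS
    branch_time: float = 0.40
    subsplit_time: float = 0.70
    branch_prob_wt: float = 0.60
    branch_prob_mut: float = 0.45
    subsplit_prob: float = 0.50
    # gene-program sizes
    n_markers_per_pop: int = 8
    n_drivers_A: int = 15
    n_antidrivers_A: int = 15
    n_bifunctional: int = 10
    n_positional: int = 10
    n_mito: int = 10
    n_cycle_s: int = 12
    n_cycle_g2m: int = 12
    # kinetics, rates per unit latent time: transcript half-life ~0.07 of
    # the trajectory, i.e. expression tracks alpha(t) with a short lag
    alpha_hi: float = 120.0
    alpha_lo: float = 4.0
    beta_mean: float = 20.0
    gamma_mean: float = 10.0
    rate_sigma: float = 0.25
    # genotype effects
    driver_effect_mut: float = 0.6
    regulator_profile: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"wt": (1.0, 0.1), "mut": (1.0, 0.85)}
    )
    # measurement model; depth and mito-load spreads are bounded, emulating
    # data whose empty-droplet and debris tails were already removed by cell
    # calling — the heavy tails re-enter only via injected QC artifacts
    target_depth: float = 1200.0
    libsize_log_halfwidth: float = 0.25
    mito_load_halfwidth: float = 0.6
    background_halfwidth: float = 0.5
    marker_turnover_factor: float = 3.0
    nb_dispersion: float = 10.0
    mito_base_fraction: float = 0.05
    cycle_boost: float = 4.0
    phase_probs: Tuple[float, float, float] = (0.5, 0.25, 0.25)  # G1, S, G2M
    # QC artifacts (applied by inject_qc_artifacts, not by simulate)
    outlier_fraction: float = 0.0
    doublet_fraction: float = 0.0
    # population separation: fraction of each population's latent-time
    # window trimmed from both ends when sampling cells; 0 keeps a fully
    # continuous trajectory, larger values leave gaps between populations
    # (well-separated blobs for clustering studies)
    population_gap: float = 0.0
    # study structure
    stages: Tuple[str, ...] = ("LB",)
    stage_time_windows: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        probs = [self.branch_prob_wt, self.branch_prob_mut, self.subsplit_prob,
                 self.outlier_fraction, self.doublet_fraction, *self.phase_probs]
        for p in probs:
            if not np.isfinite(p) or p < 0 or p > 1:
                raise ValueError(f"probability out of [0, 1] or NaN: {p!r}")
        for r in (self.alpha_hi, self.alpha_lo, self.beta_mean, self.gamma_mean):
            if not np.isfinite(r) or r <= 0:
                raise ValueError(f"kinetic rate must be positive: {r!r}")
        for pop in self.populations:
            if not (0.0 <= pop.t_lo < pop.t_hi <= 1.0):
                raise ValueError(f"population {pop.name}: empty or out-of-range interval")
        n_prog = (len(self.populations) * self.n_markers_per_pop + self.n_drivers_A
                  + self.n_antidrivers_A + self.n_bifunctional + self.n_positional
                  + self.n_mito + self.n_cycle_s + self.n_cycle_g2m + 1)
        if n_prog > self.n_genes:
            raise ValueError(f"n_genes={self.n_genes} too small for gene programs ({n_prog})")


@dataclass
class SimOutput:
    """Counts plus ground truth.

    ``adata.X`` holds spliced counts; layers "spliced"/"unspliced" hold both
    moieties.  obs carries sample/genotype/stage and all truth columns;
    obsm["truth_fate_prob"] the generative terminal-fate probabilities.
    """

    adata: ad.AnnData
    truth_drivers: Dict[str, Dict[str, List[str]]]
    config: SimConfig

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs


def well_separated_config(seed: int = 0, n_samples_per_genotype: int = 2,
                          n_cells_per_sample: int = 500, **overrides) -> SimConfig:
    """Study conditions for clustering / label-transfer benchmarks.

    Populations become balanced, discrete blobs: inter-population gaps in
    latent time, no within-population positional-pulse gradient, all cells
    in G1 (no cycle substructure), and no genotype fate bias by default (so
    both genotypes carry the same seven populations).
    """
    base = dict(
        n_samples_per_genotype=n_samples_per_genotype,
        n_cells_per_sample=n_cells_per_sample,
        branch_prob_mut=0.60,
        population_gap=0.5,
        n_positional=0,
        phase_probs=(1.0, 0.0, 0.0),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# gene-program construction


def _assign_gene_programs(cfg: SimConfig, rng: np.random.Generator):
    """Partition gene indices into functional classes."""
    idx = np.arange(cfg.n_genes)
    pos = 0

    def take(n):
        nonlocal pos
        out = idx[pos:pos + n]
        pos += n
        return out

    programs = {}
    for p in cfg.populations:
        programs[f"marker:{p.name}"] = take(cfg.n_markers_per_pop)
    programs["driver_A"] = take(cfg.n_drivers_A)
    programs["antidriver_A"] = take(cfg.n_antidrivers_A)
    programs["bifunctional"] = take(cfg.n_bifunctional)
    programs["regulator"] = take(1)
    programs["positional"] = take(cfg.n_positional)
    programs["mito"] = take(cfg.n_mito)
    programs["cycle_S"] = take(cfg.n_cycle_s)
    programs["cycle_G2M"] = take(cfg.n_cycle_g2m)
    programs["housekeeping"] = idx[pos:]
    return programs


def _ramp(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Piecewise-linear 0->1 ramp between t0 and t1."""
    return np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)


def _alpha_profiles(cfg: SimConfig, programs, genotype: str) -> Dict[str, np.ndarray]:
    """alpha(t) on the fixed grid, per terminal path, genes x grid.

    Paths share the pre-branch segment; fate programs diverge after
    ``branch_time`` (and after ``subsplit_time`` for the heart fields).
    """
    t = np.linspace(0.0, 1.0, N_GRID)
    lo, hi = cfg.alpha_lo, cfg.alpha_hi
    base = np.full((cfg.n_genes, N_GRID), lo)

    paths = {"A1": base.copy(), "A2": base.copy(), "B": base.copy()}
    path_branches = {"A1": ("root", "A", "A1"), "A2": ("root", "A", "A2"),
                     "B": ("root", "B")}

    # population markers: on inside the population window, on its branch
    # only.  Half of the root population's markers fade by the middle of
    # the root window (an early, epiblast-like program), giving pseudotime
    # an unambiguous origin
    for p in cfg.populations:
        g = programs[f"marker:{p.name}"]
        edge = 0.05
        windows = [(p.t_lo, p.t_hi)] * len(g)
        if p.branch == "root":
            t_mid = 0.5 * (p.t_lo + p.t_hi)
            n_early = (len(g) + 1) // 2
            windows[:n_early] = [(p.t_lo, t_mid)] * n_early
        for gi, (w_lo, w_hi) in zip(g, windows):
            window = _ramp(t, w_lo - edge, w_lo) * (1 - _ramp(t, w_hi, w_hi + edge))
            for path, branches in path_branches.items():
                if p.branch in branches:
                    paths[path][gi, :] = lo + (hi - lo) * window

    # fate-A drivers: rise gently through the progenitor pool (from half
    # their plateau, keeping them detected everywhere), then keep rising
    # along the cardiac branch while plateauing on the paraxial branch —
    # they track commitment to the cardiac fate without anticorrelating
    # with the sibling fate
    up_A = _ramp(t, cfg.branch_time, 1.0)
    g = programs["driver_A"]
    mid = lo + 0.45 * (hi - lo)
    pre = 0.5 * mid + 0.5 * mid * _ramp(t, 0.0, cfg.branch_time)
    for path in ("A1", "A2"):
        paths[path][g, :] = pre + (hi - mid) * up_A
    paths["B"][g, :] = pre
    # fate-A antidrivers: high at root, decay along cardiac, persist on B
    g = programs["antidriver_A"]
    down_A = 1.0 - _ramp(t, cfg.branch_time, 1.0)
    for path in ("A1", "A2"):
        paths[path][g, :] = lo + (hi - lo) * down_A
    paths["B"][g, :] = hi
    # bifunctional: mid at root, up on cardiac, down on paraxial — the
    # constructed "branching signature" genes
    g = programs["bifunctional"]
    mid_b = lo + 0.2 * (hi - lo)
    for path in ("A1", "A2"):
        paths[path][g, :] = mid_b + (hi - mid_b) * up_A
    paths["B"][g, :] = mid_b - (mid_b - lo) * _ramp(t, cfg.branch_time, 1.0)

    # persistent regulator: genotype-specific latent-time profile
    g = programs["regulator"]
    start, end = cfg.regulator_profile[genotype]
    prof = lo + (hi - lo) * (start + (end - start) * t)
    for path in paths:
        paths[path][g, :] = np.clip(prof, lo, None)

    # positional cluster: staggered on/off pulses, shared across branches;
    # onsets staggered from before t = 0 so the number of active pulses is
    # stationary across the trajectory
    g = programs["positional"]
    m = len(g)
    width = 0.35
    for k, gi in enumerate(g):
        t_on = -width + k / max(m, 1) * (1 + width)
        pulse = _ramp(t, t_on, t_on + 0.05) * (1 - _ramp(t, t_on + width, t_on + width + 0.05))
        if t_on < 0 and t_on + width > 0:
            pulse = np.maximum(pulse, (t <= t_on + width) * 1.0
                               * (1 - _ramp(t, t_on + width, t_on + width + 0.05)))
        for path in paths:
            paths[path][gi, :] = lo + (hi - lo) * pulse

    # cycle markers and housekeeping stay at a moderate constant level
    for key in ("cycle_S", "cycle_G2M", "housekeeping"):
        g = programs[key]
        for path in paths:
            paths[path][g, :] = lo + 0.25 * (hi - lo)

    # mutant underexpresses fate-A drivers (incl. bifunctional)
    if genotype == "mut":
        g = np.concatenate([programs["driver_A"], programs["bifunctional"]])
        for path in paths:
            paths[path][g, :] *= cfg.driver_effect_mut

    # mito genes: proportional to the cell's total transcription at each
    # time point, so the expected mito fraction is constant across the
    # trajectory (mitochondrial load scales with cell activity)
    g = programs["mito"]
    frac = cfg.mito_base_fraction
    for path in paths:
        other_total = np.delete(paths[path], g, axis=0).sum(axis=0)
        paths[path][g, :] = frac / (1 - frac) * other_total / max(len(g), 1)
    return paths


def _integrate_kinetics(alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray):
    """Expected (u, s) on the grid given alpha(t) (genes x grid).

    u(t) = alpha(t)/beta (fast splicing equilibrium); s integrated exactly
    per interval with alpha held at the interval midpoint:
    s_{k+1} = s_k e^{-g dt} + (abar/g)(1 - e^{-g dt}); s_0 = alpha_0/gamma.
    """
    n_genes, n_grid = alpha.shape
    dt = 1.0 / (n_grid - 1)
    u = alpha / beta[:, None]
    s = np.empty_like(alpha)
    s[:, 0] = alpha[:, 0] / gamma
    decay = np.exp(-gamma * dt)
    for k in range(n_grid - 1):
        abar = 0.5 * (alpha[:, k] + alpha[:, k + 1])
        s[:, k + 1] = s[:, k] * decay + (abar / gamma) * (1.0 - decay)
    return u, s


def expected_moments(cfg: SimConfig, genotype: str = "wt"):
    """Expected (u, s) per terminal path on the integration grid.

    Exposed so tests can compare Monte-Carlo count means against the
    closed-form integrator.  Returns (grid, {path: (u, s)}), arrays
    genes x grid.
    """
    cfg.validate()
    rng = child_rng(cfg.seed, 0)
    programs = _assign_gene_programs(cfg, rng)
    beta, gamma = _sample_rates(cfg, rng)
    out = {}
    for path, alpha in _alpha_profiles(cfg, programs, genotype).items():
        out[path] = _integrate_kinetics(alpha, beta, gamma)
    return np.linspace(0, 1, N_GRID), out


def _sample_rates(cfg: SimConfig, rng: np.random.Generator):
    beta = cfg.beta_mean * np.exp(rng.normal(0, cfg.rate_sigma, cfg.n_genes))
    gamma = cfg.gamma_mean * np.exp(rng.normal(0, cfg.rate_sigma, cfg.n_genes))
    # population markers turn over faster (both rates scaled, preserving the
    # u/s ratio), so expression tracks the population window sharply instead
    # of lingering into successor populations
    programs = _assign_gene_programs(cfg, rng)
    fast = np.concatenate([programs[k] for k in programs if k.startswith("marker:")])
    beta[fast] *= cfg.marker_turnover_factor
    gamma[fast] *= cfg.marker_turnover_factor
    return beta, gamma


# ---------------------------------------------------------------------------
# cell sampling


def _population_of(cfg: SimConfig, branch: np.ndarray, t: np.ndarray) -> np.ndarray:
    labels = np.empty(t.shape, dtype=object)
    seg = {"A1": ("root", "A", "A1"), "A2": ("root", "A", "A2"), "B": ("root", "B")}
    for p in cfg.populations:
        for b in ("A1", "A2", "B"):
            if p.branch in seg[b]:
                m = (branch == b) & (t >= p.t_lo) & (t < p.t_hi + (1e-12 if p.t_hi == 1.0 else 0))
                labels[m] = p.name
    if (labels == None).any():  # noqa: E711 — object array
        raise ValueError("populations do not tile the latent-time intervals")
    return labels


def _sample_nb(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean mu, variance mu + mu^2/theta (Gamma-Poisson)."""
    if not np.isfinite(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam)


def simulate_branching_lineage(cfg: SimConfig) -> SimOutput:
    """Draw a full two-genotype cohort along the branching lineage.

    Deterministic given ``cfg`` (including ``cfg.seed``): identical configs
    yield bit-identical outputs.
    """
    cfg.validate()
    rng_prog = child_rng(cfg.seed, 0)
    programs = _assign_gene_programs(cfg, rng_prog)
    beta, gamma = _sample_rates(cfg, rng_prog)
    rng = child_rng(cfg.seed, 1)

    grid = np.linspace(0.0, 1.0, N_GRID)
    kinetics = {}  # (genotype, path) -> (u, s) on grid
    for gt in ("wt", "mut"):
        for path, alpha in _alpha_profiles(cfg, programs, gt).items():
            kinetics[(gt, path)] = _integrate_kinetics(alpha, beta, gamma)

    stage_of_sample = {}
    obs_rows = []
    mu_s_blocks, mu_u_blocks = [], []
    fate_prob_blocks = []
    n_per = cfg.n_cells_per_sample

    sample_idx = 0
    for gt in ("wt", "mut"):
        p_branch = cfg.branch_prob_wt if gt == "wt" else cfg.branch_prob_mut
        for s_i in range(cfg.n_samples_per_genotype):
            sample = f"{gt}_{s_i + 1}"
            stage = cfg.stages[sample_idx % len(cfg.stages)] if len(cfg.stages) > 1 \
                else cfg.stages[0]
            stage_of_sample[sample] = stage
            lo, hi = cfg.stage_time_windows.get(stage, (0.0, 1.0))
            t = rng.uniform(lo, hi, n_per)

            # branch commitment
            cardiac = rng.random(n_per) < p_branch
            sub = rng.random(n_per) < cfg.subsplit_prob
            branch = np.where(cardiac, np.where(sub, "A1", "A2"), "B").astype(object)
            committed = np.where(
                t < cfg.branch_time, "root",
                np.where(~cardiac, "B",
                         np.where(t < cfg.subsplit_time, "A", np.where(sub, "A1", "A2"))),
            ).astype(object)
            labels = _population_of(cfg, branch, t)

            if cfg.population_gap > 0:
                # shrink each cell's latent time into the interior of its
                # population window, leaving inter-population gaps
                win = {p.name: (p.t_lo, p.t_hi) for p in cfg.populations}
                los = np.array([win[l][0] for l in labels])
                his = np.array([win[l][1] for l in labels])
                margin = 0.5 * cfg.population_gap * (his - los)
                t = los + margin + (t - los) * (1 - cfg.population_gap)

            # generative terminal-fate probabilities (FHF, SHF, PM)
            fp = np.zeros((n_per, 3))
            pre = t < cfg.branch_time
            fp[pre] = [p_branch * cfg.subsplit_prob, p_branch * (1 - cfg.subsplit_prob), 1 - p_branch]
            post = ~pre
            on_a_pre_split = post & cardiac & (t < cfg.subsplit_time)
            fp[on_a_pre_split] = [cfg.subsplit_prob, 1 - cfg.subsplit_prob, 0.0]
            fp[post & cardiac & (t >= cfg.subsplit_time) & sub] = [1, 0, 0]
            fp[post & cardiac & (t >= cfg.subsplit_time) & ~sub] = [0, 1, 0]
            fp[post & ~cardiac] = [0, 0, 1]

            # expected expression: interpolate grid kinetics at each cell's t
            gi = np.minimum((t * (N_GRID - 1)).astype(int), N_GRID - 2)
            frac = t * (N_GRID - 1) - gi
            mu_u = np.empty((n_per, cfg.n_genes))
            mu_s = np.empty((n_per, cfg.n_genes))
            for path in ("A1", "A2", "B"):
                m = branch == path
                if not m.any():
                    continue
                u, s = kinetics[(gt, path)]
                mu_u[m] = (u[:, gi[m]] * (1 - frac[m]) + u[:, gi[m] + 1] * frac[m]).T
                mu_s[m] = (s[:, gi[m]] * (1 - frac[m]) + s[:, gi[m] + 1] * frac[m]).T

            # cycle phase multipliers
            phase = rng.choice(np.array(["G1", "S", "G2M"]), size=n_per, p=cfg.phase_probs)
            for ph, key in (("S", "cycle_S"), ("G2M", "cycle_G2M")):
                rows = phase == ph
                mu_s[np.ix_(rows, programs[key])] *= cfg.cycle_boost
                mu_u[np.ix_(rows, programs[key])] *= cfg.cycle_boost

            # bounded per-cell background-transcription activity: off-state
            # genes share a cell-level factor (bursting / cell-state noise),
            # the dominant source of detected-gene-count variation
            bg = rng.uniform(1 - cfg.background_halfwidth,
                             1 + cfg.background_halfwidth, n_per)
            off_level = 1.5 * cfg.alpha_lo / cfg.gamma_mean
            low = mu_s < off_level
            mu_s = np.where(low, mu_s * bg[:, None], mu_s)
            mu_u = np.where(low, mu_u * bg[:, None], mu_u)

            # per-cell mitochondrial load (bounded multiplicative factor)
            mito_scale = rng.uniform(1 - cfg.mito_load_halfwidth,
                                     1 + cfg.mito_load_halfwidth, n_per)
            mu_s[:, programs["mito"]] *= mito_scale[:, None]
            mu_u[:, programs["mito"]] *= mito_scale[:, None]

            # library-size scaling: spliced totals hit depth; unspliced keep
            # their kinetic ratio to spliced
            depth = cfg.target_depth * np.exp(
                rng.uniform(-cfg.libsize_log_halfwidth,
                            cfg.libsize_log_halfwidth, n_per))
            scale = depth / mu_s.sum(axis=1)
            mu_s *= scale[:, None]
            mu_u *= scale[:, None]

            mu_s_blocks.append(mu_s)
            mu_u_blocks.append(mu_u)
            fate_prob_blocks.append(fp)
            for c in range(n_per):
                obs_rows.append((f"{sample}:C{c}", sample, gt, stage, labels[c],
                                 t[c], committed[c], phase[c]))
            sample_idx += 1

    mu_s = np.vstack(mu_s_blocks)
    mu_u = np.vstack(mu_u_blocks)
    X_s = _sample_nb(rng, mu_s, cfg.nb_dispersion)
    X_u = _sample_nb(rng, mu_u, cfg.nb_dispersion)

    import pandas as pd

    obs = pd.DataFrame(
        obs_rows,
        columns=["barcode", "sample", "genotype", "stage", "truth_label",
                 "truth_time", "truth_branch", "truth_phase"],
    ).set_index("barcode")
    obs["artifact"] = "none"

    var = _gene_metadata(cfg, programs, rng_prog)
    adata = ad.AnnData(
        X=sp.csr_matrix(X_s), obs=obs, var=var,
        layers={"spliced": sp.csr_matrix(X_s), "unspliced": sp.csr_matrix(X_u)},
    )
    adata.obsm["truth_fate_prob"] = np.vstack(fate_prob_blocks)
    adata.uns["terminal_fates"] = list(TERMINAL_FATES)

    names = var.index.to_numpy()
    truth_drivers = {
        "FHF": {"up": list(names[np.concatenate([programs["driver_A"], programs["bifunctional"]])]),
                "down": list(names[programs["antidriver_A"]])},
        "SHF": {"up": list(names[np.concatenate([programs["driver_A"], programs["bifunctional"]])]),
                "down": list(names[programs["antidriver_A"]])},
        "PM": {"up": list(names[programs["antidriver_A"]]),
               "down": list(names[programs["bifunctional"]])},
        "bifunctional": {"up": list(names[programs["bifunctional"]]), "down": []},
    }
    return SimOutput(adata=adata, truth_drivers=truth_drivers, config=cfg)


def _gene_metadata(cfg: SimConfig, programs, rng: np.random.Generator):
    import pandas as pd

    names = np.array([f"G{i:04d}" for i in range(cfg.n_genes)], dtype=object)
    for p in cfg.populations:
        for j, gi in enumerate(programs[f"marker:{p.name}"]):
            names[gi] = f"Mk{p.name}{j}"
    for key, tag in (("driver_A", "DrvA"), ("antidriver_A", "AntA"),
                     ("bifunctional", "Bif"), ("positional", "Pos"),
                     ("cycle_S", "CycS"), ("cycle_G2M", "CycG2M")):
        for j, gi in enumerate(programs[key]):
            names[gi] = f"{tag}{j}"
    for j, gi in enumerate(programs["mito"]):
        names[gi] = f"mt-G{j}"
    names[programs["regulator"][0]] = "RegX"

    gene_class = np.full(cfg.n_genes, "housekeeping", dtype=object)
    for key, g in programs.items():
        if key != "housekeeping":
            gene_class[g] = key

    # early-fading half of the root markers: pseudotime root program
    root_marker = np.zeros(cfg.n_genes, dtype=bool)
    for p in cfg.populations:
        if p.branch == "root":
            g = programs[f"marker:{p.name}"]
            root_marker[g[:(len(g) + 1) // 2]] = True

    # chromosome layout: positional cluster ordered on chr11; rest spread
    chrom = np.array([f"chr{1 + (i % 10)}" for i in range(cfg.n_genes)], dtype=object)
    tss = 10_000 + 5_000 * np.arange(cfg.n_genes)
    strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-").astype(object)
    position_index = np.full(cfg.n_genes, -1)
    for rank, gi in enumerate(programs["positional"]):
        chrom[gi] = "chr11"
        tss[gi] = 1_000_000 + 50_000 * rank
        position_index[gi] = rank

    return pd.DataFrame(
        {"gene_class": gene_class, "mito": gene_class == "mito",
         "root_marker": root_marker,
         "chromosome": chrom, "strand": strand, "tss": tss,
         "position_index": position_index},
        index=pd.Index(names, name="gene"),
    )


# ---------------------------------------------------------------------------
# QC artifacts


def inject_qc_artifacts(out: SimOutput, cfg: SimConfig | None = None) -> SimOutput:
    """Corrupt a seeded subset of cells with QC artifacts, flagging them.

    Outliers get inflated mitochondrial counts and a deflated detected-gene
    count; doublets become the elementwise sum of the cell and one random
    partner (no depth rescaling, so the doublet's total equals the sum of
    the two totals exactly).
    """
    cfg = cfg or out.config
    if cfg.outlier_fraction + cfg.doublet_fraction >= 0.5:
        raise ValueError("outlier_fraction + doublet_fraction must be < 0.5")
    n = out.n_cells
    n_out = int(round(cfg.outlier_fraction * n))
    n_dbl = int(round(cfg.doublet_fraction * n))
    if n_out + n_dbl == 0:
        return out

    rng = child_rng(cfg.seed, 2)
    adata = out.adata.copy()
    picks = rng.choice(n, size=n_out + n_dbl, replace=False)
    out_cells, dbl_cells = picks[:n_out], picks[n_out:]
    mito = adata.var["mito"].to_numpy()
    mito_idx = np.flatnonzero(mito)

    artifact = adata.obs["artifact"].to_numpy(dtype=object)
    dense = np.asarray(adata.X.todense())
    for c in out_cells:
        dense[c, mito_idx] = dense[c, mito_idx] * 8 + 5
        nonmito = np.flatnonzero(~mito & (dense[c] > 0))
        kill = rng.choice(nonmito, size=int(0.6 * len(nonmito)), replace=False)
        dense[c, kill] = 0
        artifact[c] = "outlier"
    clean = np.setdiff1d(np.arange(n), picks)
    partners = rng.choice(clean, size=n_dbl, replace=True)
    for c, j in zip(dbl_cells, partners):
        dense[c] = dense[c] + dense[j]
        artifact[c] = "doublet"

    adata.X = sp.csr_matrix(dense)
    adata.layers["spliced"] = sp.csr_matrix(dense)
    adata.obs["artifact"] = artifact
    return SimOutput(adata=adata, truth_drivers=out.truth_drivers, config=cfg)
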