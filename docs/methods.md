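# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Synthetic branching-lineage generator (`simdata`)

The generator emulates a two-genotype gastrulation study: a wild-type
("wt") and a heterozygous mutant ("mut") genotype, several embryo samples
per genotype, and a mesodermal lineage running over latent time t ∈ [0, 1].
Cells start in a bipotent progenitor pool (NMP, t < 0.4), commit at the
branch point to the cardiac branch with probability `branch_prob_wt = 0.60`
(wt) or `branch_prob_mut = 0.45` (mut), and the cardiac branch splits once
more (50/50, genotype-independent) into the two terminal heart fields, so
the terminal fates are FHF, SHF and PM. Defaults: 6 samples per genotype,
1000 cells per sample, a 200-gene panel, ~1200 transcripts per cell. The
gene panel is a scaled-down stand-in for a transcriptome: per-population
markers (8 each), cardiac drivers (15), cardiac antidrivers (15),
bifunctional branch genes (10, induced on the cardiac branch and shut down
on the paraxial branch — the constructed "branching signature"), one
persistent-regulator gene (decays along t in wt, persists in mut), a
chromosomally ordered positional cluster with staggered on/off pulses,
mitochondrial genes, S/G2M cycle programs, and neutral housekeeping decoys.

**Kinetics.** Each gene follows transcription rate α(t, branch) (piecewise
linear on a 200-point grid), splicing rate β and degradation rate γ (per
gene, lognormal around β = 20, γ = 10 per unit latent time, i.e. a
transcript half-life of ~7% of the trajectory). The unspliced moiety is
kept at its fast equilibrium u = α/β; the spliced moiety integrates
ds/dt = βu − γs exactly per grid interval with α frozen at the interval
midpoint, from the steady state at t = 0. At constant α this reproduces
the fixed point u/s = γ/β exactly, which the tests use as a closed-form
oracle. Population markers turn over 3× faster (β and γ scaled jointly, so
levels are unaffected), keeping expression inside the population window
rather than lingering into successor populations. Counts are
negative-binomial (Gamma–Poisson, dispersion θ = 10) around library-scaled
expectations.

**Measurement model.** Per-cell library size is log-uniform (±0.25),
mitochondrial load a bounded uniform factor (±0.6) on an expected mito
fraction of 5% that scales with total transcription, and off-state genes
share a bounded per-cell background-activity factor (±0.5). These bounded
spreads emulate data whose empty-droplet and debris tails were already
removed by cell calling; heavy tails re-enter only through injected QC
artifacts (outliers with inflated mito and deflated gene counts, doublets
that are exact sums of two cells). A `population_gap` option trims each
population's latent-time window when sampling, turning the continuous
trajectory into separated blobs; `well_separated_config()` bundles the
balanced, discrete-population study design used for the clustering and
label-transfer benchmarks.

**What the generator does not emulate:** ambient RNA, UMI collisions,
batch chemistry effects, genuinely novel populations absent from the
reference genotype, and transcriptome-scale gene counts. Passing tests
therefore demonstrate correctness of the algorithms and recoverability of
the configured effects — not robustness to every artifact of real data.

## QC and normalization (`qc`)

Cells are filtered per stage group when any of pct_mito (upper side only),
n_genes or n_counts (two-sided) exceeds `k_mad = 3` median absolute
deviations from the group median. When a metric's MAD is zero the IQR/1.349
substitutes; if that is zero too, any deviation from the median counts as
exceeding (otherwise near-constant inputs could never lose a cell). Known
property: on a population with genuine complexity differences (early
progenitors express fewer genes), the two-sided 3-MAD rule trims a few
percent of legitimate cells — measured ~3–4% on the generator's cohorts —
while removing 100% of injected artifacts; treat the filter as a
high-sensitivity, moderate-specificity screen.

Depth equalization thins every count with probability T_min/T per sample
(binomial thinning to the smallest sample total of the stage). Within-cell
normalization produces clipped (±√n_cells) negative-binomial Pearson
residuals with μ = (cell total × gene total)/grand total and a per-gene
method-of-moments dispersion smoothed against gene mean (lowess in log
space). This is a deliberate simplification of regularized-NB regression
with the same depth-invariance contract: proportional counts at doubled
depth keep their residual rank profile. DGEA and driver correlations run
on CP10K log1p values; PCA and clustering on the Pearson residuals.

Cell-cycle phases: S and G2M scores are mean marker expression minus a
size-matched, seeded control set drawn from expression-matched bins (25
bins; marker-only bins fall back to the expression-nearest non-markers).
Both scores ≤ 0 ⇒ G1, else the larger score wins.

## Clustering and cluster-number selection (`cluster`)

PCA runs on the variable-gene submatrix (top 2000 by binned normalized
dispersion; on a 200-gene panel this keeps all genes). Components are kept
while their explained variance exceeds median + 2·MAD of the spectrum; a
flat spectrum keeps one component with a warning. The SNN graph connects
cells whose kNN sets (k = 15, self included) have Jaccard overlap ≥ 1/15,
and Louvain (igraph `community_multilevel`) optimizes modularity at each
resolution. Each run permutes the vertex order with its own seeded stream —
the local-move pass scans vertices in order, so the permutation is the
algorithm's real source of run-to-run variability. The resolution is
bisected until every cluster count in 2..K_max is found (counts Louvain
never produces are reported; a resolution cliff falls back to the smallest
achievable count).

Selection: the clustering tree links consecutive counts by parent-origin
proportions, and every node carries the Shannon entropy of those
proportions. The consecutive-level tree is reported, but it cannot reject a
*stable* over-split: a spurious split's children still descend cleanly from
one parent (H = 0), and the instability only surfaces one level later,
diluted by averaging. K* is therefore chosen from replicate stability: the
same origin-entropy statistic computed between independently initialized
sweeps at the same level. A real population boundary reproduces exactly
(entropy 0 bits); splitting noise does not (≥ 0.13 bits in every probe
seed). K* = the largest level whose worst cross-replicate node entropy is
≤ `stability_epsilon_bits = 0.05`, a threshold set between those two
regimes. On a fully continuous trajectory (no population gaps) the rule
honestly returns small K — a continuum has no reproducible discrete
structure.

## Label projection (`project`)

Anchors are mutual k-nearest-neighbor pairs (k_anchor = 5) between the two
genotypes in a joint PCA of the per-dataset-scaled shared variable genes.
Scaling divides by each dataset's per-gene standard deviation without
per-dataset centering: the joint PCA centers the concatenated matrix, so a
query that covers only part of the reference's populations is not
artificially shifted onto the reference centroid. Anchor scores are the
Jaccard overlap of tie-complete 30-neighborhoods in the joint space
(excluding the pair's own members), rescaled to [0, 1]. Every query cell is
labeled by a score/distance-weighted vote of its nearest anchors, so
projection is exhaustive; cells without an anchor of their own are flagged.
The reverse-projection control clusters the query genotype independently,
projects the reference onto it, and compares per-population composition
deltas: concordant signs argue the composition shift is not a projection
artifact.

## Differential expression and composition (`dgea`)

Mann-Whitney U is two-sided, exact for tie-free groups of ≤ 8 cells and
tie-corrected normal otherwise; genes detected in < 10% of both groups are
excluded before testing and before the Bonferroni denominator
(Q = min(1, p·m), m recorded). Fold changes use expm1 of group mean log
expression with pseudocount 1e-9. Composition tests are two-sided Welch t
tests on per-sample proportions (absent populations contribute 0). The
driver-direction chi-square tests (n_under, n_over) against a 50/50 null
with 1 df; the 50/50 null is a documented choice — the alternative
(expression-background ratio) is not identified by the method's inputs.

## Pseudotime (`pseudotime`)

Diffusion transitions: symmetric Gaussian kernel on the symmetrized kNN
distance graph (bandwidth = median kNN distance), density-normalized
(dividing by the kernel row-sum product, removing sampling-density bias),
then row-normalized; self-transitions excluded; disconnected graphs are an
error listing components (the pipeline doubles k until connected). The
flood visits each unvisited cell with probability min(1, incoming
transition mass from visited cells); pseudotime is the mean visiting
iteration over `n_floods` (default 50–100) seeded floods, min-max
normalized. Root cells are the strongest expressers of the early root
program (the generator flags these genes in `var["root_marker"]`). The
flood's resolution is set by the graph's hop diameter, which grows with
cell density: latent-time recovery reaches Spearman ≈ 0.96–0.98 on
3000–12000-cell cohorts but degrades near ~0.5 below ~1500 cells; the
validation studies use 3000 cells.

## Velocity fate mapping (`velocity`)

The steady-state velocity model was chosen over likelihood-based kinetic
models because it is closed-form and oracle-checkable: counts are
kNN-smoothed (k = 30), γ̂ is fitted through the origin on the top/bottom 5%
of smoothed s, and v = u − γ̂s. The velocity kernel scores each kNN edge by
the cosine between v_i and the expression-space displacement, with row
probabilities ∝ exp(cos/0.2); zero-velocity cells get uniform rows. The
*fate kernel* mixes this directed kernel with the diffusion kernel at
`velocity_weight = 0.15`. The weight calibrates a real bias trade-off
measured on the generator's ground truth: a purely directed kernel shows
winner-take-all amplification (walks trapped in the progenitor pool exit
preferentially through the denser branch, inflating a generative 25%
relative fate reduction to ~70%), while a purely diffusive kernel shrinks
both genotypes toward balance. At 0.15 the mean progenitor absorption
probabilities track the generative branch probabilities (0.60/0.45
recovered as ≈ 0.59/0.46 over 20 seeds). Fate maps are computed per
genotype — the branch bias lives in each genotype's own cell density, and
walks must not cross genotypes. Terminal states are declared explicitly:
the strongest scorers of each terminal fate's marker program among
late-pseudotime cells, equal counts per fate.

Absorption probabilities use a sparse LU solve of (I − Q)B = R with
reachability checked first; the seeded random-walk estimator ("fraction of
walks ending in each fate") is retained as an independent oracle and agrees
with the solve within binomial error. Driver tables use Spearman
correlation (rank-based, hence invariant to monotone transforms of
expression) between expression and a fate's absorption probability,
computed on wild-type cells of that fate's own lineage subset (off-lineage
populations excluded — otherwise every cardiac-specific gene is trivially
also a paraxial antidriver and the branching signature loses its meaning).
Classification uses the ±0.25 rule.

## Concordance and enrichment (`concordance`)

Coordinates are bit-exact by convention: peaks are BED half-open 0-based;
the TSS is `start` on the + strand and `end − 1` on the − strand; a gene
has a promoter site when a peak intersects the closed ±250 nt window.
Overlap tests are one-sided (enrichment direction): binomial with success
probability equal to the external DEG density in the shared universe;
Fisher exact as the hypergeometric upper tail. ORA uses Bonferroni (as in
the enrichment workflow it mirrors); ranked GSEA uses the weighted KS
running sum (weight exponent 1) with a seeded gene-label permutation null,
sign-conditional p-values and Benjamini-Hochberg control. GSEA is
implemented in-package because the permutation scheme (set-membership
redistribution over genes) is part of the contract.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` executes simulate → QC → cluster → project → DGEA /
composition → pseudotime → fate → concordance from one `PipelineConfig`;
every stage's seed derives from the global seed, outputs are TSV/MTX/JSON,
and a manifest records SHA-256 hashes per output (the caching and the
determinism guarantee are hash-based, not timestamp-based). The demo
config uses 3 samples × 500 cells per genotype with a moderate population
gap (0.15) so that all stages, including cluster-number selection, have
signal at demo scale; the concordance stage runs on synthetic external
test doubles (an attenuated, noisy copy of the genotype DGEA and peaks
enriched at DEG TSSs), clearly labeled as such. Validation studies at
cohort scale live in `gastrufate.studies` and are what
`scripts/acceptance.py` and `tests/test_acceptance.py` run; their problem
sizes (300-cell oracle graphs, 20 × 12000-cell fate-bias cohorts,
3000-cell pseudotime cohorts, 200 × 2000-gene null replicates) were chosen
to give each estimate a comfortable margin of error on a single CPU.

## Known limitations

- Cell-level Mann-Whitney DGEA treats cells as independent replicates;
  sample-level pseudobulk inference is out of scope by design.
- The 3-MAD QC filter trims a few percent of legitimate low-complexity
  cells (see above).
- The steady-state velocity model assumes genes near their expression
  extremes are at steady state; strongly bursty or oscillatory genes
  violate this.
- The stability-entropy K* rule returns small K on continuous manifolds —
  correct behavior, but it means "number of clusters" is not meaningful on
  ungapped trajectories.
- Anchor-based projection assumes the query's populations are a subset of
  the reference's; novel query populations inherit the nearest reference
  label.
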