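# Pipeline output schema

All tables are TSV with header rows; matrices are MatrixMarket coordinate
integer triplets; proportions and probabilities are unitless fractions in
[0, 1] unless a column name says `percent`.

## simulate/
- `counts/` — 10x-style triplet: `matrix.mtx` (genes × cells, integer
  counts), `barcodes.tsv`, `features.tsv`, plus `spliced.mtx` /
  `unspliced.mtx` layers of the same shape.
- `truth_cells.tsv` — per barcode: `sample`, `genotype` (wt/mut), `stage`,
  `truth_label` (population), `truth_time` (latent time in [0, 1]),
  `truth_branch` (root/A/A1/A2/B), `truth_phase` (G1/S/G2M), `artifact`
  (none/outlier/doublet).
- `truth_genes.tsv` — per gene: `gene_class`, `mito` (bool), `root_marker`
  (bool), `chromosome`, `strand`, `tss` (0-based bp), `position_index`
  (rank within the positional cluster, −1 otherwise).
- `truth_fate_prob.tsv` — per barcode: generative probability of each
  terminal fate (columns FHF, SHF, PM; rows sum to 1).

## qc/
- `qc_report.tsv` — per stage group × metric: `median`, `scale` (MAD or
  fallback), `lower`/`upper` bounds, `n_removed`.
- `kept_barcodes.tsv` — barcodes passing the filter.

## cluster/
- `labelings.tsv` — per barcode: one column `k{K}` per swept cluster count
  (integer labels), `chosen` (labels at K*), `population` (marker-program
  annotation).
- `tree_edges.tsv` — `parent_level`, `parent`, `child_level`, `child`,
  `proportion` (fraction of the child's cells from that parent; sums to 1
  per child).
- `entropy_curve.tsv` — entropy (bits) per level of the curve used for
  selection.
- `k_star.txt` — the selected cluster count.

## project/
- `anchors.tsv` — `ref`, `query` (cell indices), `score` in [0, 1].
- `transferred_labels.tsv` — per mutant barcode: `label`, `score`
  (winning vote share), `direct_anchor` (bool).
- `forward_reverse_deltas.tsv` — per population: `delta_forward`,
  `delta_reverse` (mut − wt proportion deltas), `sign_agree`.

## dgea/
- `dgea_mut_vs_wt.tsv` — per tested gene: `mean_a`/`mean_b` (mut/wt mean
  log-normalized expression), `fold_change`, `U`, `p`, `Q` (Bonferroni),
  `direction` (up = higher in mutant).
- `composition_proportions.tsv` — per sample: proportion per population
  plus `genotype`.
- `composition_tests.tsv` — per population: genotype means ± SEM, Welch
  `t`, two-sided `p`.

## pseudotime/
- `pseudotime.tsv` — per barcode: pseudotime in [0, 1].
- `ks_genotype.tsv` — per group (all + shared populations): KS `D`, `p`,
  group sizes.

## fate/
- `fate_probabilities_{wt,mut}.tsv` — per barcode: absorption probability
  per terminal fate (rows sum to 1).
- `drivers_{fate}.tsv` — per gene: Spearman `rho` vs the fate's absorption
  probability, `class` (driver/antidriver/neither at ±0.25), `constant`.
- `fate_bias.json` — `cardiac_prob_wt`, `cardiac_prob_mut` (mean FHF+SHF
  probability among progenitors), `relative_reduction`.
- `branching_signature.json` — signature gene list and Venn counts.
- `driver_chisq.json` — `n_under`, `n_over`, `expected`, `statistic`, `p`.

## concordance/
- `deg_overlap.tsv` — per direction: DEG counts, `percent` overlap,
  `p_null` (expected density), one-sided `binomial_p`.
- `fc_regression.json` — OLS `slope`, `intercept`, `r`, `p`, `n`.
- `site_enrichment.json` — 2×2 `table`, sample `odds_ratio`, one-sided
  Fisher `p`.
- `ora.tsv` — per gene set: `n_set`, `n_overlap`, `expected`,
  `odds_ratio`, `p`, `Q` (Bonferroni), `score` (log2 obs/exp).
- `gsea.tsv` — per gene set: `size`, `ES`, `NES`, permutation `p`, `Q`
  (Benjamini-Hochberg).

## Run metadata
- `config.yaml` — the full pipeline configuration.
- `manifest.json` — per stage: SHA-256 hash per output file and wall-clock
  seconds; identical configs reproduce identical hashes.
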