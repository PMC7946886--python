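# Methods

## Pipeline model and assumptions

`radhub` analyses a collection of independent expression datasets (genes ×
samples, log2 scale, with per-sample condition/arm/dose/time metadata) under
the weighted gene-coexpression framework:

- **Unsigned network.** Adjacency is a_ij = |r_ij|^β with r the Pearson
  correlation across all samples of a dataset and integer β ≥ 1. The
  unsigned convention treats strongly anti-correlated genes as connected;
  it is appropriate when modules contain genes loading on a common factor
  with either sign, which is exactly the generative assumption below.
- **Scale-free criterion.** β is the smallest integer in 1..20 whose
  weighted degree distribution fits a power law: connectivities are split
  into 10 equal-width bins, log10 bin frequency is regressed on log10 bin
  mean connectivity over non-empty bins, and the fit score is
  −sign(slope)·R². The chosen β is the smallest with score ≥ 0.80; when no
  β qualifies, the argmax is recorded as an explicit fallback rather than
  silently promoted. Degenerate degree distributions (all connectivities
  equal, or fewer than three usable bins) raise a distinct error: they are
  not a "low R²" but an undefined fit.
- **Topological overlap and modules.** Genes are clustered by
  average-linkage hierarchical clustering on 1 − TOM. TOM augments direct
  adjacency with shared-neighbour weight, which stabilizes clustering in
  noisy networks.
- **Eigengene.** A module's eigengene is the first right singular vector of
  its per-gene standardized submatrix, scaled to unit variance, signed to
  correlate positively with the module's mean standardized profile (this
  sign rule makes repeated computation identical).
- **Hubness.** Intramodular connectivity k_within sums adjacency to
  same-module genes; unassigned genes have k_within = 0 by convention. Hub
  selection ranks module-assigned genes globally (no per-module quota) and
  keeps the top fraction (default 0.20), including all genes tied with the
  boundary value so selection cannot depend on input order.
- **Differential expression.** The decision rule is fold change only:
  log2FC = mean(irradiated) − mean(control), calls at |log2FC| ≥ 1
  (boundary inclusive, fixed for determinism). Welch t p-values are carried
  as a descriptive annotation and never gate anything. Consistency across
  conditions uses min_sig = ⌈0.25 × n_conditions⌉ (with 32 conditions,
  exactly 8) and a strict majority; an exact up/down tie is `inconsistent`
  and excluded from candidates.
- **Candidates.** The candidate table is the three-way intersection
  (consensus hub ∧ in catalog ∧ directionally consistent), ordered by
  (−hub_count, −total calls, gene id). The proposed modulation column is
  left `unassigned`: deciding whether to inhibit or activate a target is a
  curation step outside the computational scope, and the schema reserves
  the column so curated results can be merged.
- **Enrichment.** One-sided hypergeometric over-representation with BH
  adjustment across all tested terms; `enriched` means q < 0.05. The
  default universe is the set of genes surviving CV filtering in the
  network under test. Terms smaller than 3 genes after universe restriction
  are dropped (unstable folds). Cross-network summaries average fold
  enrichment over the networks in which a term is *enriched*, and only for
  terms enriched in at least two networks; a term enriched once raises an
  explicit signal rather than being silently dropped.

### Order of operations

Datasets are quantile normalized first, then contrasts are computed on the
normalized full matrix, then the CV filter reduces genes for network
construction only. Normalizing before filtering follows the natural reading
of the workflow; running DE on the unfiltered matrix keeps the contrast
universe shared across datasets, which the consistency summary requires.

## Numerical choices

- **Quantile normalization ties.** Tied values within a column receive the
  mean of the reference (rank-mean) values over their tied ranks. This is
  deterministic, but not exactly idempotent in the presence of ties: the
  tie-averaging perturbs column multisets, so a second application can
  shift other columns slightly. On tie-free (continuous) data the map is
  idempotent and all column sorted vectors agree to 1e-12, which is what
  the tests assert; tie handling is asserted against hand-computed values.
- **CV filtering scale.** The coefficient of variation is computed on the
  unlogged (2^x) scale by default. For log-normal expression the CV is then
  a monotone function of the log-scale standard deviation and invariant to
  multiplicative rescaling; computing CV directly on log2 values would not
  be scale-invariant. Sample (ddof = 1) standard deviations are used.
- **Dendrogram cut.** The TOM scale shifts by orders of magnitude with β,
  so no fixed cut height works across the β grid (at β ≥ 6 within-module
  merges happen above dissimilarity 0.998; at β = 3 between-module merges
  can happen below 0.994). `detect_modules` therefore defaults to a
  data-driven static cut: every midpoint between consecutive distinct merge
  heights is a candidate, and the cut maximizing Newman weighted modularity
  of the flat clusters on the TOM graph is retained. Each resulting cluster
  is then re-clustered on its own sub-dendrogram and split when the split
  increases global modularity — handling the one configuration a single
  height cannot (a fused pair of modules whose internal join sits below
  other modules' roots). The procedure is deterministic; an absolute cut
  height in (0, 1] can still be passed explicitly. Clusters below
  min_module_size (default 30) are unassigned; surviving modules are
  relabeled 1..M by decreasing size with ties broken by smallest member
  gene id.
- **Hierarchical clustering backend.** scipy's average linkage; with
  continuous similarities merge heights are almost surely distinct, making
  the partition invariant to gene input order (asserted under permutation).
- **BH adjustment** is delegated to statsmodels (`fdr_bh`) behind the
  package's `bh_fdr` surface and verified against hand-computed step-up
  values; inputs outside (0, 1] are rejected.
- **Determinism.** All randomness flows from numpy `SeedSequence`s. The
  pipeline derives per-stage child seeds from the single run seed with a
  fixed scheme (`SeedSequence([seed, salt])`, reduced below 2^31), so a
  config plus seed reproduces every output byte for byte.

## The synthetic study generator

The generator emulates the structure of a multi-cohort irradiation study at
desk scale; its defaults are the package's reference study conditions:

| parameter | default | role |
| --- | --- | --- |
| n_genes | 1000 | shared gene universe (scaled down ~15x from a typical array) |
| module_sizes | 5 × 100 | planted coexpression modules; 500 background genes |
| samples_per_dataset | 48, 28, 169, 70, 60 | the per-cohort sample counts of the emulated design |
| conditions_per_dataset | 4, 2, 14, 6, 6 | 32 irradiated-vs-control conditions in total, ≥ 4 samples per arm |
| hub_fraction_per_module | 0.12 | planted hubs (60 genes), shared across datasets |
| loading_range_hub / nonhub | 0.80–0.95 / 0.40–0.60 | |u| intervals; hub loadings strictly above non-hub |
| noise_sd | 1.0 | residual scale relative to the factor part |
| de_effect_log2 | 1.5 | planted arm shift, clearing the 2-fold rule with margin |
| frac_de | 0.08 | planted responsive genes (80), weighted toward hubs (×6) and high-amplitude genes (×c²) |
| frac_druggable | 0.30 | genes with ≥ 1 catalog drug |

Per dataset d and module m the eigengene is
e_m = standardize(f_m(dose, time) + z), z ~ N(0, 1) per sample, where f_m is
a saturating monotone dose effect (dose/(dose + h)) damped by an exponential
time decay, with module-specific amplitude (|f| ≲ 0.3), sign, half-dose and
decay constant. A module gene is

x_g = μ_g + c_g · ( s_g u_g e_m + noise_sd · sqrt(1 − u_g²) · ε ),

so at noise_sd = 1 the loading u_g *is* the gene–eigengene correlation —
the quantity module detection and hub ranking estimate. The per-gene
amplitude c_g (log-uniform; module genes 0.75–1.15, background 0.40–1.30)
models biological variability on the log2 scale: it is invisible to
correlations but drives the CV filter, so filtering enriches for module
genes while retaining a realistic share (~1/3) of high-variance background —
which also gives the degree distribution the low-connectivity mass a
scale-free fit needs. Planted DE adds ±de_effect_log2 to the irradiated
samples of 12–18 of the 32 conditions per responsive gene, with a small
opposite-direction minority so the strict-majority rule is exercised; the
stored per-gene truth direction is *derived* from the planted calls by the
same majority rule the pipeline uses. Module membership, hub status,
druggability, amplitudes and DE planting are shared across datasets;
loadings and signs are re-drawn per dataset.

### What the generator does and does not emulate

It reproduces the features the pipeline's logic depends on: multi-cohort
module structure with shared hubs, dose/time-linked eigengenes,
irradiated-vs-control contrasts at realistic arm sizes, rare directional DE
concentrated in the responsive modules, and a druggable subset. It does
**not** simulate probe-level microarray artifacts, platform/species
probe-to-gene mapping, batch effects, missing values, or correlated
drug–disease annotations. Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical behaviour under the stated factor
model, not performance on raw public cohort data, where probe mapping and
cross-species harmonization dominate the error budget.

Two interactions discovered during design are worth recording. First,
planted mean-shift DE is variance orthogonal to the module factor, so a
heavily responsive gene is *by construction* a slightly worse module member
(its correlation to the eigengene is diluted by the shift variance);
weighting DE propensity by amplitude bounds this dilution so planted hubs
stay above the non-hub connectivity band. Second, because the module
recovery conditions (one 60-sample dataset) can only host 32-condition DE
by concentrating planted shifts into ~6 conditions — far denser than the
5-dataset design — module-recovery evaluations disable DE planting to
measure the coexpression axis in isolation.

## Problem sizes and runtime

Defaults are sized for a laptop: 1000 genes (500 after CV filtering) per
network, five networks, β grid 1..20. The full pipeline runs in a few
seconds; the complete test suite (including brute-force oracles for TOM,
intramodular connectivity and the hypergeometric tail over all N ≤ 30) in
about half a minute.

## Known limitations

- Global hub ranking by k_within favours denser modules; a per-module quota
  would behave differently. The global rule is the implemented and tested
  convention, with unassigned genes excluded from ranking.
- The fold-change-only DE rule has no variance moderation; on small arms it
  is noisy, which is faithful to the implemented decision rule but means
  per-gene calls should not be over-interpreted.
- Consensus is at the hub-set level; no consensus-TOM or module-preservation
  statistics across datasets.
- A shared gene-id universe is assumed; cross-species ortholog mapping is a
  pass-through join left to the caller.
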