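# radhub

Consensus weighted gene-coexpression hub mining and drug-target
prioritization for radiation-response transcriptomics.

## The problem

Acute radiation syndrome (ARS) — whole-body exposure above ~0.7 Gy — has few
approved treatments, and human data are scarce. One systems-level route to
candidate therapies is to look for genes that sit at the center of the
transcriptional response to irradiation *reproducibly across independent
cohorts*, and that are already targets of existing drugs. `radhub`
implements that analysis as a tested, reusable Python library:

1. **Per-dataset network construction.** Each expression dataset (genes ×
   samples, log2 scale) is quantile normalized and filtered by coefficient
   of variation. Pairwise Pearson correlations are raised to a
   soft-threshold power β — the smallest integer for which the weighted
   degree distribution fits scale-free topology with signed R² ≥ 0.80 —
   giving the unsigned adjacency a_ij = |r_ij|^β. Genes are clustered by
   average-linkage hierarchical clustering on 1 − TOM, where
   TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
   is the topological overlap; each module is summarized by its eigengene
   (first principal component).
2. **Hub genes.** Within a network, hubs are the top 20% of module-assigned
   genes by intramodular connectivity k_within = Σ_{j in same module} a_ij.
3. **Consensus.** A consensus hub is a hub in at least two of the
   independently built networks; the overlap-degree histogram across
   candidate fractions (5%, 10%, 20%) justifies the 20% cut.
4. **Differential-expression consistency.** Every irradiated-vs-control
   condition yields per-gene log2 fold changes; |log2FC| ≥ 1 is a call. A
   gene is directionally consistent when it is called in at least
   ⌈0.25 × n_conditions⌉ conditions with a strict majority in one direction.
5. **Target integration.** Candidates = consensus hubs ∩ drug-target
   catalog ∩ directionally consistent genes.
6. **Enrichment.** Gene sets are scored against GMT annotations with the
   one-sided hypergeometric test, BH-adjusted (FDR < 0.05), with average
   fold enrichment summarized across networks.

Because the original cohort data live in public repositories and are not
redistributed here, the package ships a **synthetic-data generator** that
emulates the study design — five datasets of 28–169 samples over a shared
gene universe, 32 irradiated-vs-control conditions with dose (Gy) and time
metadata, planted coexpression modules with hub genes shared across
datasets, planted differential expression, and a drug-target catalog — so
every stage of the pipeline can be validated against known ground truth.

## Worked example

`examples/prioritize_targets.py` runs the whole chain on the default
synthetic study (seed 1) and prints:

```
consensus hubs: 95
druggable consensus hubs: 24
candidates (also directionally consistent): 5

         hub_count      member_networks direction  n_up  n_down                                         drugs proposed_modulation
gene_id
G0240            5  DS1,DS2,DS3,DS4,DS5        up    11       3                            CMPD0259(approved)          unassigned
G0343            5  DS1,DS2,DS3,DS4,DS5      down     0      11                            CMPD0027(launched)          unassigned
G0061            4      DS1,DS3,DS4,DS5      down     4       7                            CMPD0047(launched)          unassigned
G0132            3          DS1,DS3,DS4      down     0      11  CMPD0117(launched);CMPD0204(investigational)          unassigned
G0284            2              DS3,DS4      down     2      11         CMPD0048(launched);CMPD0210(launched)          unassigned

vs planted truth (hub AND druggable AND consistent): precision 1.00, recall 1.00 (5/5 planted targets found)
```

Reading the table: `G0240` is a hub in all five networks (`hub_count` 5),
is upregulated ≥ 2-fold in 11 of 32 conditions versus 3 downregulated
(a strict up majority), and is targeted by one approved compound —
exactly the profile the method is built to surface. The final line scores
the table against the planted truth: all five planted druggable
consistently-regulated hubs were recovered, with no false positives.

The other scripts in `examples/` each demonstrate one capability
(simulation, single-network construction, hub consensus, differential
expression, enrichment). A thin CLI mirrors the stages:

```bash
radhub simulate --seed 1 --outdir study/
radhub run-all --config pipeline.yaml --outdir results/
```

with subcommands `preprocess`, `network`, `hubs`, `consensus`, `de`,
`integrate`, `enrich` for stage-wise runs on TSV files.

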