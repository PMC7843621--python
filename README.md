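# lincnet

Circulating lncRNA–mRNA co-expression network analysis for plasma
microarray profiling studies.

Long non-coding RNAs detectable in plasma are candidate minimally-invasive
biomarkers for conditions that lack diagnostic markers, such as diabetic
cardiomyopathy in type 2 diabetes. The standard discovery workflow profiles
circulating lncRNAs and mRNAs in cases vs controls at several disease
stages, calls deregulated transcripts, and looks for "core" lncRNAs: the
handful whose expression is most densely correlated with deregulated
mRNAs, and whose partner genes enrich for disease-relevant biology.
`lincnet` implements that workflow as a tested, reusable Python library
for bioinformaticians analysing two-condition, multi-timepoint expression
studies:

- **Differential expression** — fold change (linear-scale group-mean
  ratio), two-sided Mann–Whitney U (exact for small tie-free groups,
  tie-corrected normal approximation otherwise) or Welch's *t*,
  Benjamini–Hochberg adjustment, and inclusive thresholding:
  deregulated ⇔ FC ≥ 2 (or ≤ 1/2) ∧ p ≤ 0.05. Cross-timepoint overlap,
  volcano tables and average-linkage clustering on 1 − Pearson distance.
- **Positional annotation** — each lncRNA is assigned one of six classes
  relative to the coding genes (exon sense overlapping, intron sense
  overlapping, intronic antisense, natural antisense, bidirectional,
  intergenic; most-specific overlap wins), plus per-chromosome up/down
  counts and shares of the deregulated totals.
- **Co-expression network** — all deregulated lncRNA × mRNA Pearson pairs
  over the pooled samples of a timepoint; edges kept under the strict
  rule |r| > 0.995 ∧ p < 0.05 (*t*-transform test,
  t = r·√((n−2)/(1−r²))). Hub lncRNAs are ranked by degree; the top-k
  sub-network exports to SIF/GraphML for Cytoscape.
- **Enrichment with kappa grouping** — one-sided hypergeometric tests of
  the hub-partner mRNA set against GO (BP/CC/MF) and pathway catalogs, BH
  within each namespace, then Cohen's kappa of term gene-membership
  vectors (κ > 0.03) links redundant terms into functional groups.
- **Synthetic-data generator** — a seeded simulator with planted ground
  truth (deregulated transcripts, hub correlation blocks driven by latent
  factors, enriched terms) emulating the study design of a mouse plasma
  array experiment, so every stage is testable without any download.

## Worked example

```python
import lincnet as ln

config = ln.SimulationConfig(
    n_lnc=400, n_mrna=1200,
    n_de_lnc={"6wk": (20, 14), "20wk": (60, 45)},
    n_de_mrna={"6wk": (15, 12), "20wk": (70, 50)},
    n_shared_de_lnc=(8, 5), n_hubs=4, hub_block_size=12,
    n_go_terms=30, n_pathway_terms=15, term_size_range=(8, 60), seed=42)
catalog, study, truth, gene_sets = ln.simulate_study(config)

de = ln.run_de(study, "20wk", test="mann_whitney", fc_min=2.0, p_max=0.05)
print(de.counts("lncRNA"))          # (60, 45, 105)

net = ln.build_network(de.deregulated_ids("lncRNA"),
                       de.deregulated_ids("mRNA"), study, timepoint="20wk")
hubs = ln.rank_hubs(net, k=4)
print(hubs.hubs)
# ['LNC000156', 'LNC000310', 'LNC000371', 'LNC000383']  — degree 12 each
```

The DE counts are the planted (60 up, 45 down) deregulated lncRNAs,
recovered exactly at this noise level, and the four top-degree lncRNAs
are precisely the planted hubs — each is connected to its full 12-mRNA
correlation block. The scripts in `examples/` walk through each
capability (simulation, DE + overlap, positional classes and chromosome
shares, hub networks, kappa-grouped enrichment, and the end-to-end
pipeline) and print what every number means; `lincnet --help` exposes the
same stages as a command-line tool for batch runs.

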