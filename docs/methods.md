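# Methods

This note documents the models, statistics and design choices behind
`lincnet`, in the order the pipeline runs them.

## Study design and the synthetic generator

The package targets two-condition (control vs diabetic), two-timepoint
plasma microarray studies in mouse. The simulator's defaults mirror that
design: 24,881 mRNA transcripts and 30,000 lncRNA probes (the mRNA count
is the profiled array's; lncRNA probe counts vary by array release, and
30,000 is a realistic scale, not a reported value), 12 samples per group,
timepoints labelled 6wk (diabetes without cardiomyopathy) and 20wk
(cardiomyopathy), and planted deregulated counts per timepoint equal to
the study-style up/down totals (92/60 and 1495/1860 lncRNAs, 62/65 and
1052/1528 mRNAs). 33 lncRNAs are planted as deregulated at both
timepoints, 19 up and 14 down at 20wk.

**Intensities.** Simulated directly on the log2 scale (microarray
convention; linear values are 2^x, and fold-change semantics stay exact).
Per-transcript baselines are Normal(`baseline_log2_mean` = 8,
`transcript_mean_sd` = 1.5); per-sample noise is
Normal(0, `baseline_log2_sd` = 0.25). A deregulated transcript shifts its
diabetic group mean by ±log2(fc) with fc ~ Uniform(`planted_fc_range` =
[2.5, 6.0]); the lower bound is validated to sit at or above the
downstream fold-change threshold of 2, so planted effects are always
callable in expectation.

**Hubs.** Five hub lncRNAs (up-regulated at the cardiomyopathy timepoint)
each drive a block of 104 up-regulated mRNAs — 5 × 104 = 520 distinct
partners, the scale of a top-5 hub sub-network. At that timepoint, hub
and block replace their sample noise with a shared latent factor
z = `hub_latent_sd`·u + Δ·1[diabetic] (u standard normal, Δ the hub's
planted log2 fold change) plus residual Normal(0, `hub_noise_sd` = 0.02).
Block members load on z with λ = log2(fc_member)/Δ, so each member keeps
its own planted fold change while pairwise Pearson correlations tend to
±1 as the residual vanishes; at `hub_noise_sd` = 0 they are exactly ±1.
Member correlation signs default to positive.

**Annotation.** Coordinates are 0-based half-open (BED convention)
throughout. Chromosomes are the mouse-style 1–19 + X. Coding genes are
laid down round-robin across chromosomes with a fixed three-exon
structure and 40 kb spacing; each lncRNA is constructed relative to a
host gene so its positional class is known by construction, with the
expected label stored for classifier tests. Class proportions default to
an intergenic-dominant mix (40% intergenic, 32% exon sense overlapping,
11% intronic antisense, 7% natural antisense, 5% each bidirectional and
intron sense overlapping) resembling vendor annotations of plasma
lncRNAs. A configurable share (default 10%) of planted deregulated
lncRNAs is drawn from chromosome 2, so chromosomal summaries
qualitatively show the chromosome-2 dominance seen in diabetic models;
the share is a parameter, not a claim about biology.

**Gene sets.** Random terms in the three GO namespaces plus a pathway
namespace, sizes uniform in [10, 200] over the mRNA universe. One term
per namespace is planted over each hub block; at `term_overlap_frac` =
1.0 the planted term *is* the block.

**What the generator does not model:** probe GC bias, scanner
saturation, batch effects, within-array correlation of background
transcripts, or realistic GO term-size/DAG structure. Passing tests
therefore demonstrate that the statistics recover what they define —
planted effects under Gaussian noise — not performance on real array
data.

## Differential expression

Fold change is the ratio of arithmetic group means on the linear scale
(vendor convention; a geometric-mean alternative is a flag). The default
test is the two-sided Mann–Whitney U; Welch's *t* is selectable because
both appear in array practice, and the choice is surfaced rather than
resolved silently. The exact U distribution is used when both groups have
≤ 8 samples and no ties; otherwise the tie-corrected normal approximation
**without** continuity correction — at n = 12/group the uncorrected
approximation's null rejection rate at p ≤ 0.05 (≈ 0.052) tracks the
exact test (0.0495), while the continuity-corrected version is
noticeably conservative (≈ 0.042). Transcripts constant across both
groups get p = 1 and a degenerate flag; zero control means flag the
ratio infinite and exclude the transcript from calling with a logged
warning.

Calling is inclusive exactly as the thresholds are usually printed:
up ⇔ FC ≥ 2 ∧ p ≤ 0.05, down ⇔ FC ≤ 0.5 ∧ p ≤ 0.05. The p column
defaults to raw p (the printed rule); calling on BH-adjusted p at the
same cut-off is a flag, and both counts can always be reported.
BH adjustment delegates to statsmodels' step-up implementation and is
tested against a brute-force implementation of the definition.

Quantile normalisation maps every sample onto the row-mean reference
distribution via average (tie-aware) ranks; it preserves within-sample
rank order and is idempotent on tie-free data. Missing values above a
configurable fraction (default 0) are an error; below it they are filled
with row means and logged. Note that with few transcripts (hundreds) the
empirical quantile map is coarse enough to perturb near-unit
correlations, which matters under the strict |r| > 0.995 edge rule —
at study scale (tens of thousands of transcripts) the effect is
negligible. Synthetic studies are generated on a common scale, so
pipeline runs on simulated data may disable the stage.

Hierarchical clustering of deregulated transcripts uses average linkage
on 1 − Pearson correlation of row-standardised log2 values; zero-variance
rows sit at the maximal distance 2 and are logged; ties break by input
order (scipy's merge-index rule).

Reported percentages round half away from zero to one decimal
(13/92 → 14.1%).

## Co-expression network and hubs

Correlations are computed across the pooled samples of the timepoint
(both groups) on normalised log2 intensities; restricting to one group is
a flag, and n is recorded per edge. The network keeps an edge only under
the strict inequalities |r| > `r_threshold` (default 0.995) and
p < `p_threshold` (default 0.05) — deliberately strict, in contrast to
the inclusive DE thresholds. The p-value is the classical *t*-transform
test of the Pearson coefficient (no test is canonical here; this is the
textbook choice). Where the same analysis is quoted with p < 0.005, the
threshold is the single configurable `p_threshold`.

Hubs are lncRNA nodes with degree ≥ 1 ranked by degree descending, ties
broken lexicographically by transcript id; a tie crossing the k-th rank
is flagged, and fewer than k connected lncRNAs returns all of them with a
shortfall flag. Exports: edge TSV, SIF (interaction types `pos`/`neg`)
and GraphML carrying r, p, degree and regulation attributes; TSV and
GraphML round-trip through the package's own readers.

## Enrichment and kappa grouping

Enrichment is the one-sided hypergeometric upper tail
P(X ≥ overlap) — the Fisher-exact default of GO tools — conditioned on a
background of genes both measured in the study and present in the
catalog. BH runs within each namespace (BP/CC/MF/pathway) separately
because results are reported per category; consequently the
no-false-positive guarantee under null queries holds per namespace
family, not jointly across all four (with four families the chance of at
least one null rejection somewhere approaches 1 − 0.95⁴ ≈ 19%).

Cohen's kappa compares two terms' binary gene-membership vectors over the
background: κ = (P_o − P_e)/(1 − P_e) from the 2×2 co-membership table,
defined as 1 for identical sets. Significant terms are grouped by
connected components of the κ > 0.03 graph — the printed threshold, kept
even though clustering tools commonly default to 0.4, with the flag
prominent. Components are simpler and order-independent compared with
iterative merge heuristics; the difference is that components chain
(a~b, b~c puts a and c together even if κ(a,c) is low). Each group is led
by its smallest-raw-p term (tie → larger term, then lexicographic), and
groups are ordered by leading significance.

## Pipeline and reproducibility

`run_pipeline` chains the stages under one `RunConfig` (JSON, round-trip
lossless; TOML accepted read-only) with per-stage toggles. All randomness
flows from one integer seed through named substreams, so identical
config + seed reproduces the machine-readable report byte for byte; the
report embeds the package version and a hash of the scientific
configuration (output paths excluded). Any stage failure aborts with the
stage name. `verify_report` scores a simulated run against its planted
truth: DE sensitivity and false-discovery proportion per timepoint and
biotype, hub recovery, planted-term recovery, and an instability flag for
near-empty hub networks.

## Problem sizes

The default simulation is study-scale (≈ 55k transcripts × 48 samples)
and runs the full pipeline in well under a minute on one core; the test
suite and the replicate suites in `scripts/acceptance.py` use scaled-down
studies (tens to thousands of transcripts, 50 seeded replicates for
recovery rates, 10 for null calibration) chosen so each check still has
the statistical resolution its tolerance needs.

## Known limitations

- The positional classifier's precedence order (sense-exonic >
  sense-intronic > antisense-intronic > antisense-exonic (natural
  antisense) > bidirectional > intergenic) and the 1 kb bidirectional
  window follow common vendor practice; other annotation pipelines'
  unpublished rules will differ on edge cases, so exact reproduction of
  any particular vendor's class percentages is out of scope.
- A same-strand transcript that overlaps a gene without touching an exon
  and without fitting inside one intron (e.g. running out of the gene's
  tail intron) matches none of the five specific classes and falls to
  intergenic by the precedence rules.
- GO DAG propagation, probe-to-gene collapsing, batch correction and
  moderated-variance tests are out of scope.
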