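# Methods

This note documents the statistical procedures, parameter choices and
numerical conventions behind `aqnet`, and what the synthetic benchmarks
do and do not demonstrate.

## Co-expression and mutual rank

The substrate is a nonnegative gene-by-sample abundance matrix on the
RPKM scale.  Processing order is fixed and enforced by the pipeline:
biological replicates are averaged per condition **on the raw scale**,
values are then transformed as log2(v + 1), and Pearson correlations are
computed across conditions.  The log base and pseudocount are the
package's choice (standard for RPKM data; the pseudocount preserves
zeros).  Genes with zero variance across conditions have undefined
correlation and are excluded from ranking, with a warning.

For genes a and b, rank_a(b) is the 1-based position of b when all genes
other than a are sorted by descending PCC with a; mutual rank is
MR(a,b) = sqrt(rank_a(b)·rank_b(a)).  Ranks are ordinal with ties broken
by lexicographic gene id — average ranks would make MR depend on
floating-point tie detection and spoil reproducibility.  MR is symmetric,
≥ 1, and 1 exactly for reciprocal best partners.  The guide neighborhood
takes the k genes of smallest MR (default k = 300), ascending, ties again
by gene id.  Only rank vectors touching the guide are needed, so the
neighborhood is computed from the guide's correlation vector plus one
rank-of-guide count per gene rather than from an all-pairs MR matrix.

## Promoters and motif scanning

Promoters default to 1,500 nt upstream of the TSS, excluding the TSS
base, reported 5'→3' on the gene's sense strand.  Coordinates: GFF3
input is 1-based; internally intervals are half-open 0-based.  For a +
strand gene with 1-based TSS t the genomic window is [t−1−L, t−1); for a
− strand gene it is [t, t+L), reverse-complemented on extraction.  When
reading GFF3 gene features the TSS is the feature start (+) or end (−).
Windows truncated by contig boundaries are returned shorter, with a
warning.

Scanning is single-stranded on the promoter sense strand: motif pairs
that are reverse complements of one another (AKATTCY / RGAATMT) are
treated as distinct motifs supplied explicitly, so no strand collapsing
is performed.  Each IUPAC letter compiles to a character class of its
concrete expansion; a sequence base `N` therefore matches no motif
letter, including motif `N` (conservative: masked regions cannot inflate
presence).  Overlapping occurrences are all reported via a look-ahead
regex; presence is binary per gene for enrichment.

## Enrichment statistics

For a study set of n genes inside a background of N, with K background
genes carrying a feature and k of the study genes carrying it, the
p-value is the exact hypergeometric upper tail P(X ≥ k), summed in log
space with log-gamma binomials so N ≈ 30,000 cannot overflow.  The
one-sided Fisher exact test of the corresponding 2×2 table is the same
quantity; the package computes it through an independent route
(`scipy.stats.fisher_exact`) and the test suite asserts exact agreement,
so either entry point can be used.  Multiple testing uses the
Benjamini–Hochberg step-up adjustment (via statsmodels) across all
features of one run, with significance tiers at FDR < 0.05 and a strict
FDR < 0.01.

The default counting unit is the **gene**: a promoter counts once no
matter how many occurrences it holds.  An occurrence-level mode is also
exposed (k = occurrences in study promoters against n = scannable study
positions, K/N likewise over the background) for users who prefer
per-site statistics; the two modes answer different questions and their
p-values are not comparable.

## DAP-seq target inference

FRiP (fraction of reads in peaks) is an experiment-level quality score;
the default filter retains peak sets with FRiP ≥ 0.05 (inclusive).  A
per-peak reading of the threshold is available behind a flag for peak
tables that carry per-peak scores.  A gene is a target when at least one
retained peak overlaps its promoter window by ≥ 1 bp under the half-open
convention (abutting intervals do not overlap); summit position is not
used.  Per-gene signal is the maximum over overlapping peaks — the only
aggregation that is order-preserving under peak merging — and the top-N
list (default 350) ranks by descending signal with lexicographic tie
break.

## Network assembly

Gene ids are namespaced by species prefix ("Vv:", "At:") because the two
id systems could otherwise collide.  The species-1 subnetwork is the
guide plus its neighborhood, with coexpression edges weighted by PCC
(MR kept as an edge attribute) and per-node motif-presence lists.
Species-2 genes enter when they are orthologs of retained species-1
nodes or differentially expressed under the stress contrast
(FDR < 0.05, configurable); they carry log2FC, an up/down direction, and
the set of TFs whose DAP-seq targets include them.  A `cold` hub node
connects to every DE-significant species-2 gene with an up/down edge.
Orthology is consumed as a table of precomputed pairs with confidence
scores (an upstream homology search is not re-run here).  Exports are
SIF plus node/edge attribute TSVs in lexicographic order, so identical
networks export byte-identically and the files round-trip through
`import_network`.

Two presentation utilities live here: per-row Z-scores
((v − mean)/sd, sample sd with n−1; constant rows map to zeros with a
warning) and the qPCR relative-expression fold change 2^−ΔΔCt.

## Synthetic data: what it emulates

All inputs are generated from one seed; a seed sequence spawns one child
per component (expression, promoters, peaks, DE, orthology) so any
component regenerates independently and identical configurations give
byte-identical files.

* **Expression.**  Default desk scale is 2,000 genes × 60 conditions × 3
  replicates — a scaled stand-in for a ~30,000-gene, 235-condition
  compendium averaged from ~650 samples.  log2 expression is a per-gene
  baseline (uniform 2–8) plus a latent-factor term: the planted module
  (default 30 genes including the guide) loads on one factor with
  loading a (default 0.9; expected within-module PCC = a²), and the
  remaining genes form independent background blocks (default 50 genes,
  loading 0.8) on factors of their own.  The background structure is
  deliberate: expression compendia are pervasively co-expressed, and a
  fully i.i.d. background makes the mutual-rank metric degenerate — a
  noise gene whose strongest chance correlation points at the guide
  becomes a reciprocal near-best partner (MR ≈ 5–20) and contaminates
  every neighborhood, which no realistic compendium exhibits.  Replicate
  columns add Gaussian log-noise (sd 0.2) and values are exponentiated
  to the RPKM scale (log-normal rather than negative-binomial: the
  co-expression stage operates on log values, so only the correlation
  structure matters and PCC expectations stay closed-form).
* **Promoters.**  One contig per gene (promoter + 100 bp flank),
  alternating orientation so both strands are exercised; i.i.d. bases at
  the configured GC content (default 0.4).  Foreground genes receive one
  planted instance of each motif with probability p_fg, background genes
  with p_bg, drawn uniformly from the motif's IUPAC expansion at uniform
  non-overlapping offsets; ground truth records (gene, motif, offset,
  instance).  Chance hits occur on top of planted ones at the closed-form
  per-position rate implied by the GC content.
* **Peaks.**  Per set: 50 true-target peaks placed entirely inside
  promoter windows and 50 background peaks in the flanks, 60 bp wide,
  with uniform signals; FRiP values default to (0.12, 0.08, 0.03) so the
  ≥ 5% filter is actually exercised.
* **DE and orthology.**  500 species-2 genes, 10% differentially
  expressed with |log2FC| ~ N(2, 0.5) and two-sided z-test p-values
  (se 0.25), nulls uniform; BH FDR appended.  Orthology is a partial
  one-to-one map (150 pairs) always covering the planted module.

What passing the synthetic benchmarks shows: the implementation
faithfully computes the declared statistics and recovers structure it
was designed to plant.  What it does not show: robustness to real-data
pathologies — batch effects, heteroscedastic noise, transcript-model
ambiguity in TSS choice, repeat-rich promoters, or peak-calling
artifacts — none of which the generator emulates.

## Benchmark conditions and reported quantities

`scripts/acceptance.py` measures, at the defaults above: module-recovery
precision and recall over 10 seeds (with 29 recoverable non-guide
members and k = 30, precision is capped at 29/30 ≈ 0.967 by
construction); offset-exact planted-site recovery with p_bg = 0;
DAP-seq target recovery over FRiP-retained sets; the false-positive rate
of 200 null decoy motifs and the detection rate of one planted motif
(p_fg = 0.6 vs p_bg = 0.2, study 300 of 2,000) over 20 runs each; and
two worked sequence examples — a 1,071 bp ORF translating to 356
residues, and the global-alignment identity of a synthetic 356-residue
pair differing at 3 positions (353/356 = 99.2%, match +1 / mismatch 0 /
linear gap −1; identity = matches over alignment columns, one decimal).
The test suite additionally runs the module-recovery study over 20 seeds
and the calibration studies over 50 seeds.  Problem sizes were chosen
once as desk-scale stand-ins and are not tuned per run.

## Known limitations

* Printed neighborhood lists from any specific published study are not
  bit-reproducible without that study's exact matrix, log convention and
  tie rule; the package fixes its own conventions and documents them.
* The enrichment FDRs depend on the counting unit (genes vs
  occurrences); both are exposed, gene-level is the default.
* The per-set FRiP reading of the quality filter is the standard one,
  but peak tables with per-peak scores can use the per-peak mode.
* The network builder exposes its inclusion filters (DE FDR threshold,
  orthology restriction to retained nodes) rather than hard-coding one
  study's figure membership.
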