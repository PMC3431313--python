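# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions. Everything quantitative stated here
is computed by the test suite or the acceptance script.

## Coordinates and window geometry

All coordinates are 0-based, half-open, everywhere in memory; BED and
bedGraph are native to this convention and the TSV gene-table dialect is
declared 0-based, so no shifting occurs at file boundaries. The genome is
tiled into fixed windows (default 100 bp) anchored at coordinate 0; the
final partial window of each chromosome is dropped, so every track vector
has exactly floor(length/width) entries. Chromosome names are matched as
exact strings; a warning is logged when two inputs share no names but would
match after stripping a `chr` prefix.

## Windowed Poisson enrichment test

Per window, the ChIP count k is tested against Poisson(λ) with

    λ = max( mean(input over local window) × N_c/N_i , λ_min ),

one-sided upper tail only (enrichment, not depletion). λ_min defaults to
the library-scaled genome-wide mean input rate, which prevents zero- or
near-zero-input windows from producing spurious significance; an all-zero
input track is rejected unless λ_min is supplied explicitly.

The local background window defaults to 50 windows (5 kb). A strictly
per-window input estimate (`local_background=1`) is available, but a single
100-bp slice of an input library is a very noisy rate estimate: its
sampling variance both costs power inside genuinely enriched blocks and is
the reason broad-source peak callers estimate their background from a wider
local window. With the 5-kb local mean, a fold-4 enrichment over a
background of 5 reads/window is detected in ≈92% of block-interior windows,
while the null per-window positive rate at p < 0.001 stays below 0.001
(discreteness of the Poisson test makes it conservative). Both properties
are asserted in the acceptance tests.

Tail probabilities come from the Poisson log-survival function; p-values
are floored at the smallest positive double and scores are −log10 p taken
from the log tail directly, so deeply significant windows do not saturate.

No multiple-testing correction is applied at the peak stage: the analysis
thresholds raw p < 0.001, and peaks are single 100-bp windows (adjacent
significant windows are not merged). Consequences: peak counts are window
counts, and "shared" peaks between two sets mean ≥1 bp overlap (an
identity-matching mode is available).

## Target classification

Genic regions are gene bodies extended 3 kb at both genomic ends (strand
affects only TSS identity, not the genic region), clipped at chromosome
bounds, and kept per gene even when they overlap, because target status is
a per-gene property. Distal intergenic regions are the complement of gene
bodies padded by 3 kb. Peaks are assigned to regions by their window
midpoint so each peak is counted exactly once where regions abut or
overlap. A region with ≥1 peak/kb (closed threshold) is a target locus.
Genes flanking a target intergenic region — the single nearest gene on each
side, strand ignored — are intergenic targets; genes whose own genic region
is a target are genic targets; both conditions give "both". The categories
are disjoint and exhaustive over targets.

## Families, clusters, and enrichment

A gene belongs to at most one family (first listed assignment wins, with a
logged report). A cluster is a maximal run of ≥3 same-family genes that are
adjacent in the chromosome's (chrom, start)-sorted gene order; any
intervening gene of another family or of no family breaks the run. This is
the strictest reading of "side by side"; `max_intervening` relaxes it.
Adjacency is positional, not distance-based.

Family enrichment among n target genes with k family members is the exact
binomial tail P(X ≥ k), X ~ Binomial(n, π_f), with π_f the family fraction
of all annotated genes; clustering enrichment is the analogous test among
target family genes against the genome-wide clustered fraction π_c. Both
prevalences are recomputed from whatever catalog is supplied rather than
assumed.

The family × sample z-score matrix averages window scores over each
family's genic regions — the mean, not the sum, so families with more genes
or longer regions are not favoured — and standardizes across families
within each sample (a zero-variance sample column yields z = 0 rather than
a division failure). Hierarchical ordering uses average linkage on
correlation distance (1 − Pearson r), the most common heat-map default;
the source analysis does not pin these down, so they are package choices.
Constant rows/columns (undefined correlation) are dropped with a warning.
Clustered-vs-dispersed binding levels are compared with a two-sided
Wilcoxon rank-sum test, exact when both groups have ≤10 members.

## Expression integration

Expression is quantified reads-per-kb-per-million (count/(length/1000)/
(library/10^6)); the original study's in-house quantifier is unspecified,
so this standard formula is the package's stand-in. The binding–expression
relationship uses genes sorted ascending by binding (ties broken by gene
id) in bins of 2000 genes; the reported r is the gene-level Pearson
correlation of binding against log1p expression (bin-level r is available
via flag — the choice of level is genuinely open and gene-level is the
default because it does not depend on the bin size). Deregulation is
fc = (kd + c)/(control + c) with pseudocount c = 0.1 expression units
(bounds fold changes for zero-expression genes); up ⇔ fc ≥ 1.5,
down ⇔ fc ≤ 1/1.5, so swapping conditions maps up↔down exactly. Target
categories are contrasted against seeded, size-matched random gene sets via
rank-sum tests (median p over the resamples is reported). Composition of
the up-regulated targets (non-family share, non-clustered share) is tested
with binomial tails against the composition of all targets.

## Overlap and exclusivity

The exclusivity null relocates each interval of set A uniformly within its
own chromosome, preserving per-chromosome counts and lengths but not
spacing; relocated intervals may overlap each other. This is the simplest
exchangeable null; a circular-shift mode preserving spacing is provided as
an alternative for clumped interval sets (its null can be strongly bimodal,
which is the point of offering it). The empirical p-value uses the add-one
correction, so p ∈ [1/(n_perm+1), 1] and monotone in the observed overlap;
under the null it is approximately uniform, verified by a KS check across
200 seeds. Under-overlap (exclusivity) is the one-sided alternative.
Annotation-term enrichment applies the same binomial tail per term with
Benjamini–Hochberg FDR across terms.

## Synthetic data generator

The generator emulates the statistical structure of the real analysis: it
is the fixture for every end-to-end test, with defaults that are the study
conditions used throughout the acceptance checks.

* **Genome**: 2 chromosomes × 1 Mb; 500 genes with gamma-distributed
  lengths (mean 2 kb, floor 300 bp); 20 families of 7 genes, i.e. 28% of
  genes in families, matching the reported genome-wide family prevalence.
* **Clusters**: 25% of family genes are laid out in contiguous runs
  (minimum run 3, whole families clustered until the budget is spent),
  close to the reported ~23% genome-wide clustered fraction. Cluster
  membership is positional, so gene spacing is irrelevant to detection.
* **Blocks**: one block per cluster spanning the cluster ±3 kb (overlapping
  blocks merged), plus 2 purely intergenic blocks of 10 kb placed ≥3 kb
  from every gene. Enrichment fold 4.
* **Counts**: input ~ Poisson(5 × N_i/N_c) per window; ChIP ~ Poisson(5 ×
  fold), fold = block enrichment for windows whose midpoint is inside a
  block, 1 elsewhere. Library depths default to equal (1e6 each) and are
  carried as the designed library sizes.
* **Expression**: log expression = 3.0 − 2.0·1[gene in block] + N(0, 0.5)
  per condition, exponentiated (lognormal values, simple fold-change
  semantics). In the knockdown condition the repression term is removed for
  80% of the non-clustered block genes; clustered block genes stay
  repressed, mirroring the observed resistance of clustered targets to
  de-repression.
* **Streams**: placement, block placement, counts, and expression each draw
  from an independently seeded stream derived from (seed, stage), so
  changing one stage's parameters leaves the others bit-identical; every
  output is a pure function of (config, seed).

What the generator does **not** emulate: read-level artifacts (fragment
lengths, duplicates, mappability, GC), copy-number variation, nucleosome
occupancy structure, inter-gene expression covariance, and realistic
genome-scale gene counts. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistics under the stated model, not
performance on real libraries. One visible consequence of the model: with
independent per-condition noise of sd 0.5 on the natural-log scale, ~50% of
genes show ≥1.5-fold changes by noise alone, so knockdown deregulation
calls are far noisier than in a replicate-averaged experiment; the
planted signal still shows as an up-shift and a non-clustered excess among
up-regulated targets rather than as a near-total up-dominance.

The planted-truth target set for recovery scoring is defined by running the
target classifier on a *perfect* peak set (every window whose midpoint lies
in a block); sensitivity and precision of the noisy pipeline are measured
against that oracle, isolating the statistical stages from arbitrary
edge-overlap bookkeeping.

## Problem sizes used in tests and acceptance runs

Null calibration uses 100,000 windows; oracle-equivalence grids cover
Poisson λ ≤ 50, k ≤ 200 (relative error ≤1e-10) and binomial n ≤ 5000
(≤1e-12, against a 50-digit-precision summation oracle); cluster detection
is checked against a run-length oracle on 1000 random fixtures; the
binding-expression coupling sign is checked across 100 generator seeds; the
exclusivity null across 200 seeds. The full suite runs in about a minute on
one CPU.

## Known limitations

* The λ floor and 5-kb local background are this package's documented
  choices; other input-normalization schemes (e.g. multi-scale local
  maxima) would shift borderline windows.
* Percentages in reports are rounded to integers, matching how such counts
  are usually quoted; use the raw counts in the same reports for arithmetic.
* The permutation null ignores mappability and GC composition; on real
  data, an exclusivity p-value from it is optimistic wherever the two
  interval sets share ascertainment biases.
* With very small catalogs (<2 covered families) the z-score matrix is
  refused rather than standardized on degenerate support.
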