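# h1blocks

Analysis toolkit for **block-forming chromatin binders** — proteins such as
linker histone H1.5 that, unlike sharply peaked transcription factors, coat
multi-kilobase stretches of both genic and intergenic DNA. The package
re-implements, as a tested and reusable pipeline, the computational analysis
used to map such binding from ChIP-seq: windowed Poisson enrichment testing
against input, peak-density target classification, detection of gene-family
clusters and their enrichment among targets, block-significance profiling,
binding–expression integration, knockdown deregulation breakdowns, and a
permutation test for mutual exclusivity of two peak sets. A synthetic-data
generator with planted enrichment blocks makes every stage testable end to
end without external data.

It is written for computational biologists who want either the individual
statistical operations (as library functions) or the orchestrated pipeline
(as the `h1blocks` command-line tool).

## The statistics at the core

**Windowed Poisson enrichment.** The genome is tiled into 100-bp windows.
For window *w* with ChIP count *k<sub>w</sub>* and input count
*m<sub>w</sub>*, with library sizes *N<sub>c</sub>* and *N<sub>i</sub>*, the
background rate is

&nbsp;&nbsp;&nbsp;&nbsp;λ<sub>w</sub> = max( m̄<sub>w</sub> · N<sub>c</sub>/N<sub>i</sub> , λ<sub>min</sub> ),

where m̄<sub>w</sub> is the input count averaged over a 5-kb local window
(50 windows; configurable down to strictly per-window) and λ<sub>min</sub>
is the scaled genome-wide mean input rate. The one-sided upper tail
p = P(X ≥ k<sub>w</sub>), X ~ Poisson(λ<sub>w</sub>), is computed from the
log survival function; windows with p < 0.001 are significant peaks. Peaks
are kept at single-window granularity (no merging), so peak counts, peak
densities, and peak-set overlaps are all defined per window.

**Targets.** Genic regions are gene bodies ±3 kb; distal intergenic regions
are ≥3 kb from every gene. A region with ≥1 peak per kb is a target locus;
a gene is a target when its genic region is a target and/or it is the
nearest gene on either side of a target intergenic region, giving the
disjoint categories genic / intergenic / both.

**Gene families and clusters.** A cluster is a run of ≥3 adjacent genes of
one family in a chromosome's gene order. Family membership and clustering
among target genes are tested with exact binomial tails
P(X ≥ k), X ~ Binomial(n, π), against genome-wide prevalences π.

**Blocks.** The mean peak score (−log10 p) in non-overlapping 5-kb windows
is histogrammed against a control in which peak scores are shuffled
uniformly across grid positions: genuine block structure shows up as excess
mass at both histogram extremes.

**Expression coupling.** Genes sorted by binding score are cut into
2000-gene bins; per-bin mean expression and a gene-level Pearson r between
binding and log1p expression quantify repression. Knockdown deregulation is
a 1.5-fold-change call on pseudocounted values, broken down by
family/cluster membership with binomial composition tests.

**Exclusivity.** Overlap between two peak sets (≥1 bp, half-open) is
compared with a permutation null that relocates intervals uniformly within
their chromosome; the empirical under-overlap p-value uses the add-one
correction (1 + #{shared_perm ≤ shared_obs}) / (n_perm + 1).

## Worked example

Run the full synthetic pipeline (2-Mb genome, 500 genes, 20 families,
fold-4 blocks planted over the gene-family clusters):

```python
from h1blocks import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=1), "run1")
```

or equivalently `h1blocks run --seed 1 --out-dir run1`. The manifest of that
run reports:

```
simulate:   500 genes, 7 planted blocks (5 over clusters, 2 intergenic)
callpeaks:  1141 significant 100-bp windows at p < 0.001
targets:    51 target genes = 50 genic + 1 intergenic + 0 both
families:   5 clusters; 37/51 targets in families (73%, binomial p = 5.3e-11);
            35/37 target family genes clustered (95%, p = 3.2e-19)
expression: gene-level binding-expression r = -0.72
overlap:    17/1141 peaks (1.5%) overlap the non-block genome,
            exclusivity p = 0.000999
```

Reading: peaks concentrate inside the planted blocks, so the genes under
blocks (which are mostly clustered family genes) are recovered as targets;
family membership and clustering are strongly enriched among targets
relative to their genome-wide prevalences (28% and 25% here); binding is
negatively coupled to expression because block genes were simulated as
repressed; and the peak set is significantly excluded from the block-free
(accessible) portion of the genome.

Each stage is also available standalone — `h1blocks simulate`, `callpeaks`,
`blocks`, `targets`, `families`, `expression`, `overlap` — on
BED/bedGraph/TSV inputs. All coordinates are 0-based, half-open, including
the TSV gene-table dialect.

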