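"""Synthetic genomes with planted enrichment blocks and coupled expression.

The generator emulates the statistical structure of a broad, block-forming
chromatin binder: a small multi-chromosome genome carrying gene families, a
controllable share of family genes arranged in clusters of three or more
adjacent genes, multi-kb enrichment blocks planted over those clusters (plus
purely intergenic blocks), Poisson-distributed ChIP/input window counts with
a fold increase inside blocks, and lognormal expression negatively coupled
to block membership, with a knockdown condition that lifts the repression
from a fraction of the non-clustered block genes only.

Every output is a pure function of (config, seed).  Each stage draws from
its own independently seeded stream, so changing one stage's parameters
leaves the other stages' outputs bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizingError, ValidationError
from .family_analysis import ClusterSet, detect_clusters
from .genome_io import GenomeAnnotation
from .expression_integration import ExpressionTable
from .window_stats import WindowCounts

_STREAMS = {"placement": 0, "blocks": 1, "counts": 2, "expression": 3}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stage]]))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a 2-Mb genome (2 chromosomes of 1 Mb), 500 genes of
    ~2 kb, 20 families of 7 genes (28% of genes in families), a quarter of
    family genes arranged in clusters, fold-4 enrichment blocks over a
    background of 5 reads per 100-bp window at equal library depths, and a
    repression coupling of 2 natural-log units with lognormal noise.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 500
    gene_length_mean: int = 2_000
    n_families: int = 20
    family_sizes: int | tuple[int, ...] = 7
    fraction_clustered: float = 0.25
    block_enrichment: float = 4.0
    background_rate: float = 5.0
    chip_depth: float = 1_000_000.0
    input_depth: float = 1_000_000.0
    repression_strength: float = 2.0
    derepressed_fraction: float = 0.8
    seed: int = 0
    # secondary knobs (window geometry, block placement, expression scale)
    window_width: int = 100
    flank: int = 3_000
    n_intergenic_blocks: int = 2
    intergenic_block_length: int = 10_000
    expression_noise_sd: float = 0.5
    baseline_log_expression: float = 3.0

    def __post_init__(self) -> None:
        positive = ["n_chroms", "chrom_length", "n_genes", "gene_length_mean",
                    "n_families", "window_width", "flank", "chip_depth",
                    "input_depth", "background_rate"]
        for name in positive:
            if getattr(self, name) <= 0 and not (name == "n_genes" and self.n_genes == 0):
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be nonnegative")
        for name in ("fraction_clustered", "derepressed_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.block_enrichment <= 1:
            raise ConfigurationError("block_enrichment must exceed 1")
        if self.repression_strength < 0:
            raise ConfigurationError("repression_strength must be nonnegative")
        if self.expression_noise_sd < 0:
            raise ConfigurationError("expression_noise_sd must be nonnegative")

    def sizes_list(self) -> list[int]:
        if isinstance(self.family_sizes, int):
            return [self.family_sizes] * self.n_families
        sizes = list(self.family_sizes)
        if len(sizes) != self.n_families:
            raise ConfigurationError(
                f"family_sizes has {len(sizes)} entries for {self.n_families} families"
            )
        return sizes

    def as_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["family_sizes"], int):
            d["family_sizes"] = list(d["family_sizes"])
        return d


@dataclass
class BlockTruth:
    """Planted enrichment blocks: the ground truth for recovery checks."""

    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "enrichment", "covered_families"]))

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df):
            if (df["enrichment"] <= 1).any():
                raise ValidationError("block enrichment factors must exceed 1")
            for chrom, grp in df.groupby("chrom"):
                g = grp.sort_values("start")
                if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                    raise ValidationError(f"overlapping blocks on {chrom}")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def covers(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside a block on this chromosome."""
        mask = np.zeros(len(pos), dtype=bool)
        for row in self.intervals[self.intervals["chrom"] == chrom].itertuples():
            mask |= (pos >= row.start) & (pos < row.end)
        return mask

    def gene_in_block(self, annotation: GenomeAnnotation) -> pd.Series:
        """Per gene: does the gene body overlap any block (>= 1 bp)?"""
        flags = []
        for gene in annotation.genes.itertuples():
            blocks = self.intervals[self.intervals["chrom"] == gene.chrom]
            hit = ((blocks["start"] < gene.end) & (blocks["end"] > gene.start)).any()
            flags.append(bool(hit))
        return pd.Series(flags, index=annotation.genes["gene_id"].to_numpy(),
                         name="in_block")


def generate_genome(config: SimConfig) -> GenomeAnnotation:
    """Place genes, families, and clusters on a multi-chromosome genome.

    A ``fraction_clustered`` share of family genes is laid out in contiguous
    runs of at least three same-family genes; all other genes (dispersed
    family members and singletons) are interleaved in random order.  Genes
    never overlap and are sorted per chromosome.
    """
    rng = _stage_rng(config.seed, "placement")
    chroms = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    if config.n_genes == 0:
        empty = pd.DataFrame(columns=["chrom", "start", "end", "strand",
                                      "gene_id", "family_id"])
        return GenomeAnnotation(chrom_sizes=chroms, genes=empty)

    sizes = config.sizes_list()
    n_family_genes = sum(sizes)
    if n_family_genes > config.n_genes:
        raise ConfigurationError(
            f"family sizes sum to {n_family_genes} > n_genes={config.n_genes}"
        )
    width = max(len(str(config.n_genes)), 4)
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    families: list[str | None] = []
    for fi, size in enumerate(sizes):
        families.extend([f"fam{fi:03d}"] * size)
    families.extend([None] * (config.n_genes - n_family_genes))

    # decide which family genes form clusters: walk families in order, carving
    # one run (>= 3 genes) per family until the clustered-gene budget is spent
    target_clustered = round(config.fraction_clustered * n_family_genes)
    units: list[list[int]] = []      # indices into the gene list
    cursor = 0
    remaining = target_clustered
    for size in sizes:
        idx = list(range(cursor, cursor + size))
        cursor += size
        run = 0
        if remaining >= 3 and size >= 3:
            run = min(size, max(3, remaining))
        if run:
            units.append(idx[:run])
            remaining -= run
            idx = idx[run:]
        units.extend([i] for i in idx)
    units.extend([i] for i in range(cursor, config.n_genes))

    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    # round-robin chromosomes through the shuffled unit list
    per_chrom_units: dict[str, list[list[int]]] = {c: [] for c in chroms}
    names = sorted(chroms)
    for u, unit in enumerate(units):
        per_chrom_units[names[u % len(names)]].append(unit)

    lengths = np.maximum(
        rng.gamma(shape=4.0, scale=config.gene_length_mean / 4.0,
                  size=config.n_genes).round().astype(int), 300)
    rows = []
    for chrom in names:
        chrom_units = per_chrom_units[chrom]
        flat = [i for unit in chrom_units for i in unit]
        intra_gaps = rng.integers(100, 501, size=len(flat))
        total = int(lengths[flat].sum() + intra_gaps.sum())
        n_gaps = len(chrom_units) + 1
        slack = config.chrom_length - total
        if slack <= n_gaps:
            raise SizingError(
                f"chromosome length {config.chrom_length} too small to place "
                f"{len(flat)} genes totalling {total} bp plus {n_gaps} gaps; "
                "increase chrom_length or reduce n_genes/gene_length_mean"
            )
        gaps = np.floor(rng.dirichlet(np.ones(n_gaps)) * slack).astype(int)
        pos = int(gaps[0])
        gi = 0
        for u, unit in enumerate(chrom_units):
            for j, i in enumerate(unit):
                if j > 0:
                    pos += int(intra_gaps[gi])
                start = pos
                end = start + int(lengths[i])
                rows.append((chrom, start, end, "+" if rng.random() < 0.5 else "-",
                             gene_ids[i], families[i]))
                pos = end
                gi += 1
            pos += int(gaps[u + 1])
        assert pos <= config.chrom_length
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                        "gene_id", "family_id"])
    return GenomeAnnotation(chrom_sizes=chroms, genes=genes)


def plant_blocks(annotation: GenomeAnnotation, config: SimConfig,
                 clusters: ClusterSet | None = None,
                 over_clusters: bool = True) -> BlockTruth:
    """Plant enrichment blocks over gene-family clusters and intergenic space.

    One block per cluster spans the cluster's genes extended by ``flank`` on
    both sides (blocks that would overlap are merged).  In addition,
    ``n_intergenic_blocks`` blocks of ``intergenic_block_length`` are placed
    at least ``flank`` away from every gene and clear of existing blocks.
    """
    rng = _stage_rng(config.seed, "blocks")
    if clusters is None:
        clusters = detect_clusters(annotation)
    rows: list[dict] = []
    if over_clusters:
        if len(clusters) == 0 and config.n_genes > 0:
            raise ConfigurationError(
                "blocks over clusters requested but no clusters were detected"
            )
        for cl in clusters.clusters.itertuples():
            size = annotation.chrom_sizes[cl.chrom]
            rows.append(dict(chrom=cl.chrom, start=max(cl.start - config.flank, 0),
                             end=min(cl.end + config.flank, size),
                             enrichment=float(config.block_enrichment),
                             covered_families=(cl.family_id,)))
    rows = _merge_blocks(rows)

    for _ in range(config.n_intergenic_blocks):
        placed = _place_intergenic(annotation, rows, config, rng)
        if placed is None:
            raise SizingError(
                "no intergenic gap large enough for a "
                f"{config.intergenic_block_length}-bp block {config.flank} bp from "
                "every gene"
            )
        rows.append(placed)
        rows = _merge_blocks(rows)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "enrichment",
                                     "covered_families"])
    return BlockTruth(intervals=df)


def _merge_blocks(rows: list[dict]) -> list[dict]:
    merged: list[dict] = []
    for row in sorted(rows, key=lambda r: (r["chrom"], r["start"])):
        if merged and merged[-1]["chrom"] == row["chrom"] \
                and row["start"] < merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], row["end"])
            prev["enrichment"] = max(prev["enrichment"], row["enrichment"])
            prev["covered_families"] = tuple(
                dict.fromkeys(prev["covered_families"] + row["covered_families"]))
        else:
            merged.append(dict(row))
    return merged


def _place_intergenic(annotation: GenomeAnnotation, existing: list[dict],
                      config: SimConfig, rng: np.random.Generator) -> dict | None:
    length = config.intergenic_block_length
    candidates = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        blocked: list[tuple[int, int]] = []
        for gene in annotation.genes_on(chrom).itertuples():
            blocked.append((max(gene.start - config.flank, 0),
                            min(gene.end + config.flank, size)))
        for row in existing:
            if row["chrom"] == chrom:
                blocked.append((row["start"], row["end"]))
        blocked.sort()
        cursor = 0
        for s, e in blocked + [(size, size)]:
            if s - cursor >= length:
                candidates.append((chrom, cursor, s))
            cursor = max(cursor, e)
    if not candidates:
        return None
    chrom, lo, hi = candidates[int(rng.integers(0, len(candidates)))]
    start = int(rng.integers(lo, hi - length + 1))
    return dict(chrom=chrom, start=start, end=start + length,
                enrichment=float(config.block_enrichment), covered_families=())


def oracle_peak_set(truth: BlockTruth, chrom_sizes: dict[str, int],
                    width: int = 100, score: float = 10.0):
    """The peak set a perfect caller would produce from the planted blocks.

    Every window whose midpoint lies inside a block becomes a peak.  Running
    the target classifier on this set yields the planted-truth target table
    against which recovery sensitivity and precision are measured.
    """
    from .genome_io import IntervalSet
    from .window_stats import PeakSet
    rows = []
    for chrom in sorted(chrom_sizes):
        n_win = chrom_sizes[chrom] // width
        mids = np.arange(n_win, dtype=np.int64) * width + width // 2
        for w in np.flatnonzero(truth.covers(chrom, mids)):
            rows.append((chrom, int(w) * width, (int(w) + 1) * width, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return PeakSet(intervals=IntervalSet(df), alpha=0.001, width=width)


def simulate_window_counts(annotation: GenomeAnnotation, truth: BlockTruth,
                           config: SimConfig) -> WindowCounts:
    """Draw Poisson ChIP and input counts on the window grid.

    Input windows are Poisson(background_rate x input_depth/chip_depth);
    ChIP windows are Poisson(background_rate x fold), with fold equal to the
    block's enrichment for windows whose midpoint falls inside a block and 1
    elsewhere.  The configured depths are carried as the library sizes.
    """
    rng = _stage_rng(config.seed, "counts")
    width = config.window_width
    input_rate = config.background_rate * config.input_depth / config.chip_depth
    if input_rate <= 0 or config.background_rate <= 0:
        raise ConfigurationError("window count rates must be positive")
    chip, inp = {}, {}
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        n_win = size // width
        mids = np.arange(n_win, dtype=np.int64) * width + width // 2
        fold = np.ones(n_win)
        for row in truth.intervals[truth.intervals["chrom"] == chrom].itertuples():
            inside = (mids >= row.start) & (mids < row.end)
            fold[inside] = row.enrichment
        chip[chrom] = rng.poisson(config.background_rate * fold)
        inp[chrom] = rng.poisson(input_rate, size=n_win)
    return WindowCounts(width=width, chip=chip, input=inp,
                        chip_depth=config.chip_depth, input_depth=config.input_depth)


def simulate_expression(annotation: GenomeAnnotation, truth: BlockTruth,
                        config: SimConfig,
                        clusters: ClusterSet | None = None) -> ExpressionTable:
    """Two-condition expression coupled to block membership.

    Control: log expression = baseline - repression_strength x 1[in block]
    + Normal(0, sd) noise, exponentiated (lognormal values).  Knockdown: the
    repression term is removed for a ``derepressed_fraction`` of the
    non-clustered block genes; clustered block genes stay repressed.  Noise
    is drawn independently per condition.
    """
    rng = _stage_rng(config.seed, "expression")
    if clusters is None:
        clusters = detect_clusters(annotation)
    gene_ids = annotation.genes["gene_id"].to_numpy()
    in_block = truth.gene_in_block(annotation).to_numpy() if len(truth) else \
        np.zeros(len(gene_ids), dtype=bool)
    clustered = np.isin(gene_ids, sorted(clusters.gene_ids()))
    derepress = in_block & ~clustered & \
        (rng.random(len(gene_ids)) < config.derepressed_fraction)
    base = config.baseline_log_expression
    sd = config.expression_noise_sd
    log_ctrl = base - config.repression_strength * in_block \
        + rng.normal(0.0, sd, size=len(gene_ids))
    repressed_kd = in_block & ~derepress
    log_kd = base - config.repression_strength * repressed_kd \
        + rng.normal(0.0, sd, size=len(gene_ids))
    table = pd.DataFrame({"control": np.exp(log_ctrl), "kd": np.exp(log_kd)},
                         index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionTable(table=table)
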