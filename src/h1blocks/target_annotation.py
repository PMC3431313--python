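"""Genic/intergenic region definition, peak densities, target classification.

Genic regions extend each gene body 3 kb beyond both annotated ends (the
flank is applied to both genomic ends regardless of strand, so strand does
not change a gene's genic region).  Distal intergenic regions are the parts
of the genome at least 3 kb away from every gene.  A region is a target
locus when it carries at least one significant peak per kb; a gene is a
target when its genic region is a target locus and/or it is the nearest
gene on either side of a target intergenic region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeAnnotation, IntervalSet
from .window_stats import PeakSet

logger = logging.getLogger(__name__)

CATEGORIES = ("genic", "intergenic", "both", "none")


@dataclass
class RegionSet:
    """Intervals of one kind (genic or intergenic) with peak densities.

    Columns: chrom, start, end, kind, gene_id (genic only), and after
    :func:`peak_density` also peak_count, density (peaks per kb) and
    is_target.
    """

    records: pd.DataFrame
    kind: str

    def __len__(self) -> int:
        return len(self.records)

    def targets(self) -> pd.DataFrame:
        if "is_target" not in self.records.columns:
            raise ValueError("densities not computed yet; run peak_density first")
        return self.records[self.records["is_target"]]


@dataclass
class TargetTable:
    """Per-gene binding category: genic / intergenic / both / none."""

    table: pd.DataFrame   # gene_id, category

    def __post_init__(self) -> None:
        bad = set(self.table["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"invalid categories: {sorted(bad)}")

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts().to_dict()
        out = {cat: int(c.get(cat, 0)) for cat in CATEGORIES}
        out["targets"] = out["genic"] + out["intergenic"] + out["both"]
        return out

    def target_ids(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["category"] != "none", "gene_id"])


def genic_regions(annotation: GenomeAnnotation, flank: int = 3000) -> RegionSet:
    """One region per gene: the gene body extended by ``flank`` on both ends.

    Regions are clipped at chromosome bounds; overlapping regions of
    different genes are kept separate so that target status stays a
    per-gene property.
    """
    g = annotation.genes
    sizes = g["chrom"].map(annotation.chrom_sizes)
    df = pd.DataFrame({
        "chrom": g["chrom"],
        "start": np.maximum(g["start"] - flank, 0),
        "end": np.minimum(g["end"] + flank, sizes),
        "kind": "genic",
        "gene_id": g["gene_id"],
    }).reset_index(drop=True)
    return RegionSet(records=df, kind="genic")


def _merge_padded(genes: pd.DataFrame, pad: int, size: int) -> list[tuple[int, int]]:
    """Union of gene bodies each padded by ``pad``, clipped to [0, size)."""
    merged: list[tuple[int, int]] = []
    for row in genes.sort_values("start").itertuples():
        s, e = max(row.start - pad, 0), min(row.end + pad, size)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intergenic_regions(annotation: GenomeAnnotation, buffer: int = 3000) -> RegionSet:
    """Complement of the union of gene bodies padded by ``buffer``.

    Genes less than 2*buffer apart leave no intergenic region between them;
    zero-length results are dropped.
    """
    rows = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        blocked = _merge_padded(annotation.genes_on(chrom), buffer, size)
        cursor = 0
        for s, e in blocked + [(size, size)]:
            if s > cursor:
                rows.append((chrom, cursor, s))
            cursor = max(cursor, e)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["kind"] = "intergenic"
    df["gene_id"] = pd.NA
    return RegionSet(records=df, kind="intergenic")


def peak_density(regions: RegionSet, peaks: PeakSet,
                 threshold: float = 1.0) -> RegionSet:
    """Peaks per kb for each region; target iff density >= threshold.

    A peak is assigned to the region containing its midpoint, so each
    100-bp peak is counted exactly once even where regions abut or overlap.
    """
    df = regions.records.copy()
    zero_len = df["start"] >= df["end"]
    if zero_len.any():
        logger.warning("excluding %d zero-length regions", int(zero_len.sum()))
        df = df[~zero_len].reset_index(drop=True)
    pk = peaks.records
    mids = {chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
            for chrom, grp in pk.groupby("chrom")}
    counts = np.zeros(len(df), dtype=int)
    for i, row in enumerate(df.itertuples()):
        m = mids.get(row.chrom)
        if m is None:
            continue
        counts[i] = np.searchsorted(m, row.end, side="left") - \
            np.searchsorted(m, row.start, side="left")
    df["peak_count"] = counts
    df["density"] = counts / ((df["end"] - df["start"]) / 1000.0)
    df["is_target"] = df["density"] >= threshold
    return RegionSet(records=df, kind=regions.kind)


def _flanking_genes(annotation: GenomeAnnotation, region_chrom: str,
                    start: int, end: int) -> list[str]:
    """The single nearest gene on each side of an intergenic region."""
    genes = annotation.genes_on(region_chrom)
    if genes.empty:
        return []
    out = []
    left = genes[genes["end"] <= start]
    if len(left):
        out.append(left.loc[left["end"].idxmax(), "gene_id"])
    right = genes[genes["start"] >= end]
    if len(right):
        out.append(right.loc[right["start"].idxmin(), "gene_id"])
    return out


def classify_targets(annotation: GenomeAnnotation, genic: RegionSet,
                     intergenic: RegionSet) -> TargetTable:
    """Classify every gene as genic / intergenic / both / none.

    ``genic``: the gene's own genic region is a target locus.
    ``intergenic``: the gene is the nearest gene upstream or downstream of a
    target intergenic region (strand is ignored; proximity decides).
    ``both``: both conditions hold.
    """
    genic_target_genes = set(genic.targets()["gene_id"])
    flank_genes: set[str] = set()
    for row in intergenic.targets().itertuples():
        flank_genes.update(_flanking_genes(annotation, row.chrom, row.start, row.end))
    categories = []
    for gid in annotation.genes["gene_id"]:
        g, i = gid in genic_target_genes, gid in flank_genes
        categories.append("both" if g and i else "genic" if g else
                          "intergenic" if i else "none")
    return TargetTable(table=pd.DataFrame({
        "gene_id": annotation.genes["gene_id"].to_numpy(),
        "category": categories,
    }))


def category_arithmetic(genic_only: int, intergenic_only: int, both: int) -> dict[str, int]:
    """Total target genes from disjoint per-category counts.

    The categories are disjoint and exhaustive over targets, so the total is
    their plain sum (e.g. 1204 + 2294 + 1037 = 4535).
    """
    return {
        "genic": int(genic_only),
        "intergenic": int(intergenic_only),
        "both": int(both),
        "targets": int(genic_only) + int(intergenic_only) + int(both),
    }


def regions_to_intervals(regions: RegionSet) -> IntervalSet:
    cols = [c for c in ("chrom", "start", "end", "gene_id", "density") if c in regions.records]
    df = regions.records[cols].rename(columns={"gene_id": "name", "density": "score"})
    if "score" in df.columns:
        df = df.assign(score=df["score"].fillna(0.0))
    if "name" in df.columns:
        df = df.assign(name=df["name"].fillna("."))
    return IntervalSet(df)
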