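"""Gene families: cluster detection, enrichment statistics, z-score matrices.

A gene-family *cluster* is a run of at least three genes of the same family
sitting side by side in a chromosome's gene order; any intervening gene of a
different family (or of no family) breaks the run under the default strict
reading (``max_intervening`` relaxes it).  Family enrichment among target
genes is tested with an exact one-sided binomial tail against the genome-wide
family (or clustered) prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, ValidationError
from .genome_io import GenomeAnnotation, _open_text
from .target_annotation import TargetTable, genic_regions
from .window_stats import WindowPvalues

logger = logging.getLogger(__name__)


@dataclass
class FamilyCatalog:
    """Mapping gene_id -> family_id (a gene belongs to at most one family).

    When a source lists a gene under several families the first listed
    assignment wins (reported via logging) so that prevalences and counts
    stay well defined.
    """

    table: pd.DataFrame   # gene_id, family_id

    def __post_init__(self) -> None:
        dup = self.table["gene_id"].duplicated()
        if dup.any():
            logger.info("catalog lists %d gene(s) in multiple families; "
                        "keeping first assignment", int(dup.sum()))
            self.table = self.table[~dup].reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyCatalog":
        rows = []
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValidationError(f"{path}: malformed line {lineno}: {line!r}")
                if lineno == 1 and fields[0] == "gene_id":
                    continue
                rows.append((fields[0], fields[1]))
        return cls(table=pd.DataFrame(rows, columns=["gene_id", "family_id"]))

    @classmethod
    def from_annotation(cls, annotation: GenomeAnnotation) -> "FamilyCatalog":
        g = annotation.genes
        has = g["family_id"].notna()
        return cls(table=g.loc[has, ["gene_id", "family_id"]].reset_index(drop=True))

    def family_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["family_id"]

    def members(self, family_id: str) -> list[str]:
        t = self.table
        return t.loc[t["family_id"] == family_id, "gene_id"].tolist()

    def family_genes(self) -> set[str]:
        return set(self.table["gene_id"])

    def genome_family_fraction(self, annotation: GenomeAnnotation) -> float:
        """Fraction of all annotated genes that belong to any family (pi_f)."""
        if annotation.n_genes == 0:
            raise ValidationError("empty annotation")
        in_family = self.family_genes() & set(annotation.genes["gene_id"])
        return len(in_family) / annotation.n_genes

    def genome_clustered_fraction(self, clusters: "ClusterSet",
                                  annotation: GenomeAnnotation) -> float:
        """Fraction of family genes that sit in clusters (pi_c)."""
        fam = self.family_genes() & set(annotation.genes["gene_id"])
        if not fam:
            raise ValidationError("catalog shares no genes with the annotation")
        return len(clusters.gene_ids() & fam) / len(fam)


@dataclass
class ClusterSet:
    """Detected runs of >= min_run adjacent same-family genes."""

    clusters: pd.DataFrame   # family_id, chrom, start, end, n_genes, gene_ids (tuple)
    min_run: int = 3

    def __len__(self) -> int:
        return len(self.clusters)

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.clusters["gene_ids"]:
            out.update(ids)
        return out


def detect_clusters(annotation: GenomeAnnotation,
                    catalog: FamilyCatalog | None = None,
                    min_run: int = 3, max_intervening: int = 0) -> ClusterSet:
    """Find maximal runs of adjacent same-family genes of length >= min_run.

    Adjacency is positional in the chromosome's (chrom, start)-sorted gene
    order; genomic distance between neighbours is irrelevant.  By default any
    gene of a different family (or no family) breaks a run; up to
    ``max_intervening`` such genes may be skipped inside a run if requested.
    """
    if min_run < 1:
        raise ConfigurationError("min_run must be >= 1")
    if catalog is None:
        catalog = FamilyCatalog.from_annotation(annotation)
    fam_of = catalog.family_of()
    rows = []
    for chrom in sorted(annotation.chrom_sizes):
        genes = annotation.genes_on(chrom)
        ids = genes["gene_id"].tolist()
        fams = [fam_of.get(g) for g in ids]
        i = 0
        while i < len(ids):
            f = fams[i]
            if f is None or (isinstance(f, float) and np.isnan(f)):
                i += 1
                continue
            members = [i]
            j, gap = i + 1, 0
            while j < len(ids):
                if fams[j] == f:
                    members.append(j)
                    gap = 0
                else:
                    gap += 1
                    if gap > max_intervening:
                        break
                j += 1
            if len(members) >= min_run:
                sub = genes.iloc[members]
                rows.append((f, chrom, int(sub["start"].min()), int(sub["end"].max()),
                             len(members), tuple(sub["gene_id"])))
                i = members[-1] + 1
            else:
                i += 1
    df = pd.DataFrame(rows, columns=["family_id", "chrom", "start", "end",
                                     "n_genes", "gene_ids"])
    return ClusterSet(clusters=df, min_run=min_run)


def binomial_enrichment(k: int, n: int, pi: float) -> float:
    """Exact one-sided binomial tail P(X >= k), X ~ Binomial(n, pi)."""
    if not (0 < pi < 1):
        raise ConfigurationError(f"background proportion must be in (0, 1), got {pi}")
    if not (0 <= k <= n):
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, pi))


@dataclass
class FamilyEnrichmentReport:
    """Family membership and clustering enrichment among target genes."""

    k: int                # target genes in any family
    n: int                # target genes
    pi_f: float           # genome-wide family prevalence
    p: float | None
    k_c: int              # clustered genes among target family genes
    n_c: int              # target family genes
    pi_c: float | None    # genome-wide clustered fraction of family genes
    p_c: float | None

    @property
    def pct_family(self) -> int | None:
        return round(100 * self.k / self.n) if self.n else None

    @property
    def pct_clustered(self) -> int | None:
        return round(100 * self.k_c / self.n_c) if self.n_c else None


def family_enrichment(targets: TargetTable, catalog: FamilyCatalog,
                      annotation: GenomeAnnotation,
                      clusters: ClusterSet | None = None) -> FamilyEnrichmentReport:
    """Binomial enrichment of family membership and clustering in targets.

    k of n target genes belong to families, tested against the genome-wide
    family prevalence pi_f; among the k target family genes, k_c are
    clustered, tested against the genome-wide clustered fraction pi_c.
    Percentages are reported rounded to the nearest integer.
    """
    if clusters is None:
        clusters = detect_clusters(annotation, catalog)
    target_ids = set(targets.target_ids())
    fam_genes = catalog.family_genes()
    clustered = clusters.gene_ids()
    n = len(target_ids)
    k = len(target_ids & fam_genes)
    pi_f = catalog.genome_family_fraction(annotation)
    target_fam = target_ids & fam_genes
    n_c = len(target_fam)
    k_c = len(target_fam & clustered)
    if n == 0:
        logger.warning("empty target set: enrichment p-values undefined")
        return FamilyEnrichmentReport(k=0, n=0, pi_f=pi_f, p=None,
                                      k_c=0, n_c=0, pi_c=None, p_c=None)
    p = binomial_enrichment(k, n, pi_f) if 0 < pi_f < 1 else None
    pi_c = catalog.genome_clustered_fraction(clusters, annotation) if fam_genes else None
    p_c = binomial_enrichment(k_c, n_c, pi_c) if n_c and pi_c and 0 < pi_c < 1 else None
    return FamilyEnrichmentReport(k=k, n=n, pi_f=pi_f, p=p,
                                  k_c=k_c, n_c=n_c, pi_c=pi_c, p_c=p_c)


def binding_level_comparison(scores: pd.Series, clustered_ids, nonclustered_ids) -> dict:
    """Compare binding scores of clustered vs non-clustered family genes.

    Returns per-group median/quartiles and a two-sided Wilcoxon rank-sum
    p-value (exact when both groups have <= 10 members, normal approximation
    otherwise).
    """
    a = scores.reindex(list(clustered_ids)).dropna().to_numpy()
    b = scores.reindex(list(nonclustered_ids)).dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    summarize = lambda x: dict(n=len(x), median=float(np.median(x)),
                               q1=float(np.percentile(x, 25)),
                               q3=float(np.percentile(x, 75)))
    return dict(clustered=summarize(a), nonclustered=summarize(b),
                p=float(res.pvalue), method=method)


def family_zscore_matrix(tracks: dict[str, WindowPvalues],
                         annotation: GenomeAnnotation,
                         catalog: FamilyCatalog,
                         flank: int = 3000) -> tuple[pd.DataFrame, list[str]]:
    """Family x sample matrix of standardized mean binding scores.

    Each cell is the mean window score over the family's genic regions (the
    mean, not the sum, so families with more genes or longer regions are not
    favoured), standardized to z-scores across families within each sample.
    Families with zero covered windows in any sample are dropped and listed.
    """
    if not tracks:
        raise ValidationError("at least one sample track required")
    regions = genic_regions(annotation, flank=flank).records
    fam_of = catalog.family_of()
    regions = regions.assign(family_id=regions["gene_id"].map(fam_of))
    regions = regions[regions["family_id"].notna()]
    families = sorted(regions["family_id"].unique())
    raw = pd.DataFrame(index=pd.Index(families, name="family_id"),
                       columns=sorted(tracks), dtype=float)
    for sample, pv in tracks.items():
        width = pv.width
        for fam, grp in regions.groupby("family_id"):
            chunks = []
            for row in grp.itertuples():
                s = pv.score.get(row.chrom)
                if s is None:
                    continue
                w0, w1 = row.start // width, -(-row.end // width)
                chunks.append(s[max(w0, 0): min(w1, len(s))])
            vals = np.concatenate(chunks) if chunks else np.array([])
            raw.loc[fam, sample] = vals.mean() if len(vals) else np.nan
    dropped = sorted(raw.index[raw.isna().any(axis=1)])
    if dropped:
        logger.warning("dropping %d families with zero coverage: %s",
                       len(dropped), dropped)
        raw = raw.drop(index=dropped)
    if len(raw) < 2:
        raise ValidationError("fewer than 2 families with coverage; cannot standardize")
    sd = raw.std(axis=0, ddof=0)
    z = (raw - raw.mean(axis=0)).div(sd.where(sd > 0, 1.0), axis=1)
    return z, dropped


def hierarchical_order(matrix: pd.DataFrame, axis: str = "families"
                       ) -> tuple[list, np.ndarray]:
    """Agglomerative ordering with correlation distance and average linkage.

    Distance is 1 - Pearson r between rows (families) or columns (samples).
    Rows/columns with zero variance (undefined correlation) are dropped with
    a warning.  Returns the leaf order (labels) and the scipy linkage matrix.
    """
    if axis not in {"families", "samples"}:
        raise ConfigurationError(f"axis must be 'families' or 'samples', got {axis!r}")
    data = matrix if axis == "families" else matrix.T
    var = data.var(axis=1, ddof=0)
    constant = var[var == 0].index.tolist()
    if constant:
        logger.warning("dropping %d constant %s: %s", len(constant), axis, constant)
        data = data.drop(index=constant)
    if len(data) < 2:
        raise ValidationError("need at least 2 non-constant rows to cluster")
    corr = np.corrcoef(data.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [data.index[i] for i in hierarchy.leaves_list(z)]
    return order, z
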