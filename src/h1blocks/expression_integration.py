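"""Expression quantification and binding-expression integration.

Expression is quantified reads-per-kb-per-million style.  Binding is related
to expression by sorting genes on binding score into fixed-size bins (2000
genes per bin) and by a gene-level Pearson correlation of binding against
log1p expression.  Knockdown deregulation is a plain fold-change call at a
1.5-fold threshold on pseudocounted values, and the breakdown of up-regulated
target genes by family/cluster membership is tested with binomial tails
against the composition of all targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .family_analysis import ClusterSet, FamilyCatalog, binomial_enrichment
from .target_annotation import TargetTable

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Per-gene nonnegative expression values for named conditions."""

    table: pd.DataFrame   # index gene_id, one column per condition

    def __post_init__(self) -> None:
        if (self.table < 0).any().any():
            raise ValidationError("expression values must be nonnegative")

    def condition(self, name: str) -> pd.Series:
        return self.table[name]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def quantify_expression(counts: pd.Series, lengths: pd.Series,
                        library_size: float) -> pd.Series:
    """Reads per kb of gene per million library reads.

    value = count / (length / 1000) / (library_size / 1e6)
    """
    if library_size <= 0:
        raise ValidationError(f"library size must be positive, got {library_size}")
    counts, lengths = counts.align(lengths, join="inner")
    if (counts < 0).any():
        raise ValidationError("negative read counts")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    return counts / (lengths / 1000.0) / (library_size / 1e6)


@dataclass
class BindingExpressionCurve:
    """Per-bin mean expression along the binding-sorted gene list, plus r."""

    bins: pd.DataFrame        # bin, n_genes, mean_binding, mean_expression
    r: float | None
    r_level: str              # "gene" or "bin"
    bin_size: int


def binding_expression_curve(binding: pd.Series, expression: pd.Series,
                             bin_size: int = 2000,
                             r_level: str = "gene") -> BindingExpressionCurve:
    """Mean expression in consecutive bins of genes sorted by binding score.

    Genes are sorted ascending by binding (ties broken by gene id) and cut
    into bins of ``bin_size`` genes; the final bin may be smaller.  The
    correlation r is Pearson's, computed at gene level between binding and
    log1p(expression) by default, or between bin means with
    ``r_level="bin"``.
    """
    if r_level not in {"gene", "bin"}:
        raise ConfigurationError(f"r_level must be 'gene' or 'bin', got {r_level!r}")
    df = pd.DataFrame({"binding": binding, "expression": expression}).dropna()
    if len(df) < 2:
        raise ValidationError("need at least 2 genes with both binding and expression")
    df = df.assign(_gid=df.index.astype(str)) \
        .sort_values(["binding", "_gid"], kind="mergesort").drop(columns="_gid")
    bin_idx = np.arange(len(df)) // bin_size
    grouped = df.assign(bin=bin_idx).groupby("bin")
    bins = grouped.agg(n_genes=("binding", "size"),
                       mean_binding=("binding", "mean"),
                       mean_expression=("expression", "mean")).reset_index()
    if df["binding"].nunique() == 1:
        logger.warning("binding scores are constant: correlation undefined")
        r = None
    elif r_level == "gene":
        r = float(stats.pearsonr(df["binding"], np.log1p(df["expression"]))[0])
    else:
        if len(bins) < 2 or bins["mean_binding"].nunique() == 1:
            r = None
        else:
            r = float(stats.pearsonr(bins["mean_binding"],
                                     np.log1p(bins["mean_expression"]))[0])
    return BindingExpressionCurve(bins=bins, r=r, r_level=r_level, bin_size=bin_size)


def target_expression_contrast(expression: pd.Series, targets: TargetTable,
                               seed: int = 0, n_resamples: int = 1000) -> pd.DataFrame:
    """Expression of each target category vs size-matched random gene sets.

    For every non-empty category, a two-sided Wilcoxon rank-sum test compares
    the category's expression against ``n_resamples`` random gene sets of the
    same size drawn (seeded) from all genes with expression; the median
    p-value over resamples is reported with the group summaries.
    """
    rng = np.random.default_rng(seed)
    universe = expression.dropna()
    rows = []
    for cat, grp in targets.table.groupby("category"):
        if cat == "none":
            continue
        vals = universe.reindex(grp["gene_id"]).dropna()
        if vals.empty:
            logger.warning("category %s: no expressed genes; skipped", cat)
            continue
        ps = []
        for _ in range(n_resamples):
            ctrl = universe.sample(n=len(vals), random_state=rng)
            ps.append(stats.mannwhitneyu(vals, ctrl, alternative="two-sided").pvalue)
        rows.append(dict(category=cat, n=len(vals),
                         mean=float(vals.mean()), median=float(vals.median()),
                         universe_median=float(universe.median()),
                         p_vs_random=float(np.median(ps))))
    return pd.DataFrame(rows)


@dataclass
class DeregulationCalls:
    """Fold-change classification of every gene at threshold theta."""

    calls: pd.DataFrame   # index gene_id; fold_change, category in {up, down, unchanged}
    theta: float
    pseudocount: float

    def summary(self) -> dict:
        counts = self.calls["category"].value_counts()
        up, down = int(counts.get("up", 0)), int(counts.get("down", 0))
        dereg = up + down
        return dict(n_genes=len(self.calls), n_deregulated=dereg, n_up=up,
                    n_down=down, pct_up=round(100 * up / dereg) if dereg else None)

    def deregulated_ids(self) -> pd.Index:
        c = self.calls
        return c.index[c["category"] != "unchanged"]


def classify_deregulated(control: pd.Series, kd: pd.Series, theta: float = 1.5,
                         pseudocount: float = 0.1) -> DeregulationCalls:
    """Classify genes as up / down / unchanged at a fold-change threshold.

    fold change = (kd + c) / (control + c); up iff fc >= theta, down iff
    fc <= 1/theta.  The pseudocount c bounds fold changes for genes with
    zero expression in one condition.
    """
    if theta <= 1:
        raise ConfigurationError(f"theta must exceed 1, got {theta}")
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    control, kd = control.align(kd, join="inner")
    if (control < 0).any() or (kd < 0).any():
        raise ValidationError("negative expression values")
    fc = (kd + pseudocount) / (control + pseudocount)
    category = np.where(fc >= theta, "up", np.where(fc <= 1 / theta, "down", "unchanged"))
    calls = pd.DataFrame({"fold_change": fc, "category": category}, index=control.index)
    calls.index.name = "gene_id"
    return DeregulationCalls(calls=calls, theta=theta, pseudocount=pseudocount)


@dataclass
class DeregulationBreakdown:
    """Composition of up-regulated target genes vs all targets."""

    n_deregulated: int
    n_up: int
    pct_up: int | None
    n_deregulated_targets: int
    n_up_targets: int
    pct_up_targets: int | None
    pct_up_nonfamily: int | None      # of up-regulated targets
    pct_all_nonfamily: int | None     # of all targets
    p_nonfamily: float | None
    pct_up_nonclustered: int | None
    pct_all_nonclustered: int | None
    p_nonclustered: float | None


def percentage(k: int, n: int) -> int | None:
    """Integer-rounded percentage k/n as reported in breakdown summaries."""
    return round(100 * k / n) if n else None


_pct = percentage


def deregulation_breakdown(calls: DeregulationCalls, targets: TargetTable,
                           catalog: FamilyCatalog,
                           clusters: ClusterSet) -> DeregulationBreakdown:
    """Break down up-regulated target genes by family and cluster membership.

    Reports the share of up-regulated genes among deregulated targets and,
    within the up-regulated targets, the non-family and non-clustered shares
    with one-sided binomial p-values against the corresponding shares in all
    targets.
    """
    s = calls.summary()
    target_ids = set(targets.target_ids())
    dereg = set(calls.deregulated_ids())
    up = set(calls.calls.index[calls.calls["category"] == "up"])
    dereg_t = dereg & target_ids
    up_t = up & target_ids
    if not dereg_t:
        logger.warning("no deregulated target genes; breakdown is empty")
    fam = catalog.family_genes()
    clustered = clusters.gene_ids()

    def composition(ids: set, excluded: set) -> tuple[int, int]:
        return len(ids - excluded), len(ids)

    k_nf_up, n_up_t = composition(up_t, fam)
    k_nf_all, n_all_t = composition(target_ids, fam)
    k_nc_up, _ = composition(up_t, clustered)
    k_nc_all, _ = composition(target_ids, clustered)
    pi_nf = k_nf_all / n_all_t if n_all_t else None
    pi_nc = k_nc_all / n_all_t if n_all_t else None
    p_nf = binomial_enrichment(k_nf_up, n_up_t, pi_nf) \
        if n_up_t and pi_nf and 0 < pi_nf < 1 else None
    p_nc = binomial_enrichment(k_nc_up, n_up_t, pi_nc) \
        if n_up_t and pi_nc and 0 < pi_nc < 1 else None
    return DeregulationBreakdown(
        n_deregulated=s["n_deregulated"], n_up=s["n_up"], pct_up=s["pct_up"],
        n_deregulated_targets=len(dereg_t), n_up_targets=len(up_t),
        pct_up_targets=_pct(len(up_t), len(dereg_t)),
        pct_up_nonfamily=_pct(k_nf_up, n_up_t),
        pct_all_nonfamily=_pct(k_nf_all, n_all_t),
        p_nonfamily=p_nf,
        pct_up_nonclustered=_pct(k_nc_up, n_up_t),
        pct_all_nonclustered=_pct(k_nc_all, n_all_t),
        p_nonclustered=p_nc,
    )
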