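import numpy as np
import pandas as pd
import pytest

from h1blocks.genome_io import GenomeAnnotation, IntervalSet
from h1blocks.window_stats import PeakSet, WindowPvalues
from h1blocks.synthetic_data import SimConfig


def make_annotation(genes, chrom_sizes=None):
    """Build a GenomeAnnotation from (chrom, start, end, strand, gene_id[, family]) tuples."""
    rows = []
    for g in genes:
        chrom, start, end, strand, gid = g[:5]
        fam = g[5] if len(g) > 5 else None
        rows.append(dict(chrom=chrom, start=start, end=end, strand=strand,
                         gene_id=gid, family_id=fam))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                     "gene_id", "family_id"])
    if chrom_sizes is None:
        chrom_sizes = {c: int(grp["end"].max()) + 10_000
                       for c, grp in df.groupby("chrom")}
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=df)


def make_pvalues(score_by_chrom, width=100):
    """WindowPvalues from raw -log10 p score vectors."""
    score = {c: np.asarray(v, dtype=float) for c, v in score_by_chrom.items()}
    return WindowPvalues(
        width=width,
        score=score,
        pvalue={c: 10.0 ** -v for c, v in score.items()},
        lam={c: np.ones_like(v) for c, v in score.items()},
    )


def make_peaks(windows, width=100, score=5.0, alpha=0.001):
    """PeakSet from (chrom, window_index) pairs."""
    rows = [(c, w * width, (w + 1) * width, score) for c, w in windows]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return PeakSet(intervals=IntervalSet(df), alpha=alpha, width=width)


@pytest.fixture
def three_gene_cluster():
    """A chromosome with one 3-gene family cluster spanning [10000, 25000)."""
    return make_annotation([
        ("chr1", 10_000, 14_000, "+", "A1", "famA"),
        ("chr1", 16_000, 20_000, "-", "A2", "famA"),
        ("chr1", 21_000, 25_000, "+", "A3", "famA"),
        ("chr1", 60_000, 62_000, "+", "B1", None),
    ], chrom_sizes={"chr1": 100_000})


@pytest.fixture
def default_config():
    return SimConfig(seed=0)
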