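"""Windowed Poisson enrichment testing, peak calling, and block profiling.

The core statistic: the genome is tiled into fixed 100-bp windows and, for
each window, the ChIP read count k is tested against a Poisson background
whose rate is the library-size-scaled input count for that neighbourhood,

    lambda_w = max(mbar_w * N_c / N_i, lambda_min),

where mbar_w is the input count averaged over a local window of the input
track (default 50 windows = 5 kb) and lambda_min is the scaled genome-wide
mean input rate.  The one-sided upper-tail p-value P(X >= k) is reported per
window together with its score s = -log10 p.  Significant windows (p below
alpha, default 0.001) are peaks; adjacent significant windows are kept as
separate single-window peaks.

A local (rather than strictly per-window) background follows standard
peak-caller practice: a single 100-bp input window is far too noisy an
estimate of the local rate, and smoothing it stabilizes power without
leaking ChIP signal into the background.  ``local_background=1`` recovers
the strictly per-window rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, ValidationError
from .genome_io import GenomeAnnotation, IntervalSet, WindowTrack

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)
_TINY = np.finfo(float).tiny


@dataclass
class WindowGrid:
    """Fixed tiling of a genome into non-overlapping windows anchored at 0.

    The final partial window of each chromosome is dropped, so each
    chromosome contributes exactly floor(length / width) windows.
    """

    chrom_sizes: dict[str, int]
    width: int = 100

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"window width must be positive, got {self.width}")
        for chrom, size in self.chrom_sizes.items():
            if size < self.width:
                logger.warning(
                    "chromosome %s (length %d) shorter than window width %d: empty grid",
                    chrom, size, self.width,
                )

    def n_windows(self, chrom: str) -> int:
        return self.chrom_sizes[chrom] // self.width

    @property
    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.chrom_sizes)

    def window_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_windows(chrom), dtype=np.int64) * self.width


def tile_windows(chrom_sizes: dict[str, int], width: int = 100) -> WindowGrid:
    """Tile every chromosome into ``width``-bp windows anchored at coordinate 0."""
    return WindowGrid(chrom_sizes=chrom_sizes, width=width)


@dataclass
class WindowCounts:
    """ChIP and input read counts per fixed-width window, with library sizes."""

    width: int
    chip: dict[str, np.ndarray]
    input: dict[str, np.ndarray]
    chip_depth: float
    input_depth: float

    def __post_init__(self) -> None:
        if set(self.chip) != set(self.input):
            raise ValidationError("ChIP and input tracks cover different chromosomes")
        if self.chip_depth <= 0 or self.input_depth <= 0:
            raise ValidationError("library depths must be positive")
        for chrom in self.chip:
            k, m = np.asarray(self.chip[chrom]), np.asarray(self.input[chrom])
            if len(k) != len(m):
                raise ValidationError(f"{chrom}: ChIP and input vector lengths differ")
            if (k < 0).any() or (m < 0).any():
                raise ValidationError(f"{chrom}: negative window counts")
            self.chip[chrom], self.input[chrom] = k, m

    @classmethod
    def from_tracks(cls, chip: WindowTrack, input: WindowTrack,
                    chip_depth: float | None = None,
                    input_depth: float | None = None) -> "WindowCounts":
        """Combine two single-sample tracks; depths default to track totals."""
        if chip.width != input.width:
            raise ValidationError("ChIP and input tracks have different window widths")
        chroms = set(chip.data) | set(input.data)
        c = {ch: chip.data.get(ch, np.zeros(len(input.data[ch]))) for ch in chroms}
        m = {ch: input.data.get(ch, np.zeros(len(chip.data[ch]))) for ch in chroms}
        for ch in chroms:
            n = max(len(c[ch]), len(m[ch]))
            c[ch] = np.pad(c[ch], (0, n - len(c[ch])))
            m[ch] = np.pad(m[ch], (0, n - len(m[ch])))
        return cls(width=chip.width, chip=c, input=m,
                   chip_depth=chip_depth if chip_depth is not None else max(chip.total(), 1.0),
                   input_depth=input_depth if input_depth is not None else max(input.total(), 1.0))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chip)


@dataclass
class WindowPvalues:
    """One-sided Poisson enrichment p-values and scores per window."""

    width: int
    pvalue: dict[str, np.ndarray]
    score: dict[str, np.ndarray]     # -log10 p
    lam: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return sorted(self.pvalue)

    def score_track(self) -> WindowTrack:
        return WindowTrack(width=self.width, data={c: v.copy() for c, v in self.score.items()})


@dataclass
class PeakSet:
    """Significant single-window peaks (p < alpha) with their scores."""

    intervals: IntervalSet
    alpha: float
    width: int = 100

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def records(self) -> pd.DataFrame:
        return self.intervals.records

    def window_index(self, chrom: str) -> np.ndarray:
        df = self.records
        starts = df.loc[df["chrom"] == chrom, "start"].to_numpy()
        return starts // self.width


def poisson_tail(k: np.ndarray | int, lam: np.ndarray | float) -> np.ndarray:
    """Numerically stable one-sided upper tail P(X >= k) for X ~ Poisson(lam).

    Underflowing tails are floored at the smallest positive float so the
    p-value stays in (0, 1]; scores should be derived from the log tail.
    """
    p = stats.poisson.sf(np.asarray(k) - 1, lam)
    return np.maximum(p, _TINY)


def poisson_enrichment(counts: WindowCounts, local_background: int = 50,
                       lambda_min: float | None = None) -> WindowPvalues:
    """Per-window one-sided Poisson test of ChIP enrichment over input.

    Parameters
    ----------
    counts : WindowCounts
        ChIP and input counts with library depths N_c, N_i.
    local_background : int
        Number of windows the input is averaged over when estimating the
        local rate (1 = strictly per-window input).
    lambda_min : float, optional
        Floor on the background rate.  Defaults to the scaled genome-wide
        mean input count; must be supplied explicitly when the input track
        is all zero.
    """
    if local_background < 1:
        raise ConfigurationError("local_background must be >= 1 window")
    scale = counts.chip_depth / counts.input_depth
    total_windows = sum(len(v) for v in counts.input.values())
    if total_windows == 0:
        raise ValidationError("empty count tracks")
    mean_input = sum(float(v.sum()) for v in counts.input.values()) / total_windows
    if lambda_min is None:
        if mean_input == 0:
            raise ValidationError(
                "input track is all zero; supply an explicit lambda_min policy override"
            )
        lambda_min = mean_input * scale
    if lambda_min <= 0:
        raise ConfigurationError("lambda_min must be positive")

    pvals, scores, lams = {}, {}, {}
    for chrom in counts.chroms:
        k = counts.chip[chrom]
        m = counts.input[chrom].astype(float)
        if len(m) == 0:
            pvals[chrom] = np.empty(0)
            scores[chrom] = np.empty(0)
            lams[chrom] = np.empty(0)
            continue
        if local_background > 1:
            mbar = ndimage.uniform_filter1d(m, size=local_background, mode="nearest")
        else:
            mbar = m
        lam = np.maximum(mbar * scale, lambda_min)
        logp = stats.poisson.logsf(np.asarray(k) - 1, lam)
        pvals[chrom] = np.maximum(np.exp(logp), _TINY)
        scores[chrom] = np.maximum(-logp / _LN10, 0.0)
        lams[chrom] = lam
    return WindowPvalues(width=counts.width, pvalue=pvals, score=scores, lam=lams)


def call_peaks(pvals: WindowPvalues, alpha: float = 0.001) -> PeakSet:
    """Return every window with p < alpha as a single-window peak.

    Adjacent significant windows are deliberately not merged: peak counts
    and peak-set overlaps are defined at window granularity throughout.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    rows = []
    for chrom in pvals.chroms:
        p = pvals.pvalue[chrom]
        hits = np.flatnonzero(p < alpha)
        for w in hits:
            rows.append((chrom, int(w) * pvals.width, (int(w) + 1) * pvals.width,
                         float(pvals.score[chrom][w])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return PeakSet(intervals=IntervalSet(df), alpha=alpha, width=pvals.width)


@dataclass
class BlockHistogram:
    """Average peak significance per 5-kb window and its score histogram.

    ``control`` repeats the computation after uniformly shuffling the peak
    scores across grid positions (per chromosome, same score multiset), the
    random-peak control against which genuine block structure shows up as
    excess mass at both ends of the histogram.
    """

    block_width: int
    values: dict[str, np.ndarray]
    control_values: dict[str, np.ndarray]
    bin_edges: np.ndarray
    counts: np.ndarray
    control_counts: np.ndarray

    def all_values(self, control: bool = False) -> np.ndarray:
        src = self.control_values if control else self.values
        return np.concatenate([src[c] for c in sorted(src)]) if src else np.array([])


def _masked_scores(pvals: WindowPvalues, peaks: PeakSet) -> dict[str, np.ndarray]:
    """Score vectors keeping peak windows only (non-peak windows contribute 0)."""
    out = {}
    for chrom in pvals.chroms:
        s = np.zeros_like(pvals.score[chrom])
        if chrom in set(peaks.records["chrom"]):
            idx = peaks.window_index(chrom)
            idx = idx[idx < len(s)]
            s[idx] = pvals.score[chrom][idx]
        out[chrom] = s
    return out


def block_profile(pvals: WindowPvalues, peaks: PeakSet, block_width: int = 5000,
                  shuffle_seed: int = 0, n_bins: int = 40) -> BlockHistogram:
    """Average significance of peaks within non-overlapping 5-kb windows.

    Each block's value is the mean score of its constituent 100-bp windows,
    with non-peak windows contributing score 0; a trailing partial block is
    dropped.  Blocks are tiled from coordinate 0.
    """
    if block_width % pvals.width:
        raise ConfigurationError(
            f"block width {block_width} is not a multiple of window width {pvals.width}"
        )
    per_block = block_width // pvals.width
    rng = np.random.default_rng(shuffle_seed)
    masked = _masked_scores(pvals, peaks)
    values, control = {}, {}
    for chrom in sorted(masked):
        s = masked[chrom]
        n_blocks = len(s) // per_block
        trimmed = s[: n_blocks * per_block]
        values[chrom] = trimmed.reshape(n_blocks, per_block).mean(axis=1) \
            if n_blocks else np.empty(0)
        shuffled = rng.permutation(s)[: n_blocks * per_block]
        control[chrom] = shuffled.reshape(n_blocks, per_block).mean(axis=1) \
            if n_blocks else np.empty(0)
    obs = np.concatenate(list(values.values())) if values else np.array([])
    ctl = np.concatenate(list(control.values())) if control else np.array([])
    hi = max(obs.max(initial=0.0), ctl.max(initial=0.0), 1e-9)
    edges = np.linspace(0.0, hi * (1 + 1e-9), n_bins + 1)
    counts, _ = np.histogram(obs, bins=edges)
    control_counts, _ = np.histogram(ctl, bins=edges)
    return BlockHistogram(block_width=block_width, values=values, control_values=control,
                          bin_edges=edges, counts=counts, control_counts=control_counts)


def promoter_bin_matrix(pvals: WindowPvalues, annotation: GenomeAnnotation,
                        upstream: int = 5500, downstream: int = 2500,
                        bin_width: int = 500) -> pd.DataFrame:
    """Mean window score in fixed bins around each TSS, strand-aware.

    Bins tile [-upstream, +downstream) around the TSS (default 16 bins of
    500 bp spanning -5.5 kb to +2.5 kb).  Column 1 is always the most
    upstream bin: for minus-strand genes the bins run toward higher
    coordinates mirrored, so upstream means upstream of transcription.  Bins
    falling outside the chromosome (or beyond the window grid) are missing
    values, not zeros.  The TSS is snapped down to its containing window.
    """
    if bin_width % pvals.width:
        raise ConfigurationError(
            f"bin width {bin_width} is not a multiple of window width {pvals.width}"
        )
    if (upstream + downstream) % bin_width:
        raise ConfigurationError("promoter span must be a multiple of the bin width")
    n_bins = (upstream + downstream) // bin_width
    per_bin = bin_width // pvals.width
    tss = annotation.tss()
    rows, index = [], []
    for gene in annotation.genes.itertuples():
        chrom = gene.chrom
        if chrom not in pvals.score:
            logger.warning("gene %s: chromosome %s absent from score track; row dropped",
                           gene.gene_id, chrom)
            continue
        s = pvals.score[chrom]
        t = int(tss[gene.gene_id])
        t0 = (t // pvals.width) * pvals.width
        vals = np.full(n_bins, np.nan)
        for b in range(n_bins):
            if gene.strand == "+":
                start = t0 - upstream + b * bin_width
            else:
                start = t0 + upstream - (b + 1) * bin_width
            w0 = start // pvals.width
            if w0 < 0 or w0 + per_bin > len(s):
                continue
            vals[b] = s[w0: w0 + per_bin].mean()
        rows.append(vals)
        index.append(gene.gene_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"),
                        columns=[f"bin{b + 1}" for b in range(n_bins)])
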