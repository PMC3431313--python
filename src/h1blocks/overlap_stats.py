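"""Peak-set comparison and annotation-term enrichment.

Overlap between two interval sets is counted at the element level: an
interval of A is "shared" when it overlaps any interval of B by at least one
base (half-open semantics), or, under identity matching, when an identical
interval exists in B.  Exclusivity (under-overlap, the one-sided alternative
matching a mutual-exclusion claim) is assessed by a permutation null in
which A's intervals are relocated uniformly at random within their own
chromosome, preserving per-chromosome interval counts and lengths; a
circular-shift variant preserves inter-interval spacing instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .genome_io import IntervalSet
from .family_analysis import binomial_enrichment


@dataclass
class OverlapReport:
    """Descriptive and (optionally) inferential overlap summary."""

    n_a: int
    n_b: int
    shared: int
    fraction: float            # shared / |A|
    p: float | None = None     # empirical under-overlap (exclusivity) p
    null_mean: float | None = None
    null_sd: float | None = None
    n_perm: int | None = None
    method: str = "overlap"

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _check_chrom_names(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ca, cb = set(a["chrom"]), set(b["chrom"])
    if ca and cb and not (ca & cb):
        raise ValidationError(
            f"no shared chromosome names between sets: {sorted(ca)} vs {sorted(cb)}"
        )


def _merge(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays, sorted."""
    out = {}
    for chrom, grp in df.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        ms, me = [], []
        for s, e in zip(starts, ends):
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        out[chrom] = (np.asarray(ms), np.asarray(me))
    return out


def _count_shared(starts: np.ndarray, ends: np.ndarray,
                  merged: tuple[np.ndarray, np.ndarray] | None) -> int:
    """Number of query intervals overlapping >= 1 bp of the merged set."""
    if merged is None or len(starts) == 0:
        return 0
    ms, me = merged
    if len(ms) == 0:
        return 0
    # a query [s, e) overlaps block i iff ms[i] < e and me[i] > s; blocks are
    # disjoint and sorted, so locate the first block ending after s.
    idx = np.searchsorted(me, starts, side="right")
    hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < ends)
    return int(hit.sum())


def overlap_fraction(a: IntervalSet, b: IntervalSet,
                     match: str = "overlap") -> OverlapReport:
    """Count intervals of A shared with B and the shared fraction of A.

    ``match="overlap"`` (default): >= 1 bp overlap qualifies.
    ``match="identity"``: only an exactly identical interval in B qualifies.
    """
    if match not in {"overlap", "identity"}:
        raise ConfigurationError(f"match must be 'overlap' or 'identity', got {match!r}")
    da, db = a.records, b.records
    if len(da) and len(db):
        _check_chrom_names(da, db)
    if match == "identity":
        keys_b = set(zip(db["chrom"], db["start"], db["end"]))
        shared = sum((row.chrom, row.start, row.end) in keys_b
                     for row in da.itertuples())
    else:
        merged = _merge(db)
        shared = 0
        for chrom, grp in da.groupby("chrom"):
            shared += _count_shared(grp["start"].to_numpy(), grp["end"].to_numpy(),
                                    merged.get(chrom))
    n_a = len(da)
    return OverlapReport(n_a=n_a, n_b=len(db), shared=shared,
                         fraction=shared / n_a if n_a else 0.0, method=match)


def exclusivity_test(a: IntervalSet, b: IntervalSet, chrom_sizes: dict[str, int],
                     n_perm: int = 1000, seed: int | None = None,
                     mode: str = "relocate") -> OverlapReport:
    """Permutation test for mutual exclusivity (under-overlap) of A and B.

    Null: A's intervals are placed uniformly at random within their own
    chromosome (lengths and per-chromosome counts preserved; relocated
    intervals may overlap each other), or circularly shifted by one random
    per-chromosome offset with ``mode="circular"`` (preserves spacing).
    Empirical p = (1 + #{perm: shared_perm <= shared_obs}) / (n_perm + 1),
    with the add-one correction keeping p positive.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if mode not in {"relocate", "circular"}:
        raise ConfigurationError(f"mode must be 'relocate' or 'circular', got {mode!r}")
    da = a.records
    for row in da.itertuples():
        size = chrom_sizes.get(row.chrom)
        if size is None:
            raise ValidationError(f"interval on unknown chromosome {row.chrom!r}")
        if row.end - row.start > size:
            raise ValidationError(
                f"interval {row.chrom}:{row.start}-{row.end} longer than its chromosome"
            )
    obs = overlap_fraction(a, b).shared
    merged_b = _merge(b.records)
    rng = np.random.default_rng(seed)
    per_chrom = [(chrom, grp["start"].to_numpy(), (grp["end"] - grp["start"]).to_numpy())
                 for chrom, grp in da.groupby("chrom")]
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        shared = 0
        for chrom, starts, lengths in per_chrom:
            size = chrom_sizes[chrom]
            mb = merged_b.get(chrom)
            if mode == "relocate":
                new_starts = rng.integers(0, size - lengths + 1)
                shared += _count_shared(new_starts, new_starts + lengths, mb)
            else:
                # one random circular shift per chromosome; intervals crossing
                # the end wrap around and count if either piece overlaps B
                shift = int(rng.integers(0, size))
                s2 = (starts + shift) % size
                plain = s2 + lengths <= size
                shared += _count_shared(s2[plain], s2[plain] + lengths[plain], mb)
                for s, ln in zip(s2[~plain], lengths[~plain]):
                    hit = _count_shared(np.array([s]), np.array([size]), mb) or \
                        _count_shared(np.array([0]), np.array([s + ln - size]), mb)
                    shared += int(bool(hit))
        null[i] = shared
    p = (1 + int((null <= obs).sum())) / (n_perm + 1)
    n_a = len(da)
    return OverlapReport(n_a=n_a, n_b=len(b.records), shared=obs,
                         fraction=obs / n_a if n_a else 0.0, p=p,
                         null_mean=float(null.mean()), null_sd=float(null.std(ddof=0)),
                         n_perm=n_perm, method=mode)


def term_enrichment(gene_set, term_map: dict[str, set], universe) -> pd.DataFrame:
    """Binomial annotation-term enrichment with Benjamini-Hochberg FDR.

    For each term, k = members of the gene set annotated with the term is
    tested against Binomial(n = |set|, pi = term prevalence in the universe);
    BH step-up adjusted values are reported across all tested terms.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValidationError("gene set must be a subset of the universe")
    n = len(gene_set)
    rows = []
    for term, members in sorted(term_map.items()):
        members = set(members) & universe
        pi = len(members) / len(universe)
        k = len(gene_set & members)
        if pi <= 0:
            continue
        p = 1.0 if pi >= 1 else binomial_enrichment(k, n, pi)
        rows.append(dict(term=term, k=k, n=n, pi=pi, p=p))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "pi", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df
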