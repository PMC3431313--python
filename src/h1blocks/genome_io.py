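"""Reading and writing of the genomic file formats the pipeline touches.

All coordinates are 0-based, half-open internally.  BED and bedGraph are
native to that convention; the TSV gene-table dialect used here declares its
coordinates 0-based as well, so no shifting happens at any file boundary.
Chromosome names are matched as exact strings ("chr1" and "1" are different
chromosomes; a warning is logged when a mismatch looks like a prefix issue).
Files ending in ``.gz`` are read and written transparently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "family_id"]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _warn_on_prefix_mismatch(names_a, names_b, context: str) -> None:
    a, b = set(names_a), set(names_b)
    if not a or not b or (a & b):
        return
    stripped = {n.removeprefix("chr") for n in a} & {n.removeprefix("chr") for n in b}
    if stripped:
        logger.warning(
            "%s: no shared chromosome names but names match after stripping "
            "'chr' prefix; no normalization is applied", context
        )


@dataclass(frozen=True)
class GenomeAnnotation:
    """Gene annotation over a genome with known chromosome sizes.

    ``genes`` holds one row per gene with columns chrom, start, end, strand,
    gene_id and (optionally null) family_id, sorted by (chrom, start).
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom!r} has nonpositive length {size}")
        df = self.genes
        missing = [c for c in GENE_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ValidationError(f"gene table lacks columns {missing}")
        if "family_id" not in df.columns:
            df = df.assign(family_id=pd.NA)
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValidationError(f"duplicate gene_id(s): {sorted(set(dups))}")
        bad_strand = set(df["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValidationError(f"invalid strand value(s): {sorted(bad_strand)}")
        for row in df.itertuples():
            size = self.chrom_sizes.get(row.chrom)
            if size is None:
                raise ValidationError(f"gene {row.gene_id}: unknown chromosome {row.chrom!r}")
            if not (0 <= row.start < row.end <= size):
                raise ValidationError(
                    f"gene {row.gene_id}: coordinates [{row.start}, {row.end}) out of "
                    f"bounds for {row.chrom} (length {size})"
                )
        object.__setattr__(self, "genes", df)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]

    def tss(self) -> pd.Series:
        """Strand-aware transcription start site per gene (indexed by gene_id)."""
        g = self.genes
        pos = np.where(g["strand"].to_numpy() == "+", g["start"], g["end"])
        return pd.Series(pos, index=g["gene_id"].to_numpy(), name="tss")


@dataclass
class IntervalSet:
    """A set of genomic intervals with optional name and score columns."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = self.records
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValidationError(f"interval table lacks column {col!r}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValidationError("intervals must satisfy start < end")
            if (df["start"] < 0).any():
                raise ValidationError("negative interval coordinates")
            if "score" in df.columns and df["score"].isna().any():
                raise ValidationError("NaN interval scores are not allowed")
        self.records = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.records, other.records
        common = [c for c in a.columns if c in b.columns]
        return len(a) == len(b) and a[common].equals(b[common])

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        for row in self.records.itertuples():
            size = chrom_sizes.get(row.chrom)
            if size is None or row.end > size:
                raise ValidationError(
                    f"interval {row.chrom}:{row.start}-{row.end} exceeds genome bounds"
                )

    def chroms(self) -> list[str]:
        return sorted(self.records["chrom"].unique())


@dataclass
class WindowTrack:
    """Per-chromosome count (or score) vectors on a fixed window grid.

    Vector length for a chromosome of length L is floor(L / width): the final
    partial window is dropped, and that convention is recorded here so every
    consumer sees the same grid.
    """

    width: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"window width must be positive, got {self.width}")
        self.data = {c: np.asarray(v) for c, v in self.data.items()}

    def n_windows(self, chrom: str) -> int:
        return len(self.data[chrom])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def concatenated(self) -> np.ndarray:
        """All windows in sorted chromosome order as one vector."""
        return np.concatenate([self.data[c] for c in sorted(self.data)]) \
            if self.data else np.array([])


def load_annotation(path: str | Path, format: str = "tsv",
                    chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Load a gene annotation from a TSV gene table or a BED6 file.

    The TSV dialect has a header line and columns chrom, start, end, strand,
    gene_id and optionally family_id, 0-based half-open.  BED6 carries the
    gene id in the name column.  Duplicate gene ids and malformed lines are
    rejected with the offending line numbers.
    """
    if format not in {"tsv", "bed"}:
        raise ValidationError(f"unknown annotation format {format!r}")
    rows: list[dict] = []
    seen: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "tsv":
                    if lineno == 1 and fields[0] == "chrom":
                        continue
                    chrom, start, end, strand, gene_id = fields[:5]
                    family = fields[5] if len(fields) > 5 and fields[5] not in ("", ".") else None
                else:
                    chrom, start, end, gene_id = fields[:4]
                    strand = fields[5] if len(fields) > 5 else "+"
                    family = None
                start_i, end_i = int(start), int(end)
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if gene_id in seen:
                raise ValidationError(
                    f"{path}: duplicate gene_id {gene_id!r} at lines {seen[gene_id]} and {lineno}"
                )
            seen[gene_id] = lineno
            rows.append(dict(chrom=chrom, start=start_i, end=end_i, strand=strand,
                             gene_id=gene_id, family_id=family))
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["end"].max()) for c, g in genes.groupby("chrom")}
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


def load_track(path: str | Path, width: int = 100, format: str = "bedgraph",
               chrom_sizes: dict[str, int] | None = None) -> WindowTrack:
    """Load a bedGraph (or 4-column TSV) coverage file onto the window grid.

    Every interval must align exactly to the grid (start and end multiples of
    ``width``); a misaligned interval raises :class:`AlignmentError` rather
    than being redistributed.  Values may span several windows.  If
    ``chrom_sizes`` is given, vectors are pre-sized to floor(L/width) and
    zero-filled; otherwise each chromosome extends to its last covered window.
    """
    if format not in {"bedgraph", "tsv"}:
        raise ValidationError(f"unknown track format {format!r}")
    per_chrom: dict[str, dict[int, float]] = {}
    n_lines = 0
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if start % width or end % width or start >= end:
                raise AlignmentError(
                    f"{path}: line {lineno}: interval [{start}, {end}) not aligned to "
                    f"{width}-bp window grid"
                )
            if value < 0:
                raise ValidationError(f"{path}: line {lineno}: negative count {value}")
            n_lines += 1
            store = per_chrom.setdefault(chrom, {})
            for w in range(start // width, end // width):
                store[w] = value
    if n_lines == 0:
        logger.warning("%s: empty track file; returning zero-filled track", path)
    data: dict[str, np.ndarray] = {}
    if chrom_sizes is not None:
        _warn_on_prefix_mismatch(per_chrom, chrom_sizes, str(path))
        for chrom, size in chrom_sizes.items():
            vec = np.zeros(size // width)
            for w, v in per_chrom.get(chrom, {}).items():
                if w < len(vec):
                    vec[w] = v
            data[chrom] = vec
    else:
        for chrom, store in per_chrom.items():
            vec = np.zeros(max(store) + 1)
            for w, v in store.items():
                vec[w] = v
            data[chrom] = vec
    return WindowTrack(width=width, data=data)


def write_track(track: WindowTrack, path: str | Path, sparse: bool = True) -> None:
    """Write a window track as bedGraph; zero windows are omitted when sparse."""
    with _open_text(path, "wt") as out:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            for w, v in enumerate(vec):
                if sparse and v == 0:
                    continue
                start = w * track.width
                out.write(f"{chrom}\t{start}\t{start + track.width}\t{_fmt(v)}\n")


def _fmt(v: float) -> str:
    return f"{int(v)}" if float(v).is_integer() else f"{v:.6g}"


def write_intervals(iset: IntervalSet, path: str | Path, format: str = "bed") -> None:
    """Write an interval set as BED (name/score optional) or bedGraph (score)."""
    if format not in {"bed", "bedgraph"}:
        raise ValidationError(f"unknown interval format {format!r}")
    df = iset.records
    with _open_text(path, "wt") as out:
        for i, row in enumerate(df.itertuples()):
            if format == "bedgraph":
                score = getattr(row, "score", 0.0)
                out.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_fmt(score)}\n")
            else:
                name = getattr(row, "name", None)
                score = getattr(row, "score", None)
                cols = [row.chrom, row.start, row.end]
                if score is not None:
                    cols += [name if name is not None else f"iv{i}", _fmt(float(score))]
                elif name is not None:
                    cols.append(name)
                out.write("\t".join(str(c) for c in cols) + "\n")


def load_intervals(path: str | Path, format: str = "bed") -> IntervalSet:
    """Load a BED (3-6 columns) or bedGraph file into an :class:`IntervalSet`."""
    rows = []
    has_name = has_score = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                rec = dict(chrom=fields[0], start=int(fields[1]), end=int(fields[2]))
                if format == "bedgraph" and len(fields) > 3:
                    rec["score"] = float(fields[3])
                    has_score = True
                elif len(fields) > 3:
                    rec["name"] = fields[3]
                    has_name = True
                    if len(fields) > 4:
                        rec["score"] = float(fields[4])
                        has_score = True
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: malformed line {lineno}: {line!r}") from exc
            rows.append(rec)
    cols = ["chrom", "start", "end"] + (["name"] if has_name else []) + (
        ["score"] if has_score else [])
    return IntervalSet(pd.DataFrame(rows, columns=cols))


def write_gene_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the gene annotation in the package's TSV dialect (0-based)."""
    df = annotation.genes.copy()
    df["family_id"] = df["family_id"].fillna(".")
    with _open_text(path, "wt") as out:
        out.write("\t".join(GENE_COLUMNS) + "\n")
        df.to_csv(out, sep="\t", header=False, index=False)


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome-sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, length = line.split("\t")[:2]
                sizes[name] = int(length)
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: malformed line {lineno}: {line!r}") from exc
    return sizes


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for name in sorted(chrom_sizes):
            out.write(f"{name}\t{chrom_sizes[name]}\n")
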