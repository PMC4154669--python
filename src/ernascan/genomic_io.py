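"""Genomic interval containers, readers/writers, and overlap/coverage primitives.

All coordinates are 0-based half-open (BED convention). Bulk interval data is
held in pandas DataFrames with BED6 columns ``chrom, start, end, name, score,
strand``; read sets additionally carry the library size N (uniquely mapped
reads excluding ribosomal regions), the normalizer used for RPKM.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    """Malformed record in a BED-like file; message carries the line number."""


def _opener(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ReadSet:
    """Uniquely mapped, strand-specific read intervals for one tissue.

    ``library_size`` is N: the number of unique reads excluding those
    overlapping ribosomal-RNA regions.
    """

    reads: pd.DataFrame
    library_size: int = 0
    tissue: str = ""

    def __post_init__(self):
        if self.library_size > len(self.reads):
            raise ValueError("library_size exceeds number of reads")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CoverageTrack:
    """Per-chromosome binned read depth; optionally split by strand."""

    bin_size: int
    data: dict = field(default_factory=dict)  # chrom -> np.ndarray
    by_strand: dict = field(default_factory=dict)  # strand -> {chrom: array}

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))


# ---------------------------------------------------------------------------
# read extension
# ---------------------------------------------------------------------------

def extend_reads(readset: ReadSet, total_length: int,
                 chrom_lengths: dict[str, int]) -> ReadSet:
    """Extend each alignment to ``total_length`` bp in its 3' direction.

    Plus-strand reads keep their start; minus-strand reads keep their end.
    Results are clipped to chromosome bounds. Unstranded reads are an error:
    3' extension is undefined without a strand.
    """
    df = readset.reads
    if len(df) and (~df["strand"].isin(["+", "-"])).any():
        raise ValueError("unstranded read: strand required for 3' extension")
    if len(df) and (df["end"] - df["start"] > total_length).any():
        raise ValueError("total_length shorter than an existing read")
    out = df.copy()
    plus = out["strand"] == "+"
    out.loc[plus, "end"] = out.loc[plus, "start"] + total_length
    out.loc[~plus, "start"] = out.loc[~plus, "end"] - total_length
    out["start"] = out["start"].clip(lower=0)
    lens = out["chrom"].map(chrom_lengths)
    out["end"] = np.minimum(out["end"].to_numpy(), lens.to_numpy())
    return ReadSet(out, library_size=readset.library_size,
                   tissue=readset.tissue)


# ---------------------------------------------------------------------------
# overlap primitives
# ---------------------------------------------------------------------------

def overlap_query(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[int, int]]:
    """All (index_a, index_b) pairs with >=1 bp overlap on the same chromosome.

    Strand-blind; half-open adjacency ([0,10) vs [10,20)) is not overlap.
    """
    pairs: list[tuple[int, int]] = []
    for chrom, bsub in b.groupby("chrom", sort=False):
        tree = IntervalTree()
        for idx, row in bsub.iterrows():
            tree.addi(row["start"], row["end"], idx)
        asub = a[a["chrom"] == chrom]
        for idx, row in asub.iterrows():
            for hit in tree.overlap(row["start"], row["end"]):
                pairs.append((idx, hit.data))
    pairs.sort()
    return pairs


class IntervalCounter:
    """Counts intervals intersecting arbitrary query windows in O(log n).

    Built once from a set of intervals (e.g. extended reads); a query
    [s, e) on a chromosome returns the number of intervals with
    start < e and end > s, i.e. >=1 bp intersection.
    """

    def __init__(self, df: pd.DataFrame):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._starts[chrom] = np.sort(sub["start"].to_numpy())
            self._ends[chrom] = np.sort(sub["end"].to_numpy())

    def count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._starts:
            return 0
        n_started = np.searchsorted(self._starts[chrom], end, side="left")
        n_finished = np.searchsorted(self._ends[chrom], start, side="right")
        return int(n_started - n_finished)

    def count_many(self, chroms: Iterable[str], starts: np.ndarray,
                   ends: np.ndarray) -> np.ndarray:
        chroms = list(chroms)
        out = np.zeros(len(chroms), dtype=int)
        order = pd.Series(range(len(chroms))).groupby(pd.Series(chroms))
        for chrom, idx in order.groups.items():
            idx = np.asarray(idx)
            if chrom not in self._starts:
                continue
            st = np.searchsorted(self._starts[chrom], ends[idx], side="left")
            fi = np.searchsorted(self._ends[chrom], starts[idx], side="right")
            out[idx] = st - fi
        return out


def any_overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean mask over ``query`` rows: True where >=1 bp overlap with subject."""
    counter = IntervalCounter(subject)
    return counter.count_many(query["chrom"], query["start"].to_numpy(),
                              query["end"].to_numpy()) > 0


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def _diff_coverage(sub: pd.DataFrame, length: int, bin_size: int) -> np.ndarray:
    nbins = -(-length // bin_size)
    diff = np.zeros(length + 1, dtype=np.int64)
    np.add.at(diff, sub["start"].to_numpy(), 1)
    np.add.at(diff, sub["end"].to_numpy(), -1)
    depth = np.cumsum(diff[:-1])
    pad = nbins * bin_size - length
    if pad:
        depth = np.concatenate([depth, np.zeros(pad, dtype=np.int64)])
    if bin_size == 1:
        return depth.astype(float)
    return depth.reshape(nbins, bin_size).sum(axis=1) / bin_size


def coverage(readset: ReadSet, chrom_lengths: dict[str, int], bin_size: int = 1,
             strand_mode: str = "combined") -> CoverageTrack:
    """Binned read-depth track; ``by_strand`` tracks sum to the combined one."""
    track = CoverageTrack(bin_size=bin_size)
    df = readset.reads
    for chrom, length in chrom_lengths.items():
        sub = df[df["chrom"] == chrom]
        track.data[chrom] = _diff_coverage(sub, length, bin_size)
    if strand_mode == "by_strand":
        for strand in ("+", "-"):
            per = {}
            for chrom, length in chrom_lengths.items():
                sub = df[(df["chrom"] == chrom) & (df["strand"] == strand)]
                per[chrom] = _diff_coverage(sub, length, bin_size)
            track.by_strand[strand] = per
    return track


# ---------------------------------------------------------------------------
# BED / bedGraph / refFlat I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, ncols: int) -> tuple:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < ncols:
        raise BedParseError(f"line {lineno}: expected >={ncols} fields, "
                            f"got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
    if start < 0 or end <= start:
        raise BedParseError(f"line {lineno}: invalid interval {start}-{end}")
    return fields, start, end


def read_bed(path, ncols: int = 6) -> pd.DataFrame:
    """Read BED (3-6 columns) into a BED6 DataFrame; missing fields defaulted."""
    rows = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields, start, end = _parse_bed_line(line, lineno, min(ncols, 3))
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path, ncols: int = 6) -> None:
    with _opener(path, "wt") as fh:
        for row in df.itertuples(index=False):
            fields = [row.chrom, row.start, row.end]
            if ncols > 3:
                fields.append(row.name)
            if ncols > 4:
                score = row.score
                fields.append(int(score) if float(score).is_integer()
                              else score)
            if ncols > 5:
                fields.append(row.strand)
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_reads_bed(path, tissue: str = "") -> ReadSet:
    """Load a BED6 read file; drop records not flagged unique (score != 1)."""
    df = read_bed(path)
    n_multi = int((df["score"] != 1).sum())
    if n_multi:
        logger.info("dropped %d non-unique reads from %s", n_multi, path)
        df = df[df["score"] == 1].reset_index(drop=True)
    return ReadSet(df, library_size=len(df), tissue=tissue)


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields, start, end = _parse_bed_line(line, lineno, 4)
            rows.append((fields[0], start, end, float(fields[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    for chrom, sub in df.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise BedParseError(f"overlapping bedGraph intervals on {chrom}")
    return df


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode a coverage track; values fixed at 6 decimals."""
    with _opener(path, "wt") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            bs = track.bin_size
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{v:.6f}\n")


def bedgraph_to_track(df: pd.DataFrame, chrom_lengths: dict[str, int],
                      bin_size: int = 1) -> CoverageTrack:
    """Expand a bedGraph DataFrame to a dense per-bin CoverageTrack."""
    track = CoverageTrack(bin_size=bin_size)
    for chrom, length in chrom_lengths.items():
        nbins = -(-length // bin_size)
        arr = np.zeros(nbins * bin_size, dtype=float)
        for row in df[df["chrom"] == chrom].itertuples(index=False):
            arr[row.start:min(row.end, length)] = row.value
        if bin_size == 1:
            track.data[chrom] = arr
        else:
            track.data[chrom] = arr.reshape(nbins, bin_size).mean(axis=1)
    return track


REFFLAT_COLUMNS = ["gene_name", "tx_name", "chrom", "strand", "tx_start",
                   "tx_end", "cds_start", "cds_end", "exon_count",
                   "exon_starts", "exon_ends"]


def read_refflat(path) -> pd.DataFrame:
    """refFlat-like 11-column gene table; exon lists comma-separated."""
    rows = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise BedParseError(f"line {lineno}: expected 11 fields")
            try:
                rec = (fields[0], fields[1], fields[2], fields[3],
                       int(fields[4]), int(fields[5]), int(fields[6]),
                       int(fields[7]), int(fields[8]), fields[9], fields[10])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: bad integer field") from exc
            rows.append(rec)
    return pd.DataFrame(rows, columns=REFFLAT_COLUMNS)


def write_refflat(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=REFFLAT_COLUMNS)


def exon_intervals(gene_row) -> list[tuple[int, int]]:
    starts = [int(x) for x in str(gene_row.exon_starts).rstrip(",").split(",")]
    ends = [int(x) for x in str(gene_row.exon_ends).rstrip(",").split(",")]
    return list(zip(starts, ends))


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping (start, end) pairs on one chromosome."""
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
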