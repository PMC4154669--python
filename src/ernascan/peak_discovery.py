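"""De novo sliding-window discovery of intergenic transcribed regions.

A fixed-width window slides along each chromosome in constant steps; every
window position holding at least ``min_reads`` extended reads (strand-agnostic)
qualifies, and overlapping or abutting qualifying windows merge into maximal
enriched regions. Regions intersecting any annotated interval (genes, mRNAs,
ESTs, rRNA) are then discarded, leaving intergenic candidates. A saturation
analysis re-runs the scan on nested read subsamples to show how discovery
scales with sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import IntervalCounter, ReadSet, any_overlap_mask

logger = logging.getLogger(__name__)

REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                  "read_count", "peak_center"]


@dataclass
class ScanParams:
    window: int = 500
    step: int = 50
    min_reads: int = 10

    def __post_init__(self):
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def _peak_center(sub: pd.DataFrame, start: int, end: int) -> int:
    """Leftmost position of maximum combined read depth within [start, end)."""
    diff = np.zeros(end - start + 1, dtype=np.int64)
    s = np.clip(sub["start"].to_numpy() - start, 0, end - start)
    e = np.clip(sub["end"].to_numpy() - start, 0, end - start)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    depth = np.cumsum(diff[:-1])
    return start + int(np.argmax(depth))


def sliding_window_scan(readset: ReadSet, chrom_lengths: dict[str, int],
                        params: ScanParams | None = None) -> pd.DataFrame:
    """Scan for read-enriched regions; returns a region table.

    Counting is the number of extended reads intersecting each window (not
    base coverage), without regard to strand. The result is invariant to
    read input order.
    """
    params = params or ScanParams()
    df = readset.reads
    counter = IntervalCounter(df)
    regions = []
    for chrom, length in chrom_lengths.items():
        sub = df[df["chrom"] == chrom]
        if not len(sub):
            continue
        starts = np.arange(0, max(1, length - params.window + 1), params.step)
        ends = np.minimum(starts + params.window, length)
        counts = counter.count_many([chrom] * len(starts), starts, ends)
        ok = counts >= params.min_reads
        if not ok.any():
            continue
        # merge overlapping/abutting qualifying windows into maximal regions
        qs, qe = starts[ok], ends[ok]
        breaks = np.flatnonzero(qs[1:] > qe[:-1]) + 1
        for block_s, block_e in zip(np.split(qs, breaks), np.split(qe, breaks)):
            rs, re = int(block_s[0]), int(block_e[-1])
            hit = sub[(sub["start"] < re) & (sub["end"] > rs)]
            regions.append((chrom, rs, re, "", 0.0, ".", len(hit),
                            _peak_center(hit, rs, re)))
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    out = out.sort_values(["chrom", "start"], kind="mergesort",
                          ignore_index=True)
    out["name"] = [f"region{i:05d}" for i in range(len(out))]
    return out


def filter_annotated(regions: pd.DataFrame,
                     exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop regions with >=1 bp overlap with any annotated interval."""
    if not len(regions):
        return regions.copy()
    mask = any_overlap_mask(regions, exclusions)
    logger.info("annotation filter removed %d of %d regions",
                int(mask.sum()), len(regions))
    return regions[~mask].reset_index(drop=True)


def merge_region_sets(per_tissue: dict[str, pd.DataFrame],
                      reads: dict[str, ReadSet],
                      chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Union of the tissues' enriched regions, merged where overlapping.

    Per-tissue read counts are recomputed on the merged intervals and the
    peak center is recalculated from combined coverage over both tissues.
    """
    all_regions = pd.concat(per_tissue.values(), ignore_index=True)
    if not len(all_regions):
        out = all_regions[["chrom", "start", "end", "name", "score",
                           "strand", "peak_center"]].copy()
        for t in reads:
            out[f"count_{t}"] = pd.Series(dtype=int)
        return out
    merged_rows = []
    for chrom, sub in all_regions.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged_rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged_rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    out["name"] = [f"tstr_cand{i:05d}" for i in range(len(out))]
    out["score"] = 0.0
    out["strand"] = "."
    combined = pd.concat([rs.reads for rs in reads.values()],
                         ignore_index=True)
    for tissue, rs in reads.items():
        counter = IntervalCounter(rs.reads)
        out[f"count_{tissue}"] = counter.count_many(
            out["chrom"], out["start"].to_numpy(), out["end"].to_numpy())
    centers = []
    for row in out.itertuples(index=False):
        hit = combined[(combined["chrom"] == row.chrom)
                       & (combined["start"] < row.end)
                       & (combined["end"] > row.start)]
        centers.append(_peak_center(hit, row.start, row.end))
    out["peak_center"] = centers
    return out


def saturation_analysis(readset: ReadSet, chrom_lengths: dict[str, int],
                        exclusions: pd.DataFrame, fractions: list[float],
                        seed: int, params: ScanParams | None = None,
                        nested: bool = True) -> pd.DataFrame:
    """Region counts from random read subsamples of increasing size.

    With ``nested=True`` subsamples are nested (each fraction's reads contain
    the smaller fractions'), which makes the region count deterministically
    non-decreasing in the fraction.
    """
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    fractions = sorted(fractions)
    rng = np.random.default_rng(seed)
    n = len(readset.reads)
    order = rng.permutation(n)
    rows = []
    for frac in fractions:
        k = int(round(frac * n))
        idx = order[:k] if nested else rng.permutation(n)[:k]
        sub = readset.reads.iloc[np.sort(idx)].reset_index(drop=True)
        subset = ReadSet(sub, library_size=len(sub), tissue=readset.tissue)
        regions = filter_annotated(
            sliding_window_scan(subset, chrom_lengths, params), exclusions)
        rows.append((frac, k, len(regions)))
    return pd.DataFrame(rows, columns=["fraction", "n_reads", "n_regions"])
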