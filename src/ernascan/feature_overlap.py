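"""Overlap of TSTRs with enhancer-associated features and enrichment tests.

Each TSTR is summarized in a 1 kb window around its peak center: the score of
the most constrained overlapping phastCons element, overlap with CAGE-derived
candidate TSSs (peak midpoint extended 1 kb each side), and classification as
p300- and/or H3K27ac-enriched when the window's relative ChIP coverage meets
or exceeds the 95th percentile of background coverage estimated across 1 Mb
of sequence. Class-level summaries and Fisher's exact tests quantify the
association between transcription and enhancer marks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CoverageTrack, IntervalCounter

logger = logging.getLogger(__name__)

FEATURE_WINDOW = 1_000  # bp around the peak center
CLASS_ORDER = ["none", "k27ac_only", "p300_only", "both"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def _center_windows(tstrs: pd.DataFrame, window: int) -> tuple:
    centers = tstrs["peak_center"].to_numpy()
    half = window // 2
    return np.maximum(centers - half, 0), centers + half


def conservation_score(tstrs: pd.DataFrame, phastcons: pd.DataFrame,
                       window: int = FEATURE_WINDOW) -> pd.DataFrame:
    """Max score of phastCons elements intersecting each center window.

    Adds ``cons_score`` (NaN where nothing overlaps) and a boolean
    ``conserved`` flag; an element touching the window by a single base
    counts.
    """
    out = tstrs.copy()
    ws, we = _center_windows(out, window)
    scores = np.full(len(out), np.nan)
    for chrom, sub in phastcons.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["score"].to_numpy(dtype=float)
        mask = (out["chrom"] == chrom).to_numpy()
        for i in np.flatnonzero(mask):
            hit = (starts < we[i]) & (ends > ws[i])
            if hit.any():
                scores[i] = max(np.nanmax(vals[hit]),
                                scores[i] if not np.isnan(scores[i])
                                else -np.inf)
    out["cons_score"] = scores
    out["conserved"] = ~np.isnan(scores)
    return out


def cage_overlap(tstrs: pd.DataFrame, cage_peaks: pd.DataFrame,
                 window: int = FEATURE_WINDOW,
                 extension: int = 1_000) -> pd.DataFrame:
    """Flag TSTRs whose center window hits any CAGE midpoint +- extension."""
    out = tstrs.copy()
    if not len(cage_peaks):
        out["has_cage"] = False
        return out
    mid = (cage_peaks["start"] + cage_peaks["end"]) // 2
    ext = pd.DataFrame({
        "chrom": cage_peaks["chrom"],
        "start": np.maximum(mid - extension, 0),
        "end": mid + extension,
    })
    counter = IntervalCounter(ext)
    ws, we = _center_windows(out, window)
    out["has_cage"] = counter.count_many(out["chrom"], ws, we) > 0
    return out


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p (sum of hypergeometric probabilities not
    exceeding the observed table's). Degenerate margins give p=1."""
    arr = [[table.a, table.b], [table.c, table.d]]
    if (table.a + table.b == 0 or table.c + table.d == 0
            or table.a + table.c == 0 or table.b + table.d == 0):
        logger.warning("degenerate 2x2 margin; Fisher p set to 1")
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def conservation_enrichment(tstr_conserved: np.ndarray,
                            control_conserved: np.ndarray) -> tuple:
    """Fractions and Fisher p for TSTR-vs-control conserved overlap."""
    a = int(tstr_conserved.sum())
    b = int(len(tstr_conserved) - a)
    c = int(control_conserved.sum())
    d = int(len(control_conserved) - c)
    p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    return a / max(a + b, 1), c / max(c + d, 1), p


def _window_mean_coverage(track: CoverageTrack, chrom: str, start: int,
                          end: int) -> float:
    bs = track.bin_size
    arr = track.data.get(chrom)
    if arr is None or end <= start:
        return 0.0
    lo, hi = start // bs, -(-end // bs)
    sel = arr[lo:min(hi, len(arr))]
    return float(sel.mean()) if len(sel) else 0.0


def chip_enrichment_classify(tstrs: pd.DataFrame, chip: dict,
                             input_track: CoverageTrack | None,
                             background_chrom: str,
                             background_span: tuple[int, int],
                             window: int = FEATURE_WINDOW,
                             percentile: float = 95.0,
                             bin_width: int = 1_000,
                             strategy: str = "input_subtracted",
                             min_span: int = 1_000_000) -> pd.DataFrame:
    """Classify TSTRs by p300/H3K27ac enrichment against a 95th-percentile
    background.

    Per mark, a TSTR is enriched when its center-window mean coverage
    (input-subtracted by default; ``strategy="raw"`` skips the correction)
    is >= the ``percentile`` of background coverages computed over
    ``bin_width`` bins tiling ``background_span`` (at least 1 Mb).
    """
    span_len = background_span[1] - background_span[0]
    if span_len < min_span:
        raise ValueError(
            f"background span must cover at least {min_span} bp")
    out = tstrs.copy()
    ws, we = _center_windows(out, window)
    bg_edges = np.arange(background_span[0], background_span[1] + 1,
                         bin_width)

    def relative(track, chrom, s, e):
        v = _window_mean_coverage(track, chrom, s, e)
        if strategy == "input_subtracted" and input_track is not None:
            v -= _window_mean_coverage(input_track, chrom, s, e)
        return v

    for mark, track in chip.items():
        bg = np.array([relative(track, background_chrom, int(s), int(e))
                       for s, e in zip(bg_edges[:-1], bg_edges[1:])])
        cutoff = np.percentile(bg, percentile)
        vals = np.array([relative(track, c, int(s), int(e)) for c, s, e
                         in zip(out["chrom"], ws, we)])
        out[f"enriched_{mark}"] = vals >= cutoff
    p300 = out.get("enriched_p300", pd.Series(False, index=out.index))
    k27 = out.get("enriched_k27ac", pd.Series(False, index=out.index))
    out["chip_class"] = np.select(
        [p300 & k27, p300 & ~k27, ~p300 & k27],
        ["both", "p300_only", "k27ac_only"], default="none")
    return out


def distance_to_nearest_tss(tstrs: pd.DataFrame,
                            genes: pd.DataFrame) -> pd.DataFrame:
    """|peak center - nearest TSS| in bp; the TSS is strand-aware
    (tx_start for + genes, tx_end for - genes). Requires >= 1 gene."""
    if not len(genes):
        raise ValueError("no genes provided")
    tss = np.where(genes["strand"] == "+", genes["tx_start"],
                   genes["tx_end"]).astype(np.int64)
    tss_by_chrom = {c: np.sort(tss[(genes["chrom"] == c).to_numpy()])
                    for c in genes["chrom"].unique()}
    all_tss = np.sort(tss)
    out = tstrs.copy()
    dists = []
    for row in out.itertuples(index=False):
        cands = tss_by_chrom.get(row.chrom)
        if cands is None or not len(cands):
            cands = all_tss  # no gene on this chromosome: nearest anywhere
        i = np.searchsorted(cands, row.peak_center)
        best = min((abs(int(row.peak_center) - int(cands[j]))
                    for j in (i - 1, i) if 0 <= j < len(cands)))
        dists.append(best)
    out["tss_distance"] = dists
    return out


def class_summaries(tstrs: pd.DataFrame, tissues: list[str]) -> pd.DataFrame:
    """Per-enrichment-class medians of expression, conserved fraction, mean
    DI, and median TSS distance; empty classes yield NA rows."""
    rows = []
    for cls in CLASS_ORDER:
        sub = tstrs[tstrs["chip_class"] == cls]
        row = {"chip_class": cls, "n": len(sub)}
        for t in tissues:
            col = f"rpkm_{t}"
            row[f"median_rpkm_{t}"] = (float(sub[col].median())
                                       if len(sub) and col in sub else np.nan)
            dcol = f"di_{t}"
            row[f"mean_di_{t}"] = (float(sub[dcol].mean())
                                   if len(sub) and dcol in sub else np.nan)
        row["conserved_fraction"] = (float(sub["conserved"].mean())
                                     if len(sub) and "conserved" in sub
                                     else np.nan)
        row["median_tss_distance"] = (float(sub["tss_distance"].median())
                                      if len(sub) and "tss_distance" in sub
                                      else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def di_cumulative(tstrs: pd.DataFrame, tissue: str,
                  by_class: bool = True) -> pd.DataFrame:
    """Cumulative distribution of the directionality index per class."""
    rows = []
    groups = (tstrs.groupby("chip_class") if by_class
              else [("all", tstrs)])
    for cls, sub in groups:
        di = np.sort(sub[f"di_{tissue}"].to_numpy())
        for i, v in enumerate(di, 1):
            rows.append((cls, float(v), i / len(di)))
    return pd.DataFrame(rows, columns=["chip_class", "di", "cumulative"])
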