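"""Strand-separated coverage metaprofiles and class-ordered heatmap matrices.

The metaprofile averages read depth in 25 bp bins across a 10 kb window
centered on each anchor (e.g. positions of maximal ChIP coverage), separately
for forward-strand, reverse-strand, and combined reads, scaled per million
mapped reads. Per bin, the mean is trimmed to the 5th-95th percentile band of
the across-anchor distribution; because sequencing-coverage outliers are
one-sided (depth is bounded below by zero and heavy-tailed above), the trim
rounds down at the low tail and up at the high tail, which keeps the retained
anchor set stable when an extreme high-coverage anchor enters the set.

The heatmap matrix lays out input-corrected, depth-normalized ChIP coverage
in 25 bp bins across +-25 kb around each TSTR center, rows grouped by
enrichment class (none, H3K27ac only, p300 only, both) and values centered
and scaled by the matrix-wide mean and SD so datasets are comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genomic_io import CoverageTrack, ReadSet
from .feature_overlap import CLASS_ORDER

logger = logging.getLogger(__name__)

PROFILE_SPAN = 10_000
PROFILE_BIN = 25
HEATMAP_FLANK = 25_000
HEATMAP_BIN = 25


@dataclass
class MetaProfile:
    """Trimmed-mean coverage by distance from anchor, per strand class."""

    bin_offsets: np.ndarray          # bp offset of bin centers from anchor
    sense: np.ndarray
    antisense: np.ndarray
    combined: np.ndarray
    n_anchors: int = 0
    smoothed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.bin_offsets, "sense": self.sense,
                           "antisense": self.antisense,
                           "combined": self.combined})
        for key, vals in self.smoothed.items():
            df[f"smoothed_{key}"] = vals
        return df


def _base_coverage(reads: pd.DataFrame, chrom_lengths: dict[str, int],
                   strand: str | None = None) -> dict[str, np.ndarray]:
    cov = {}
    for chrom, length in chrom_lengths.items():
        sub = reads[reads["chrom"] == chrom]
        if strand is not None:
            sub = sub[sub["strand"] == strand]
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, np.clip(sub["start"].to_numpy(), 0, length), 1)
        np.add.at(diff, np.clip(sub["end"].to_numpy(), 0, length), -1)
        cov[chrom] = np.cumsum(diff[:-1])
    return cov


def _anchor_matrix(cov: dict[str, np.ndarray], anchors: pd.DataFrame,
                   span: int, bin_size: int) -> np.ndarray:
    half = span // 2
    nbins = span // bin_size
    mat = np.zeros((len(anchors), nbins))
    for i, row in enumerate(anchors.itertuples(index=False)):
        arr = cov.get(row.chrom)
        if arr is None:
            continue
        c = int(row.anchor)
        lo, hi = c - half, c + half
        window = np.zeros(span, dtype=float)
        s, e = max(lo, 0), min(hi, len(arr))
        if e > s:
            window[s - lo:e - lo] = arr[s:e]
        mat[i] = window.reshape(nbins, bin_size).mean(axis=1)
    return mat


def trimmed_mean(values: np.ndarray, lower: float = 0.05,
                 upper: float = 0.05) -> float:
    """Rank-based trimmed mean: drop floor(lower*n) smallest and
    ceil(upper*n) largest values."""
    n = len(values)
    lo = math.floor(lower * n)
    hi = n - (math.ceil(upper * n) if upper * n >= 1 else 0)
    if hi <= lo:
        return float(np.mean(values))
    return float(np.mean(np.sort(values, kind="stable")[lo:hi]))


def metaprofile(anchors: pd.DataFrame, readset: ReadSet,
                chrom_lengths: dict[str, int], span: int = PROFILE_SPAN,
                bin_size: int = PROFILE_BIN,
                trim: tuple[float, float] = (0.05, 0.05)) -> MetaProfile:
    """Per-bin 5th-95th trimmed-mean coverage around anchors, per strand.

    ``anchors`` needs columns ``chrom`` and ``anchor`` (the bp position to
    center on). Values are scaled per million mapped reads of the library.
    """
    if not len(anchors):
        raise ValueError("need at least one anchor")
    if len(anchors) < 20:
        logger.warning("only %d anchors: percentile trimming is unstable",
                       len(anchors))
    scale = 1e6 / readset.library_size if readset.library_size else 1.0
    profiles = {}
    for key, strand in (("sense", "+"), ("antisense", "-"),
                        ("combined", None)):
        cov = _base_coverage(readset.reads, chrom_lengths, strand)
        mat = _anchor_matrix(cov, anchors, span, bin_size)
        profiles[key] = np.array(
            [trimmed_mean(mat[:, j], *trim) for j in range(mat.shape[1])]
        ) * scale
    nbins = span // bin_size
    offsets = (np.arange(nbins) + 0.5) * bin_size - span / 2
    return MetaProfile(bin_offsets=offsets, sense=profiles["sense"],
                       antisense=profiles["antisense"],
                       combined=profiles["combined"],
                       n_anchors=len(anchors))


def loess_smooth(values: np.ndarray, span: float = 0.1) -> np.ndarray:
    """Locally weighted regression over bin index; reproduces constants and
    straight lines exactly."""
    values = np.asarray(values, dtype=float)
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if span * len(values) < 3:
        raise ValueError("span too small for a local fit")
    x = np.arange(len(values), dtype=float)
    return lowess(values, x, frac=span, it=0, return_sorted=False)


def smooth_profile(profile: MetaProfile, span: float = 0.1) -> MetaProfile:
    for key in ("sense", "antisense", "combined"):
        profile.smoothed[key] = loess_smooth(getattr(profile, key), span)
    return profile


def anchors_from_chip_peaks(peaks: pd.DataFrame, chip: CoverageTrack
                            ) -> pd.DataFrame:
    """Anchor each peak at its maximum ChIP coverage (leftmost on ties)."""
    rows = []
    bs = chip.bin_size
    for row in peaks.itertuples(index=False):
        arr = chip.data.get(row.chrom)
        if arr is None:
            continue
        lo, hi = row.start // bs, max(row.start // bs + 1, -(-row.end // bs))
        sel = arr[lo:min(hi, len(arr))]
        best = lo + int(np.argmax(sel)) if len(sel) else lo
        rows.append((row.chrom, int((best + 0.5) * bs)))
    return pd.DataFrame(rows, columns=["chrom", "anchor"])


def _track_value_at(track: CoverageTrack, chrom: str, pos: int) -> float:
    arr = track.data.get(chrom)
    if arr is None:
        return 0.0
    i = pos // track.bin_size
    if 0 <= i < len(arr):
        return float(arr[i])
    return 0.0


def heatmap_matrix(tstrs: pd.DataFrame, chip: CoverageTrack,
                   input_track: CoverageTrack | None = None,
                   flank: int = HEATMAP_FLANK, bin_size: int = HEATMAP_BIN
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Class-ordered, input-corrected, z-scaled coverage matrix around TSTRs.

    Returns the matrix (rows follow CLASS_ORDER) and a row-index frame with
    TSTR names and classes. Both tracks are normalized to mean 1 genome-wide
    before the input subtraction; the final matrix is centered and scaled by
    its overall mean and SD (all zeros, with a warning, if the SD is 0).
    """
    order = []
    for cls in CLASS_ORDER:
        order.extend(tstrs.index[tstrs["chip_class"] == cls].tolist())
    sub = tstrs.loc[order]
    nbins = 2 * flank // bin_size

    def norm_factor(track):
        total = track.total()
        nbin = sum(len(a) for a in track.data.values())
        mean = total / nbin if nbin else 0.0
        return 1.0 / mean if mean else 1.0

    f_chip = norm_factor(chip)
    f_inp = norm_factor(input_track) if input_track is not None else 0.0
    mat = np.zeros((len(sub), nbins))
    for i, row in enumerate(sub.itertuples(index=False)):
        c = int(row.peak_center)
        for j in range(nbins):
            pos = c - flank + j * bin_size + bin_size // 2
            v = _track_value_at(chip, row.chrom, pos) * f_chip
            if input_track is not None:
                v -= _track_value_at(input_track, row.chrom, pos) * f_inp
            mat[i, j] = v
    sd = mat.std()
    if sd == 0:
        logger.warning("constant heatmap matrix; returning zeros")
        mat = np.zeros_like(mat)
    else:
        mat = (mat - mat.mean()) / sd
    index = sub[["name", "chip_class"]].reset_index(drop=True)
    return mat, index
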