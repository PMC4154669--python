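"""Differential-expression statistics for intergenic transcribed regions.

The core test contrasts the proportion of each tissue's library falling in a
region's 2 kb center window: with n_A reads of N_A library reads in tissue A
and n_B of N_B in tissue B,

    z = (p_A - p_B) / sqrt(p0 (1 - p0) (1/N_A + 1/N_B)),
    p_t = n_t / N_t,  p0 = (n_A + n_B) / (N_A + N_B),

with a two-sided normal p-value. Regions significant at ``alpha`` are
assigned to the tissue with the higher proportion (tissue-specifically
transcribed regions, TSTRs). Companion quantities: RPKM with an optional
2^-9 visualization floor, the tissue-specificity index (s-u)/(s+u), the
strand directionality index |f-r|/(f+r), zero-substituted fold changes for
validated enhancers, catalog concordance, an exact binomial concordance
test, and seeded selection of qPCR validation candidates from the top 30%
of |z|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import IntervalCounter, ReadSet

logger = logging.getLogger(__name__)

RPKM_FLOOR = 2.0 ** -9
EXPRESSION_WINDOW = 2_000  # bp, centered on the region's peak


@dataclass(frozen=True)
class RegionCounts:
    """Window read counts n and library sizes N for the two tissues."""

    n_a: int
    n_b: int
    big_n_a: int
    big_n_b: int

    def __post_init__(self):
        if not (0 <= self.n_a <= self.big_n_a
                and 0 <= self.n_b <= self.big_n_b):
            raise ValueError("require 0 <= n <= N for both tissues")


@dataclass(frozen=True)
class DiffResult:
    p_hat_a: float
    p_hat_b: float
    p0: float
    z: float
    p: float


def two_proportion_z(counts: RegionCounts) -> DiffResult:
    """Two-proportion z-test on window read counts vs library sizes.

    The squared statistic equals the Pearson chi-square of the corresponding
    2x2 table. Degenerate pooled proportions (0 or 1) give z=0, p=1: no
    evidence of a difference when nothing (or everything) is observed.
    """
    if counts.big_n_a <= 0 or counts.big_n_b <= 0:
        raise ValueError("library sizes must be positive")
    pa = counts.n_a / counts.big_n_a
    pb = counts.n_b / counts.big_n_b
    p0 = (counts.n_a + counts.n_b) / (counts.big_n_a + counts.big_n_b)
    if p0 <= 0.0 or p0 >= 1.0:
        return DiffResult(pa, pb, p0, 0.0, 1.0)
    se = math.sqrt(p0 * (1.0 - p0)
                   * (1.0 / counts.big_n_a + 1.0 / counts.big_n_b))
    z = (pa - pb) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return DiffResult(pa, pb, p0, z, min(p, 1.0))


def two_proportion_z_arrays(n_a, n_b, big_n_a: int, big_n_b: int):
    """Vectorized z and two-sided p over arrays of window counts."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    pa = n_a / big_n_a
    pb = n_b / big_n_b
    p0 = (n_a + n_b) / (big_n_a + big_n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(p0 * (1 - p0) * (1 / big_n_a + 1 / big_n_b))
        z = np.where((p0 > 0) & (p0 < 1), (pa - pb) / se, 0.0)
    p = np.minimum(2 * stats.norm.sf(np.abs(z)), 1.0)
    p = np.where((p0 > 0) & (p0 < 1), p, 1.0)
    return z, p


def rpkm(count: float, region_length: int, library_size: int,
         visualization_floor: bool = False) -> float:
    """Reads per kilobase per million mapped (library excludes rRNA reads)."""
    if region_length <= 0 or library_size <= 0:
        raise ValueError("region length and library size must be positive")
    value = count / (region_length / 1_000.0) / (library_size / 1e6)
    if visualization_floor and value < RPKM_FLOOR:
        return RPKM_FLOOR
    return value


def specificity_index(s: float, u: float) -> float:
    """(s - u)/(s + u): 1 = exclusive to the matching tissue, -1 = opposite."""
    if s < 0 or u < 0:
        raise ValueError("expression values must be non-negative")
    if s + u == 0:
        logger.warning("specificity index undefined at s=u=0; returning 0")
        return 0.0
    return (s - u) / (s + u)


def directionality_index(f: float, r: float) -> float:
    """|f - r|/(f + r): 0 = balanced bidirectional, 1 = fully unidirectional."""
    if f < 0 or r < 0:
        raise ValueError("strand counts must be non-negative")
    if f + r == 0:
        logger.warning("directionality index undefined at f=r=0; returning 0")
        return 0.0
    return abs(f - r) / (f + r)


def window_counts(regions: pd.DataFrame, readsets: dict[str, ReadSet],
                  window: int = EXPRESSION_WINDOW,
                  by_strand: bool = False) -> pd.DataFrame:
    """Extended reads intersecting each region's ``window`` bp center window.

    Windows are centered on ``peak_center``; counts are per tissue and,
    optionally, per strand (for directionality).
    """
    out = regions.copy()
    half = window // 2
    ws = np.maximum(out["peak_center"].to_numpy() - half, 0)
    we = out["peak_center"].to_numpy() + half
    out["win_start"], out["win_end"] = ws, we
    for tissue, rs in readsets.items():
        counter = IntervalCounter(rs.reads)
        out[f"n_{tissue}"] = counter.count_many(out["chrom"], ws, we)
        if by_strand:
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                sub = rs.reads[rs.reads["strand"] == strand]
                c = IntervalCounter(sub)
                out[f"n_{tissue}_{tag}"] = c.count_many(out["chrom"], ws, we)
    return out


def call_tstrs(regions: pd.DataFrame, readsets: dict[str, ReadSet],
               alpha: float = 0.01, window: int = EXPRESSION_WINDOW
               ) -> pd.DataFrame:
    """Score every candidate region and assign significant ones to a tissue.

    Adds z, p, per-tissue RPKM, specificity and directionality indices, and a
    ``tissue`` column holding the winning tissue for p < alpha (strict) or
    "none" for sub-threshold regions (the grey class of the dot plots).
    """
    tissues = list(readsets)
    if len(tissues) != 2:
        raise ValueError("TSTR calling requires exactly two tissues")
    ta, tb = tissues
    na_lib, nb_lib = readsets[ta].library_size, readsets[tb].library_size
    out = window_counts(regions, readsets, window=window, by_strand=True)
    z, p = two_proportion_z_arrays(out[f"n_{ta}"], out[f"n_{tb}"],
                                   na_lib, nb_lib)
    out["z"], out["p"] = z, p
    win_len = out["win_end"] - out["win_start"]
    out[f"rpkm_{ta}"] = [rpkm(n, l, na_lib)
                         for n, l in zip(out[f"n_{ta}"], win_len)]
    out[f"rpkm_{tb}"] = [rpkm(n, l, nb_lib)
                         for n, l in zip(out[f"n_{tb}"], win_len)]
    pa = out[f"n_{ta}"] / na_lib
    pb = out[f"n_{tb}"] / nb_lib
    winner = np.where(pa > pb, ta, tb)
    out["tissue"] = np.where(out["p"] < alpha, winner, "none")
    si = []
    for row, t in zip(out.itertuples(index=False), out["tissue"]):
        s_tissue = t if t != "none" else (ta if getattr(row, f"n_{ta}")
                                          / na_lib >= getattr(row, f"n_{tb}")
                                          / nb_lib else tb)
        u_tissue = tb if s_tissue == ta else ta
        si.append(specificity_index(getattr(row, f"rpkm_{s_tissue}"),
                                    getattr(row, f"rpkm_{u_tissue}")))
    out["si"] = si
    for t in tissues:
        out[f"di_{t}"] = [directionality_index(f, r) for f, r in
                          zip(out[f"n_{t}_fwd"], out[f"n_{t}_rev"])]
    return out


def enhancer_fold_change(count_a: int, count_b: int, big_n_a: int,
                         big_n_b: int) -> tuple[float, float, float]:
    """Fold change and z-test p for a validated enhancer's 2 kb window.

    A zero count in either tissue is set to 1 before the ratio so the fold
    change stays finite; the returned log2 fold change is signed positive
    toward tissue A. The p-value is computed on the raw (pre-substitution)
    counts.
    """
    _, p = two_proportion_z_arrays([count_a], [count_b], big_n_a, big_n_b)
    a = max(count_a, 1)
    b = max(count_b, 1)
    fold = max(a, b) / min(a, b)
    log2fc = math.log2(a / b)
    return fold, log2fc, float(p[0])


def enhancer_volcano(enhancers: pd.DataFrame, readsets: dict[str, ReadSet],
                     window: int = EXPRESSION_WINDOW) -> pd.DataFrame:
    """Per-enhancer fold change / p-value table (volcano-plot data)."""
    tissues = list(readsets)
    ta, tb = tissues
    regions = enhancers.copy()
    regions["peak_center"] = (regions["start"] + regions["end"]) // 2
    counted = window_counts(regions, readsets, window=window)
    rows = []
    for row in counted.itertuples(index=False):
        fold, lfc, p = enhancer_fold_change(
            getattr(row, f"n_{ta}"), getattr(row, f"n_{tb}"),
            readsets[ta].library_size, readsets[tb].library_size)
        rows.append((row.name, row.chrom, row.start, row.end,
                     getattr(row, f"n_{ta}"), getattr(row, f"n_{tb}"),
                     fold, lfc, p))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end",
                                       f"n_{ta}", f"n_{tb}", "fold",
                                       "log2fc", "p"])


def concordance_fraction(enhancers: pd.DataFrame,
                         readsets: dict[str, ReadSet],
                         tissue: str,
                         window: int = EXPRESSION_WINDOW) -> float:
    """Fraction of ``tissue``-labelled enhancers with strictly more reads in
    that tissue's window than in the other tissue's; ties are discordant."""
    if not len(enhancers):
        raise ValueError("empty enhancer catalog")
    sub = enhancers[enhancers["name"] == tissue]
    if not len(sub):
        raise ValueError(f"no enhancers labelled {tissue!r}")
    other = [t for t in readsets if t != tissue][0]
    regions = sub.copy()
    regions["peak_center"] = (regions["start"] + regions["end"]) // 2
    counted = window_counts(regions, readsets, window=window)
    return float((counted[f"n_{tissue}"] > counted[f"n_{other}"]).mean())


def exact_concordance_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value, doubled-smaller-tail convention.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p0).
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("null probability must lie in (0, 1)")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def select_qpcr_candidates(tstrs: pd.DataFrame, m: int,
                           seed: int) -> pd.DataFrame:
    """Seeded random draw of ``m`` regions from the top 30% by |z|."""
    ranked = tstrs.reindex(
        tstrs["z"].abs().sort_values(ascending=False, kind="mergesort").index)
    pool_size = math.ceil(0.3 * len(ranked))
    pool = ranked.head(pool_size)
    if m > pool_size:
        raise ValueError(f"requested {m} candidates from a pool of "
                         f"{pool_size}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool_size, size=m, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)
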