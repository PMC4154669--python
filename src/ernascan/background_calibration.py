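"""Random-region background estimation and read-threshold calibration.

Control regions with the same number and sizes as a query set are placed
uniformly in annotation-free sequence; the fraction meeting each read-count
threshold is recomputed over many iterations (100 by default) and summarized
by a normal fit (mean, SD), against which an observed enhancer fraction gets
an upper-tail p-value. The threshold report contrasts validated enhancers
with this background across thresholds — the calibration behind choosing a
minimum read count for enhancer prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import BED6_COLUMNS, IntervalCounter, ReadSet
from .synthetic_data import GenomeModel

logger = logging.getLogger(__name__)


@dataclass
class BackgroundModel:
    """Mean/SD of control-region threshold fractions across iterations."""

    iterations: int
    window: int
    stats: dict = field(default_factory=dict)  # threshold -> (mean, sd)


def random_control_regions(count: int, sizes: list[int],
                           exclusions: pd.DataFrame, genome: GenomeModel,
                           seed: int, max_tries: int = 1_000) -> pd.DataFrame:
    """Uniformly placed intervals of the given sizes avoiding all exclusions.

    Placement is rejection sampling over (chromosome, start) proportional to
    admissible length; the output size multiset equals the input multiset.
    """
    if count != len(sizes):
        raise ValueError("count must equal len(sizes)")
    rng = np.random.default_rng(seed)
    counter = IntervalCounter(exclusions)
    chroms = [c for c, _ in genome.chromosomes]
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    rows = []
    for i, size in enumerate(sizes):
        for attempt in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            if lengths[chrom] <= size:
                continue
            s = int(rng.integers(0, lengths[chrom] - size))
            if counter.count(chrom, s, s + size) == 0:
                rows.append((chrom, s, s + size, f"ctrl{i:05d}", 0.0, "."))
                break
        else:
            raise RuntimeError(
                f"could not place control region of size {size} after "
                f"{max_tries} tries")
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def _window_fractions(regions: pd.DataFrame, counter: IntervalCounter,
                      thresholds: list[int], window: int) -> dict[int, float]:
    centers = ((regions["start"] + regions["end"]) // 2).to_numpy()
    half = window // 2
    counts = counter.count_many(regions["chrom"],
                                np.maximum(centers - half, 0),
                                centers + half)
    return {t: float((counts >= t).mean()) for t in thresholds}


def background_iterate(readset: ReadSet, region_sizes: list[int],
                       exclusions: pd.DataFrame, genome: GenomeModel,
                       thresholds: list[int], iterations: int = 100,
                       window: int = 1_000, seed: int = 0
                       ) -> BackgroundModel:
    """Fit the background: per iteration, place fresh controls and record the
    fraction meeting each threshold in a ``window`` bp midpoint window."""
    if iterations < 2:
        raise ValueError("need >= 2 iterations for an SD")
    if any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be >= 1")
    rng = np.random.default_rng(seed)
    counter = IntervalCounter(readset.reads)
    fracs = {t: [] for t in thresholds}
    for _ in range(iterations):
        regions = random_control_regions(
            len(region_sizes), region_sizes, exclusions, genome,
            seed=int(rng.integers(2**31)))
        got = _window_fractions(regions, counter, thresholds, window)
        for t in thresholds:
            fracs[t].append(got[t])
    model = BackgroundModel(iterations=iterations, window=window)
    for t in thresholds:
        arr = np.array(fracs[t])
        model.stats[t] = (float(arr.mean()), float(arr.std(ddof=1)))
    return model


def background_pvalue(observed_fraction: float, model: BackgroundModel,
                      threshold: int) -> float:
    """Upper-tail normal p-value of an observed fraction under the fit."""
    mean, sd = model.stats[threshold]
    if sd == 0.0:
        logger.warning("background SD is 0 at threshold %d", threshold)
        return 0.0 if observed_fraction > mean else 1.0
    return float(stats.norm.sf((observed_fraction - mean) / sd))


def threshold_report(enhancers: pd.DataFrame, readset: ReadSet,
                     model: BackgroundModel) -> pd.DataFrame:
    """Enhancer vs background fractions per threshold, with fold ratio and p.

    Enhancer counting uses the same midpoint-window convention (and width) as
    the background model it is compared against.
    """
    if not len(enhancers):
        raise ValueError("empty enhancer catalog")
    counter = IntervalCounter(readset.reads)
    thresholds = sorted(model.stats)
    enh = _window_fractions(enhancers, counter, thresholds, model.window)
    rows = []
    for t in thresholds:
        mean, _sd = model.stats[t]
        ratio = enh[t] / mean if mean > 0 else (0.0 if enh[t] == 0
                                                else float("inf"))
        rows.append((t, enh[t], mean, ratio,
                     background_pvalue(enh[t], model, t)))
    return pd.DataFrame(rows, columns=["threshold", "enhancer_fraction",
                                       "control_fraction", "fold_ratio", "p"])
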