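"""Correlation between TSTR tissue specificity and that of nearby genes.

Each TSTR is paired with its 1st-5th nearest genes (distance = |TSTR peak
center - TSS|, strand-ignored, ties broken by gene id) and with a random
same-chromosome gene as a control. Gene expression is RPKM over the union of
exon intervals per tissue; tissue-specificity indices of genes and TSTRs use
the TSTR's matching tissue as the numerator. For each neighbor rank, pairs
are sorted by gene specificity, grouped into bins of 20, and the Pearson
correlation is computed over the bin means — the binning damps single-gene
noise while preserving the monotone relationship.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import rpkm, specificity_index
from .genomic_io import IntervalCounter, ReadSet, exon_intervals, merge_intervals

logger = logging.getLogger(__name__)


def gene_expression_table(genes: pd.DataFrame, readsets: dict[str, ReadSet]
                          ) -> pd.DataFrame:
    """Per-gene RPKM per tissue over the merged exon union."""
    counters = {t: IntervalCounter(rs.reads) for t, rs in readsets.items()}
    rows = []
    for g in genes.itertuples(index=False):
        merged = merge_intervals(exon_intervals(g))
        exon_len = sum(e - s for s, e in merged)
        tss = g.tx_start if g.strand == "+" else g.tx_end
        row = {"gene": g.gene_name, "chrom": g.chrom, "tss": tss,
               "exon_length": exon_len}
        for t, counter in counters.items():
            count = sum(counter.count(g.chrom, s, e) for s, e in merged)
            row[f"rpkm_{t}"] = rpkm(count, exon_len,
                                    readsets[t].library_size)
        rows.append(row)
    return pd.DataFrame(rows)


def gene_specificity_index(gene_row, matching_tissue: str,
                           other_tissue: str) -> float:
    """Gene SI oriented by the paired TSTR's matching tissue."""
    s = gene_row[f"rpkm_{matching_tissue}"]
    u = gene_row[f"rpkm_{other_tissue}"]
    return specificity_index(s, u)


def rank_nearest_genes(tstr_center: int, chrom: str,
                       gene_table: pd.DataFrame, k_max: int = 5
                       ) -> pd.DataFrame:
    """The k_max nearest genes by |center - TSS|, any strand; ties break on
    gene id (lexicographic)."""
    sub = gene_table[gene_table["chrom"] == chrom].copy()
    sub["distance"] = np.abs(sub["tss"].to_numpy() - tstr_center)
    sub = sub.sort_values(["distance", "gene"], kind="mergesort")
    return sub.head(k_max).reset_index(drop=True)


def build_pairs(tstrs: pd.DataFrame, gene_table: pd.DataFrame,
                tissues: tuple[str, str], k_max: int = 5) -> pd.DataFrame:
    """TSTR-gene pairs for ranks 1..k_max with both specificity indices.

    Only called (tissue-assigned) TSTRs are paired; genes are ranked within
    the TSTR's chromosome (nearest genes "regardless of strand").
    """
    ta, tb = tissues
    rows = []
    for row in tstrs.itertuples(index=False):
        if row.tissue == "none":
            continue
        match = row.tissue
        other = tb if match == ta else ta
        chrom_genes = gene_table[gene_table["chrom"] == row.chrom]
        if not len(chrom_genes):
            logger.warning("no genes on %s; skipping %s", row.chrom, row.name)
            continue
        ranked = rank_nearest_genes(row.peak_center, row.chrom, chrom_genes,
                                    k_max)
        for k, g in enumerate(ranked.itertuples(index=False), 1):
            gsi = specificity_index(getattr(g, f"rpkm_{match}"),
                                    getattr(g, f"rpkm_{other}"))
            rows.append((row.name, row.tissue, row.si, g.gene, gsi, k,
                         int(g.distance)))
    return pd.DataFrame(rows, columns=["tstr", "tissue", "tstr_si", "gene",
                                       "gene_si", "rank", "distance"])


def random_gene_control(tstrs: pd.DataFrame, gene_table: pd.DataFrame,
                        tissues: tuple[str, str], seed: int) -> pd.DataFrame:
    """One uniformly drawn same-chromosome gene per called TSTR (seeded)."""
    ta, tb = tissues
    rng = np.random.default_rng(seed)
    rows = []
    for row in tstrs.itertuples(index=False):
        if row.tissue == "none":
            continue
        chrom_genes = gene_table[gene_table["chrom"] == row.chrom]
        if not len(chrom_genes):
            logger.warning("no genes on %s; skipping %s", row.chrom, row.name)
            continue
        g = chrom_genes.iloc[int(rng.integers(len(chrom_genes)))]
        match = row.tissue
        other = tb if match == ta else ta
        gsi = specificity_index(g[f"rpkm_{match}"], g[f"rpkm_{other}"])
        rows.append((row.name, row.tissue, row.si, g["gene"], gsi, "random",
                     int(abs(g["tss"] - row.peak_center))))
    return pd.DataFrame(rows, columns=["tstr", "tissue", "tstr_si", "gene",
                                       "gene_si", "rank", "distance"])


def bin_and_correlate(pairs: pd.DataFrame, bin_size: int = 20
                      ) -> tuple[float, pd.DataFrame]:
    """Pearson R over bin-mean specificity indices.

    Pairs are sorted by gene SI and cut into consecutive bins of ``bin_size``;
    a final partial bin is kept if it holds at least half a bin, otherwise it
    merges into the previous one. Returns (R, bin-mean table).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    sub = pairs.sort_values(["gene_si", "gene"], kind="mergesort",
                            ignore_index=True)
    n = len(sub)
    n_bins = n // bin_size
    rem = n % bin_size
    if rem >= max(1, bin_size // 2) or n_bins == 0:
        edges = [min(i * bin_size, n) for i in range(n_bins + 2)]
        edges[-1] = n
    else:
        edges = [i * bin_size for i in range(n_bins)] + [n]
    edges = sorted(set(edges))
    if len(edges) < 3:
        raise ValueError("need at least 2 bins to correlate")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        chunk = sub.iloc[lo:hi]
        rows.append((float(chunk["gene_si"].mean()),
                     float(chunk["tstr_si"].mean()), hi - lo))
    bins = pd.DataFrame(rows, columns=["gene_si_mean", "tstr_si_mean", "n"])
    r = float(stats.pearsonr(bins["gene_si_mean"], bins["tstr_si_mean"])[0])
    return r, bins


def rank_correlation_table(pairs: pd.DataFrame, control: pd.DataFrame,
                           bin_size: int = 20,
                           per_tissue: bool = True) -> pd.DataFrame:
    """Pearson R per neighbor rank (and the random control), per tissue."""
    def safe_r(sub):
        try:
            return bin_and_correlate(sub, bin_size)[0]
        except ValueError:
            logger.warning("too few pairs (%d) for %d-gene bins; R omitted",
                           len(sub), bin_size)
            return float("nan")

    rows = []
    groups = (pairs["tissue"].unique().tolist() if per_tissue else ["all"])
    for tissue in groups:
        psub = pairs if tissue == "all" else pairs[pairs["tissue"] == tissue]
        csub = (control if tissue == "all"
                else control[control["tissue"] == tissue])
        for k in sorted(psub["rank"].unique()):
            rows.append((tissue, str(k), safe_r(psub[psub["rank"] == k])))
        if len(csub):
            rows.append((tissue, "random", safe_r(csub)))
    return pd.DataFrame(rows, columns=["tissue", "rank", "pearson_r"])
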