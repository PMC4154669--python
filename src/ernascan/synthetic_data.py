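"""Seeded simulator for two-tissue strand-specific RNA-seq fixtures.

Emulates the statistical structure the analysis assumes: a small genome,
non-overlapping gene models with exonic (and weaker intronic) transcription,
ribosomal-RNA loci that dominate raw read counts but are excluded from the
library size, planted intergenic loci with configurable per-tissue expression
and strand balance, and correlated enhancer-associated feature tracks
(p300/H3K27ac ChIP coverage and peaks, phastCons elements, CAGE tag clusters,
a validated-enhancer catalog). Every planted locus is recorded in a truth
table so downstream stages can be scored for parameter recovery.

All randomness flows from a single integer seed; identical (config, seed)
pairs produce byte-identical output bundles.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (BED6_COLUMNS, CoverageTrack, ReadSet, IntervalCounter,
                         write_bed, write_bedgraph, write_refflat,
                         REFFLAT_COLUMNS)


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple  # of (name, length)

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class PlantedLocus:
    """Ground-truth intergenic locus with per-tissue expression and features."""

    name: str
    chrom: str
    start: int
    end: int
    mean_reads: dict  # tissue -> expected read count at depth 1.0
    sense_fraction: float = 0.5
    has_p300: bool = False
    has_k27ac: bool = False
    conserved: bool = False
    has_cage: bool = False
    is_known_enhancer: bool = False
    active_tissue: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.sense_fraction <= 1.0:
            raise ValueError("sense_fraction must be in [0, 1]")
        if any(m < 0 for m in self.mean_reads.values()):
            raise ValueError("mean read counts must be non-negative")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SimConfig:
    """Study conditions for the two-tissue simulation.

    Defaults model a 2 x 1 Mb genome with 40 genes, two rRNA loci, 100
    tissue-specific planted loci (5-fold expression difference, weaker tissue
    at 30 expected reads) and 100 non-specific loci, under negative-binomial
    count noise. ``noise="poisson"`` gives exact binomial-compatible counts
    for statistical-calibration experiments.
    """

    chromosome_lengths: tuple = (("chr1", 1_000_000), ("chr2", 1_000_000))
    tissues: tuple = ("heart", "limb")
    depth: dict = field(default_factory=lambda: {"heart": 1.0, "limb": 1.0})
    read_length: int = 50

    n_genes: int = 40
    gene_length: int = 8_000
    exons_per_gene: int = 5
    exon_length: int = 200
    exon_reads_per_gene: float = 200.0
    intron_read_fraction: float = 0.1

    n_rrna: int = 2
    rrna_length: int = 5_000
    rrna_reads: float = 5_000.0

    n_specific_loci: int = 100
    n_nonspecific_loci: int = 100
    locus_length: int = 1_000
    specific_high_mean: float = 150.0
    specific_low_mean: float = 30.0
    # optional (lo, hi): draw each specific locus's high mean uniformly, so
    # planted loci span a spectrum of fold changes (needed for analyses that
    # rely on specificity spread, e.g. neighbor correlation)
    specific_high_mean_range: tuple | None = None
    nonspecific_mean: float = 40.0
    sense_fraction: float = 0.5

    p300_prob: float = 0.6
    k27ac_prob: float = 0.7
    conserved_prob_specific: float = 0.7
    conserved_prob_nonspecific: float = 0.28
    cage_prob_specific: float = 0.5
    known_enhancer_prob: float = 0.3
    # some catalog enhancers are active without tissue-biased transcription;
    # they hold catalog concordance near the ~80% seen in vivo
    known_enhancer_prob_nonspecific: float = 0.2

    background_rate: float = 0.003  # genome-wide stray reads per bp
    noise: str = "nb"
    dispersion: float = 0.1

    # couple gene expression to the nearest tissue-specific locus so the
    # neighbor-correlation analysis has signal to recover; the bias decays
    # with distance, mirroring enhancer-target proximity
    gene_si_coupling: float = 0.8
    gene_si_decay: float = 20_000.0

    chip_background_lam: float = 5.0
    chip_peak_height: float = 60.0
    chip_peak_halfwidth: int = 500
    phastcons_background_n: int = 400
    phastcons_length: int = 300
    cage_background_n: int = 50

    min_gap: int = 3_000
    seed: int = 0

    @classmethod
    def correlation_study(cls, **overrides) -> "SimConfig":
        """Conditions for the TSTR/nearest-gene correlation analysis.

        Needs a spectrum of locus specificities (drawn fold changes) and a
        gene-dense genome so a TSTR's nearest gene is usually the gene its
        expression bias is coupled to, mirroring the gene:enhancer ratio of
        real annotations.
        """
        base = dict(
            chromosome_lengths=tuple((f"chr{i}", 1_000_000)
                                     for i in range(1, 5)),
            noise="poisson", specific_high_mean_range=(36, 400),
            n_genes=400, gene_length=4_000, exons_per_gene=3,
            exon_reads_per_gene=300.0, n_specific_loci=120,
            n_nonspecific_loci=24, min_gap=1_500,
            gene_si_coupling=0.9, gene_si_decay=30_000.0)
        base.update(overrides)
        return cls(**base)

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(d < 0 for d in self.depth.values()):
            raise ValueError("depth must be non-negative")
        if self.noise not in ("nb", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class AnnotationSet:
    """Gene models plus rRNA loci; provides the intergenic exclusion set."""

    genes: pd.DataFrame  # refFlat-like
    rrna: pd.DataFrame   # BED6

    def exclusions(self) -> pd.DataFrame:
        """Union of gene spans and rRNA loci, the 'annotated' filter set."""
        gene_iv = self.genes[["chrom", "tx_start", "tx_end", "gene_name"]]
        gene_iv = gene_iv.rename(columns={"tx_start": "start",
                                          "tx_end": "end",
                                          "gene_name": "name"})
        gene_iv = gene_iv.assign(score=0.0, strand=".")
        return pd.concat([gene_iv[BED6_COLUMNS], self.rrna[BED6_COLUMNS]],
                         ignore_index=True)


@dataclass
class FeatureTracks:
    chip_coverage: dict      # mark -> CoverageTrack
    chip_input: CoverageTrack
    chip_peaks: dict         # mark -> BED6 DataFrame
    phastcons: pd.DataFrame  # BED5 (score = conservation)
    cage: pd.DataFrame       # BED6
    enhancers: pd.DataFrame  # BED6, name = active tissue label


@dataclass
class SimBundle:
    config: SimConfig
    genome: GenomeModel
    annotation: AnnotationSet
    loci: list
    readsets: dict           # tissue -> ReadSet
    truth: pd.DataFrame
    tracks: FeatureTracks


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def build_genome(config: SimConfig) -> GenomeModel:
    return GenomeModel(tuple(config.chromosome_lengths))


def _place_items(rng, chrom_len: int, item_lengths: list[int],
                 min_gap: int) -> list[tuple[int, int]]:
    """Lay out non-overlapping intervals with random gaps (stick-breaking)."""
    k = len(item_lengths)
    total = sum(item_lengths)
    slack = chrom_len - total - min_gap * (k + 1)
    if slack < 0:
        raise ValueError("items do not fit on chromosome at requested density")
    # split slack into k+1 random gap increments
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + min_gap
    out, pos = [], 0
    for gap, length in zip(gaps, item_lengths):
        pos += int(gap)
        out.append((pos, pos + length))
        pos += length
    return out


def build_annotation(genome: GenomeModel, config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[AnnotationSet, list]:
    """Place genes, rRNA loci, and planted intergenic loci without overlap.

    Returns the annotation and the list of PlantedLocus; loci are intergenic
    by construction so the downstream annotation filter must retain them all.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config
    nchrom = len(genome.chromosomes)
    tissue_a, tissue_b = cfg.tissues

    # round-robin item assignment across chromosomes
    items = ([("gene", cfg.gene_length)] * cfg.n_genes
             + [("rrna", cfg.rrna_length)] * cfg.n_rrna
             + [("locus", cfg.locus_length)]
               * (cfg.n_specific_loci + cfg.n_nonspecific_loci))
    per_chrom: list[list] = [[] for _ in range(nchrom)]
    for i, item in enumerate(items):
        per_chrom[i % nchrom].append(item)

    gene_rows, rrna_rows, locus_ivs = [], [], []
    for (chrom, length), chrom_items in zip(genome.chromosomes, per_chrom):
        order = rng.permutation(len(chrom_items))
        chrom_items = [chrom_items[i] for i in order]
        placed = _place_items(rng, length, [l for _, l in chrom_items],
                              cfg.min_gap)
        for (kind, _), (s, e) in zip(chrom_items, placed):
            if kind == "gene":
                gene_rows.append((chrom, s, e))
            elif kind == "rrna":
                rrna_rows.append((chrom, s, e))
            else:
                locus_ivs.append((chrom, s, e))

    # gene models: evenly spaced fixed-length exons inside the span
    recs = []
    for gi, (chrom, s, e) in enumerate(gene_rows):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = max(1, cfg.exons_per_gene)
        span = e - s
        step = span // n_ex
        ex_starts = [s + j * step for j in range(n_ex)]
        ex_ends = [min(x + cfg.exon_length, e) for x in ex_starts]
        recs.append((f"gene{gi:04d}", f"gene{gi:04d}.t1", chrom, strand,
                     s, e, s, e, n_ex,
                     ",".join(map(str, ex_starts)) + ",",
                     ",".join(map(str, ex_ends)) + ","))
    genes = pd.DataFrame(recs, columns=REFFLAT_COLUMNS)

    rrna = pd.DataFrame(
        [(c, s, e, f"rRNA{i}", 0.0, "+") for i, (c, s, e) in
         enumerate(rrna_rows)], columns=BED6_COLUMNS)

    # planted loci: specific loci alternate active tissue; features correlate
    # with specificity
    loci: list[PlantedLocus] = []
    order = rng.permutation(len(locus_ivs))
    locus_ivs = [locus_ivs[i] for i in order]
    for li, (chrom, s, e) in enumerate(locus_ivs):
        specific = li < cfg.n_specific_loci
        if specific:
            active = tissue_a if li % 2 == 0 else tissue_b
            other = tissue_b if active == tissue_a else tissue_a
            high = cfg.specific_high_mean
            if cfg.specific_high_mean_range is not None:
                lo, hi = cfg.specific_high_mean_range
                high = float(rng.uniform(lo, hi))
            means = {active: high, other: cfg.specific_low_mean}
            conserved = rng.random() < cfg.conserved_prob_specific
            locus = PlantedLocus(
                name=f"locus{li:04d}", chrom=chrom, start=s, end=e,
                mean_reads=means, sense_fraction=cfg.sense_fraction,
                has_p300=rng.random() < cfg.p300_prob,
                has_k27ac=rng.random() < cfg.k27ac_prob,
                conserved=conserved,
                has_cage=rng.random() < cfg.cage_prob_specific,
                is_known_enhancer=rng.random() < cfg.known_enhancer_prob,
                active_tissue=active)
        else:
            means = {t: cfg.nonspecific_mean for t in cfg.tissues}
            is_enh = rng.random() < cfg.known_enhancer_prob_nonspecific
            label = (cfg.tissues[int(rng.integers(2))] if is_enh else None)
            locus = PlantedLocus(
                name=f"locus{li:04d}", chrom=chrom, start=s, end=e,
                mean_reads=means, sense_fraction=cfg.sense_fraction,
                conserved=rng.random() < cfg.conserved_prob_nonspecific,
                is_known_enhancer=is_enh, active_tissue=label)
        loci.append(locus)

    return AnnotationSet(genes=genes, rrna=rrna), loci


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _draw_count(rng, mean: float, config: SimConfig) -> int:
    if mean <= 0:
        return 0
    if config.noise == "poisson":
        return int(rng.poisson(mean))
    r = 1.0 / config.dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _uniform_reads(rng, chrom, lo, hi, n, read_len, sense_frac):
    if n == 0 or hi - lo < read_len:
        return []
    starts = rng.integers(lo, hi - read_len + 1, size=n)
    strands = np.where(rng.random(n) < sense_frac, "+", "-")
    return [(chrom, int(s), int(s) + read_len, st)
            for s, st in zip(starts, strands)]


def simulate_reads(genome: GenomeModel, annotation: AnnotationSet,
                   loci: list, config: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[dict, pd.DataFrame]:
    """Emit per-tissue ReadSets and the ground-truth table.

    Read counts at planted loci follow the configured noise model around the
    locus mean scaled by tissue depth; strand is Bernoulli(sense_fraction).
    Gene background covers exons densely and introns at a reduced rate; rRNA
    loci receive heavy coverage but are excluded from the library size N.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cfg = config
    rl = cfg.read_length

    # distance-decaying expression bias of each gene toward the active
    # tissue of its nearest tissue-specific planted locus
    def locus_si(l):
        hi, lo = max(l.mean_reads.values()), min(l.mean_reads.values())
        return (hi - lo) / (hi + lo) if hi + lo else 0.0

    specific = [(l.chrom, l.center, l.active_tissue, locus_si(l))
                for l in loci if l.active_tissue is not None
                and len(set(l.mean_reads.values())) > 1]
    gene_bias: dict[str, tuple[str | None, float]] = {}
    for g in annotation.genes.itertuples(index=False):
        tss = g.tx_start if g.strand == "+" else g.tx_end
        best = None
        for chrom, center, tissue, si in specific:
            if chrom != g.chrom:
                continue
            d = abs(center - tss)
            if best is None or d < best[1]:
                best = (tissue, d, si)
        if best is None or cfg.gene_si_coupling == 0:
            gene_bias[g.gene_name] = (None, 0.0)
        else:
            # bias scales with the locus's own specificity and decays with
            # distance, so gene SI tracks nearby-locus SI
            gene_bias[g.gene_name] = (
                best[0],
                cfg.gene_si_coupling * best[2]
                * float(np.exp(-best[1] / cfg.gene_si_decay)))

    readsets = {}
    for tissue in cfg.tissues:
        depth = cfg.depth.get(tissue, 0.0)
        rows = []
        if depth > 0:
            for locus in loci:
                n = _draw_count(rng, locus.mean_reads.get(tissue, 0) * depth,
                                cfg)
                rows += _uniform_reads(rng, locus.chrom, locus.start,
                                       locus.end, n, rl,
                                       locus.sense_fraction)
            for g in annotation.genes.itertuples(index=False):
                bias_tissue, bias = gene_bias[g.gene_name]
                factor = 1.0
                if bias_tissue is not None:
                    factor = 1.0 + bias if tissue == bias_tissue else 1.0 - bias
                mean_exon = cfg.exon_reads_per_gene * factor * depth
                exon_n = int(rng.poisson(mean_exon))
                intron_n = int(rng.poisson(mean_exon
                                           * cfg.intron_read_fraction))
                ex_starts = [int(x) for x in g.exon_starts.rstrip(",").split(",")]
                ex_ends = [int(x) for x in g.exon_ends.rstrip(",").split(",")]
                lens = np.array([e - s for s, e in zip(ex_starts, ex_ends)],
                                dtype=float)
                if exon_n and lens.sum() > 0:
                    which = rng.choice(len(lens), size=exon_n,
                                       p=lens / lens.sum())
                    for w in which:
                        lo, hi = ex_starts[w], ex_ends[w]
                        hi = max(hi, lo + rl)
                        s = int(rng.integers(lo, hi - rl + 1))
                        rows.append((g.chrom, s, s + rl, g.strand))
                sense = 1.0 if g.strand == "+" else 0.0
                rows += _uniform_reads(rng, g.chrom, g.tx_start, g.tx_end,
                                       intron_n, rl, sense)
            for r in annotation.rrna.itertuples(index=False):
                n = int(rng.poisson(cfg.rrna_reads * depth))
                rows += _uniform_reads(rng, r.chrom, r.start, r.end, n, rl,
                                       0.5)
            for chrom, length in genome.chromosomes:
                n = int(rng.poisson(cfg.background_rate * length * depth))
                rows += _uniform_reads(rng, chrom, 0, length, n, rl, 0.5)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        df = df.sort_values(["chrom", "start", "end", "strand"],
                            kind="mergesort").reset_index(drop=True)
        df.insert(3, "name", [f"{tissue}_read{i}" for i in range(len(df))])
        df.insert(4, "score", 1)
        if len(df):
            counter = IntervalCounter(annotation.rrna)
            in_rrna = counter.count_many(df["chrom"], df["start"].to_numpy(),
                                         df["end"].to_numpy()) > 0
            lib_n = int((~in_rrna).sum())
        else:
            lib_n = 0
        readsets[tissue] = ReadSet(df, library_size=lib_n, tissue=tissue)

    truth = truth_table(loci, cfg)
    return readsets, truth


def truth_table(loci: list, config: SimConfig) -> pd.DataFrame:
    rows = []
    for l in loci:
        row = {"name": l.name, "chrom": l.chrom, "start": l.start,
               "end": l.end, "sense_fraction": l.sense_fraction,
               "has_p300": int(l.has_p300), "has_k27ac": int(l.has_k27ac),
               "conserved": int(l.conserved), "has_cage": int(l.has_cage),
               "is_known_enhancer": int(l.is_known_enhancer),
               "active_tissue": l.active_tissue or "none",
               "specific": int(len(set(l.mean_reads.values())) > 1)}
        for t in config.tissues:
            row[f"mean_reads_{t}"] = l.mean_reads.get(t, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature tracks
# ---------------------------------------------------------------------------

def simulate_feature_tracks(loci: list, annotation: AnnotationSet,
                            genome: GenomeModel, config: SimConfig,
                            rng: np.random.Generator | None = None
                            ) -> FeatureTracks:
    """ChIP coverage/peaks, phastCons, CAGE, and enhancer-catalog tracks.

    ChIP coverage is Poisson background plus a triangular enrichment bump at
    loci flagged for the mark; the matched input track is pure background.
    phastCons elements sit at conserved loci plus scattered background
    elements kept clear of planted loci; CAGE peaks likewise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    cfg = config
    lengths = genome.lengths
    bin_size = 25

    def background_track():
        t = CoverageTrack(bin_size=bin_size)
        for chrom, length in genome.chromosomes:
            nbins = -(-length // bin_size)
            t.data[chrom] = rng.poisson(cfg.chip_background_lam,
                                        size=nbins).astype(float)
        return t

    chip_cov, chip_peaks = {}, {}
    for mark, flag in (("p300", "has_p300"), ("k27ac", "has_k27ac")):
        track = background_track()
        peak_rows = []
        for locus in loci:
            if not getattr(locus, flag):
                continue
            c = locus.center
            hw = cfg.chip_peak_halfwidth
            lo_bin = max(0, (c - hw) // bin_size)
            hi_bin = min(len(track.data[locus.chrom]),
                         -(-(c + hw) // bin_size))
            centers = (np.arange(lo_bin, hi_bin) + 0.5) * bin_size
            bump = cfg.chip_peak_height * np.clip(
                1.0 - np.abs(centers - c) / hw, 0.0, None)
            track.data[locus.chrom][lo_bin:hi_bin] += bump
            peak_rows.append((locus.chrom, c - hw, c + hw,
                              f"{mark}_{locus.name}", 0.0, "."))
        chip_cov[mark] = track
        chip_peaks[mark] = pd.DataFrame(peak_rows, columns=BED6_COLUMNS)

    input_track = background_track()

    # admissible background space: away from planted loci (1 kb margin)
    locus_iv = pd.DataFrame(
        [(l.chrom, max(0, l.start - 1_500), l.end + 1_500, l.name, 0.0, ".")
         for l in loci], columns=BED6_COLUMNS)
    locus_counter = IntervalCounter(locus_iv)

    def scatter(n, elem_len):
        rows = []
        chroms = [c for c, _ in genome.chromosomes]
        tries = 0
        while len(rows) < n and tries < 50 * n + 100:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, lengths[chrom] - elem_len))
            if locus_counter.count(chrom, s, s + elem_len) == 0:
                rows.append((chrom, s, s + elem_len))
        return rows

    pc_rows = []
    for l in loci:
        if l.conserved:
            c = l.center
            half = cfg.phastcons_length // 2
            score = float(rng.integers(300, 601))
            pc_rows.append((l.chrom, c - half, c + half,
                            f"pc_{l.name}", score, "."))
    for chrom, s, e in scatter(cfg.phastcons_background_n,
                               cfg.phastcons_length):
        pc_rows.append((chrom, s, e, "pc_bg", float(rng.integers(200, 401)),
                        "."))
    phastcons = pd.DataFrame(pc_rows, columns=BED6_COLUMNS)

    cage_rows = []
    for l in loci:
        if l.has_cage:
            c = l.center
            cage_rows.append((l.chrom, c - 10, c + 10, f"cage_{l.name}",
                              0.0, "+"))
    for chrom, s, e in scatter(cfg.cage_background_n, 20):
        cage_rows.append((chrom, s, e, "cage_bg", 0.0, "+"))
    cage = pd.DataFrame(cage_rows, columns=BED6_COLUMNS)

    enh_rows = [(l.chrom, l.start, l.end, l.active_tissue or "none", 0.0, ".")
                for l in loci if l.is_known_enhancer]
    enhancers = pd.DataFrame(enh_rows, columns=BED6_COLUMNS)

    return FeatureTracks(chip_coverage=chip_cov, chip_input=input_track,
                         chip_peaks=chip_peaks, phastcons=phastcons,
                         cage=cage, enhancers=enhancers)


# ---------------------------------------------------------------------------
# bundle assembly and serialization
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run the full generator with one seed driving every stage."""
    rng = np.random.default_rng(config.seed)
    genome = build_genome(config)
    annotation, loci = build_annotation(genome, config, rng)
    readsets, truth = simulate_reads(genome, annotation, loci, config, rng)
    tracks = simulate_feature_tracks(loci, annotation, genome, config, rng)
    return SimBundle(config=config, genome=genome, annotation=annotation,
                     loci=loci, readsets=readsets, truth=truth, tracks=tracks)


def config_hash(config: SimConfig) -> str:
    text = repr(sorted(asdict(config).items(), key=lambda kv: kv[0]))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Serialize a bundle: BED6 reads, refFlat genes, bedGraph ChIP tracks,
    BED feature files, TSV truth table, and a key-value manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    for tissue, rs in bundle.readsets.items():
        write_bed(rs.reads, outdir / f"reads_{tissue}.bed")
    write_refflat(bundle.annotation.genes, outdir / "genes.refflat")
    write_bed(bundle.annotation.exclusions(), outdir / "exclusions.bed")
    write_bed(bundle.annotation.rrna, outdir / "rrna.bed")
    for mark, track in bundle.tracks.chip_coverage.items():
        write_bedgraph(track, outdir / f"chip_{mark}.bedgraph")
        write_bed(bundle.tracks.chip_peaks[mark],
                  outdir / f"peaks_{mark}.bed")
    write_bedgraph(bundle.tracks.chip_input, outdir / "chip_input.bedgraph")
    write_bed(bundle.tracks.phastcons, outdir / "phastcons.bed")
    write_bed(bundle.tracks.cage, outdir / "cage.bed")
    write_bed(bundle.tracks.enhancers, outdir / "enhancers.bed")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"seed\t{cfg.seed}\n")
        fh.write(f"config_hash\t{config_hash(cfg)}\n")
        fh.write(f"noise\t{cfg.noise}\n")
        for chrom, length in bundle.genome.chromosomes:
            fh.write(f"chrom\t{chrom}\t{length}\n")
        for tissue, rs in bundle.readsets.items():
            fh.write(f"library_size_{tissue}\t{rs.library_size}\n")
            fh.write(f"total_reads_{tissue}\t{len(rs.reads)}\n")
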