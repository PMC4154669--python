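"""End-to-end orchestration: simulate -> call -> difftest -> background ->
overlap -> profile -> correlate -> report, under one configuration and seed.

Every analysis constant is a named configuration field (200 bp read
extension, >=10-read discovery threshold, p<0.01, 2 kb expression and 1 kb
feature windows, 100 background iterations, 25 bp profile bins, 5th-95th
trim, 20-gene correlation bins, +-25 kb heatmap flanks). All randomness is
derived from the single pipeline seed, so a rerun with identical config is
byte-identical. Each stage logs the record counts entering and leaving its
filters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background_calibration as bg
from . import coverage_profiles as cp
from . import diffexpr as dx
from . import feature_overlap as fo
from . import neighbor_correlation as nc
from . import peak_discovery as pk
from . import synthetic_data as sd
from .genomic_io import ReadSet, extend_reads

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "call", "difftest", "background", "overlap",
              "profile", "correlate", "report"]


@dataclass
class PipelineConfig:
    outdir: str = "ernascan_out"
    seed: int = 0
    stages: tuple = tuple(ALL_STAGES)

    sim: sd.SimConfig = field(default_factory=sd.SimConfig)

    extension_length: int = 200
    window: int = 500
    step: int = 50
    min_reads: int = 10
    alpha: float = 0.01
    expression_window: int = 2_000
    feature_window: int = 1_000
    background_iterations: int = 100
    background_thresholds: tuple = (1, 10)
    background_window: int = 1_000
    profile_span: int = 10_000
    profile_bin: int = 25
    loess_span: float = 0.1
    heatmap_flank: int = 25_000
    heatmap_bin: int = 25
    genes_per_bin: int = 20
    k_nearest: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("chromosome_lengths",):
            if key in sim_raw:
                sim_raw[key] = tuple(tuple(x) for x in sim_raw[key])
        for key in ("tissues",):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.sim = sd.SimConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        """Plain-type dict of every analysis parameter; the output directory
        is excluded so reruns into different locations compare equal."""
        def plain(x):
            if isinstance(x, tuple):
                return [plain(v) for v in x]
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            return x
        d = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        d.pop("outdir", None)
        return d

    def hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: sd.SimBundle | None = None
    readsets_ext: dict = field(default_factory=dict)
    regions_per_tissue: dict = field(default_factory=dict)
    candidates: pd.DataFrame | None = None
    tstrs: pd.DataFrame | None = None
    volcano: pd.DataFrame | None = None
    concordance: dict = field(default_factory=dict)
    background_reports: dict = field(default_factory=dict)
    class_summary: pd.DataFrame | None = None
    enrichment: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    heatmaps: dict = field(default_factory=dict)
    correlations: pd.DataFrame | None = None


def run_full(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every enabled stage in order; returns all in-memory artifacts."""
    cfg = config
    result = PipelineResult(config=cfg)
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    stages = set(cfg.stages)

    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    bundle = sd.simulate_bundle(sim_cfg)
    result.bundle = bundle
    lengths = bundle.genome.lengths
    tissues = list(sim_cfg.tissues)
    if write and "simulate" in stages:
        sd.write_bundle(bundle, outdir / "simulated")

    if "call" not in stages:
        return result
    exclusions = bundle.annotation.exclusions()
    for tissue in tissues:
        ext = extend_reads(bundle.readsets[tissue], cfg.extension_length,
                           lengths)
        result.readsets_ext[tissue] = ext
        params = pk.ScanParams(cfg.window, cfg.step, cfg.min_reads)
        raw = pk.sliding_window_scan(ext, lengths, params)
        kept = pk.filter_annotated(raw, exclusions)
        logger.info("%s: %d enriched regions, %d intergenic", tissue,
                    len(raw), len(kept))
        result.regions_per_tissue[tissue] = kept
    result.candidates = pk.merge_region_sets(result.regions_per_tissue,
                                             result.readsets_ext, lengths)

    if "difftest" in stages:
        result.tstrs = dx.call_tstrs(result.candidates, result.readsets_ext,
                                     alpha=cfg.alpha,
                                     window=cfg.expression_window)
        catalog = bundle.tracks.enhancers
        if len(catalog):
            result.volcano = dx.enhancer_volcano(
                catalog, result.readsets_ext, window=cfg.expression_window)
            for tissue in tissues:
                if (catalog["name"] == tissue).any():
                    frac = dx.concordance_fraction(
                        catalog, result.readsets_ext, tissue,
                        window=cfg.expression_window)
                    n = int((catalog["name"] == tissue).sum())
                    k = int(round(frac * n))
                    result.concordance[tissue] = {
                        "fraction": frac, "n": n,
                        "p": dx.exact_concordance_test(k, n, 0.5)}

    if "background" in stages and len(bundle.tracks.enhancers):
        sizes = (bundle.tracks.enhancers["end"]
                 - bundle.tracks.enhancers["start"]).tolist()
        for i, tissue in enumerate(tissues):
            model = bg.background_iterate(
                result.readsets_ext[tissue], sizes, exclusions,
                bundle.genome, list(cfg.background_thresholds),
                iterations=cfg.background_iterations,
                window=cfg.background_window, seed=cfg.seed + 101 + i)
            result.background_reports[tissue] = bg.threshold_report(
                bundle.tracks.enhancers, result.readsets_ext[tissue], model)

    if "overlap" in stages and result.tstrs is not None:
        called = result.tstrs[result.tstrs["tissue"] != "none"].copy()
        called = fo.conservation_score(called, bundle.tracks.phastcons,
                                       window=cfg.feature_window)
        called = fo.cage_overlap(called, bundle.tracks.cage,
                                 window=cfg.feature_window)
        bg_chrom, bg_len = bundle.genome.chromosomes[0]
        called = fo.chip_enrichment_classify(
            called, bundle.tracks.chip_coverage, bundle.tracks.chip_input,
            background_chrom=bg_chrom, background_span=(0, bg_len),
            window=cfg.feature_window, min_span=min(1_000_000, bg_len))
        called = fo.distance_to_nearest_tss(called, bundle.annotation.genes)
        result.tstrs = result.tstrs.merge(
            called[["name", "cons_score", "conserved", "has_cage",
                    "enriched_p300", "enriched_k27ac", "chip_class",
                    "tss_distance"]], on="name", how="left")
        result.class_summary = fo.class_summaries(called, tissues)
        # feature enrichment vs size-matched random controls
        sizes = [cfg.feature_window] * len(called)
        controls = bg.random_control_regions(
            len(called), sizes, exclusions, bundle.genome,
            seed=cfg.seed + 301)
        controls["peak_center"] = (controls["start"] + controls["end"]) // 2
        ctrl_cons = fo.conservation_score(controls, bundle.tracks.phastcons,
                                          window=cfg.feature_window)
        ctrl_cage = fo.cage_overlap(controls, bundle.tracks.cage,
                                    window=cfg.feature_window)
        for key, t_flag, c_flag in (
                ("conservation", called["conserved"], ctrl_cons["conserved"]),
                ("cage", called["has_cage"], ctrl_cage["has_cage"])):
            tf, cf, p = fo.conservation_enrichment(
                t_flag.to_numpy(), c_flag.to_numpy())
            result.enrichment[key] = {"tstr_fraction": tf,
                                      "control_fraction": cf, "p": p}
        heat_input = called

        if "profile" in stages:
            for mark, peaks in bundle.tracks.chip_peaks.items():
                if not len(peaks):
                    continue
                anchors = cp.anchors_from_chip_peaks(
                    peaks, bundle.tracks.chip_coverage[mark])
                for tissue in tissues:
                    prof = cp.metaprofile(anchors,
                                          result.readsets_ext[tissue],
                                          lengths, span=cfg.profile_span,
                                          bin_size=cfg.profile_bin)
                    cp.smooth_profile(prof, span=cfg.loess_span)
                    result.profiles[(mark, tissue)] = prof
                mat, index = cp.heatmap_matrix(
                    heat_input, bundle.tracks.chip_coverage[mark],
                    bundle.tracks.chip_input, flank=cfg.heatmap_flank,
                    bin_size=cfg.heatmap_bin)
                result.heatmaps[mark] = (mat, index)

    if "correlate" in stages and result.tstrs is not None:
        gene_table = nc.gene_expression_table(bundle.annotation.genes,
                                              result.readsets_ext)
        pairs = nc.build_pairs(result.tstrs, gene_table,
                               tuple(tissues), k_max=cfg.k_nearest)
        control = nc.random_gene_control(result.tstrs, gene_table,
                                         tuple(tissues),
                                         seed=cfg.seed + 401)
        if len(pairs):
            result.correlations = nc.rank_correlation_table(
                pairs, control, bin_size=cfg.genes_per_bin)

    if write and "report" in stages:
        write_report(result, outdir)
    return result


def write_report(result: PipelineResult, outdir) -> None:
    """Machine-readable TSVs plus a plain-text summary; all deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    float_fmt = "%.6g"

    def dump(df, name):
        if df is not None and len(df):
            df.to_csv(outdir / name, sep="\t", index=False,
                      float_format=float_fmt)

    dump(result.tstrs, "tstr_table.tsv")
    dump(result.volcano, "enhancer_volcano.tsv")
    dump(result.class_summary, "class_summary.tsv")
    dump(result.correlations, "neighbor_correlation.tsv")
    for tissue, rep in result.background_reports.items():
        dump(rep, f"background_{tissue}.tsv")
    for (mark, tissue), prof in result.profiles.items():
        dump(prof.to_frame(), f"profile_{mark}_{tissue}.tsv")
    for mark, (mat, index) in result.heatmaps.items():
        pd.DataFrame(mat).to_csv(outdir / f"heatmap_{mark}.tsv", sep="\t",
                                 index=False, header=False,
                                 float_format=float_fmt)
        dump(index, f"heatmap_{mark}_index.tsv")

    lines = [f"config_hash\t{cfg.hash()}", f"seed\t{cfg.seed}"]
    if result.tstrs is not None:
        for tissue in result.bundle.config.tissues:
            n = int((result.tstrs["tissue"] == tissue).sum())
            lines.append(f"tstr_count_{tissue}\t{n}")
        lines.append(
            f"candidate_regions\t{len(result.tstrs)}")
    for tissue, c in result.concordance.items():
        lines.append(f"concordance_{tissue}\t{c['fraction']:.4f}\t"
                     f"n={c['n']}\tp={c['p']:.3g}")
    for key, e in result.enrichment.items():
        lines.append(f"enrichment_{key}\t{e['tstr_fraction']:.4f}\t"
                     f"control={e['control_fraction']:.4f}\tp={e['p']:.3g}")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
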