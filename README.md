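# ernascan

Discovery and characterization of **tissue-specifically transcribed
regions (TSTRs)** — candidate enhancer-RNA (eRNA) loci — from
strand-specific total RNA-seq of two tissues.

Active enhancers are often transcribed into short, usually bidirectional,
non-coding RNAs. Where two tissues are profiled, intergenic regions whose
transcription is significantly biased toward one tissue are strong
candidates for tissue-specific enhancers. `ernascan` implements that
analysis end to end for computational biologists working on regulatory
genomics: sliding-window discovery of read-enriched intergenic regions,
a two-proportion z-test for tissue specificity, random-region background
calibration, overlap with enhancer-associated features (phastCons
conservation, CAGE-derived TSSs, p300/H3K27ac ChIP signal, validated
enhancer catalogs), strand-separated coverage metaprofiles, and the
correlation between TSTR and nearest-gene tissue specificity. A fully
seeded synthetic-data generator produces complete two-tissue fixtures with
known ground truth, so every stage is testable without external data.

## The statistic at the core

Reads (extended to 200 bp in their 3' direction) are counted in a 2 kb
window around each candidate region's peak; with n_A of N_A library reads
in tissue A and n_B of N_B in tissue B,

```
z = (p̂_A − p̂_B) / √(p̂₀(1 − p̂₀)(1/N_A + 1/N_B)),   p̂ₜ = nₜ/Nₜ,  p̂₀ = (n_A+n_B)/(N_A+N_B)
```

with a two-sided normal p-value (z² equals the Pearson χ² of the 2×2
table). Regions with p < 0.01 become TSTRs of the tissue with the higher
proportion. Companion statistics: RPKM (library size excludes
rRNA-overlapping reads), the tissue-specificity index SI = (s−u)/(s+u),
and the strand directionality index DI = |f−r|/(f+r). See
`docs/methods.md` for the full model, parameters, and conventions.

## Worked example

```python
from ernascan.pipeline import PipelineConfig, run_full
from ernascan.synthetic_data import SimConfig
from ernascan.evaluation import score_recovery

cfg = PipelineConfig(outdir="demo_out", seed=1,
                     sim=SimConfig(noise="poisson"))
res = run_full(cfg)

tstrs = res.tstrs
for tissue in ("heart", "limb"):
    print(f"{tissue} TSTRs: {(tstrs['tissue'] == tissue).sum()}")
score = score_recovery(tstrs, res.bundle.truth)
print(f"planted specific loci recovered: {score['sensitivity']:.0%}")
print(f"non-specific loci called: {score['false_call_rate']:.0%}")
for tissue, c in res.concordance.items():
    print(f"{tissue} enhancer concordance: {c['fraction']:.0%} "
          f"(n={c['n']}, p={c['p']:.2g})")
e = res.enrichment["conservation"]
print(f"conserved: {e['tstr_fraction']:.0%} of TSTRs vs "
      f"{e['control_fraction']:.0%} of controls (p={e['p']:.1g})")
```

Output:

```
heart TSTRs: 51
limb TSTRs: 50
planted specific loci recovered: 100%
non-specific loci called: 1%
heart enhancer concordance: 83% (n=24, p=0.0015)
limb enhancer concordance: 90% (n=20, p=0.0004)
conserved: 64% of TSTRs vs 28% of controls (p=3e-07)
```

This simulates a 2 × 1 Mb two-tissue genome with 100 planted
tissue-specific loci (5-fold expression difference) and 100 non-specific
loci, runs discovery → differential test → background → feature overlap →
profiles → correlation, and scores the calls against the generator's truth
table: all 100 specific loci are recovered in the correct tissue, 1% of
null loci are (falsely) called at α = 0.01, ~83–90% of catalog enhancers
show higher eRNA expression in their annotated activity tissue, and
conserved-element overlap is strongly enriched over size-matched random
intergenic controls. `demo_out/` holds the TSTR table, volcano data,
background calibration tables, per-class summaries, profile and heatmap
matrices, and a plain-text summary, all deterministic under the seed.

The same pipeline is scriptable from a shell:

```
ernascan simulate --seed 1 --outdir sim_out
ernascan run --config config.yaml --seed 1
```

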