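# Methods

`ernascan` identifies tissue-specifically transcribed regions (TSTRs) —
candidate enhancer-RNA loci — from strand-specific total RNA-seq of two
tissues, and characterizes them against enhancer-associated genomic
features. This note describes the statistical model, every tunable that
matters, what the simulator does and does not emulate, and the numerical
conventions.

## Discovery model

Uniquely aligned 50 bp reads are extended to 200 bp in their 3' direction
(the expected fragment length) and scanned with a sliding window (default
500 bp, step 50 bp). Window counting is the number of extended reads
intersecting the window, without regard to strand. Windows holding at least
`min_reads` (default 10) qualify; overlapping or abutting qualifying windows
merge into maximal enriched regions, so no separate gap parameter exists.
Regions overlapping any annotated interval — gene bodies (introns included),
mRNAs/ESTs, rRNA — by one or more base pairs are removed; what survives is
intergenic. Each region carries a peak center: the leftmost position of
maximal combined read depth.

The window and step sizes are honest defaults rather than published
values — the upstream tool the analysis descends from does not document
them — and both are configuration keys echoed into every report header.

## Differential test

For each candidate region, reads are counted in a 2 kb window centered on
the peak (strand-agnostic, extended reads), giving n_A and n_B against
library sizes N_A and N_B (unique reads excluding rRNA-overlapping ones).
The two-proportion z-test is

    z = (n_A/N_A − n_B/N_B) / sqrt(p0 (1 − p0) (1/N_A + 1/N_B)),
    p0 = (n_A + n_B)/(N_A + N_B),

with a two-sided normal p-value; z² is identical to the Pearson chi-square
of the corresponding 2×2 table (asserted to 1e-9 in tests). Regions with
p < 0.01 (strict) are assigned to the tissue with the higher proportion; the
rest stay unassigned. No multiple-testing correction is applied, matching
the procedure the pipeline reproduces; a BH column can be added downstream
but never gates calls. The degenerate pooled proportions 0 and 1 return
z = 0, p = 1: nothing observed is no evidence of difference.

Companion statistics, all on raw 2 kb-window counts:

- RPKM = n / (L/1000) / (N/10⁶), with an optional visualization floor of
  2⁻⁹ for log-scale dot plots.
- Tissue-specificity index SI = (s − u)/(s + u), s the expression in the
  region's assigned tissue. Computed on counts rather than RPKM — within a
  fixed window and one library the two are proportional, so the ratio is
  identical; counts avoid needless division.
- Directionality index DI = |f − r|/(f + r) on strand-split window counts;
  0 is balanced bidirectional transcription, 1 unidirectional.
- Validated-enhancer fold changes substitute 1 for a zero count before the
  ratio (keeping the fold finite); the volcano p-value uses the raw counts.
- The exact concordance test is the doubled-smaller-tail binomial:
  p = min(1, 2·min(P(X≤k), P(X≥k))), X ~ Bin(n, p0). For 12 successes in 15
  trials at p0 = 1/3 it yields 5.7e-4, printing as 0.0006.
- qPCR candidates are drawn uniformly (seeded) from the top 30% of |z|.

## Background calibration

Control regions matching a query set in number and size are placed
uniformly in annotation-free sequence by rejection sampling. Over 100
iterations, the fraction of controls holding ≥ t reads in a 1 kb midpoint
window is recorded per threshold t, and a normal fit (mean, SD) supplies
upper-tail p-values for observed enhancer fractions. The 1 kb width applies
to threshold calibration; expression and fold-change analyses use the 2 kb
window. Whether the published control fractions used 1 or 2 kb is not
stated; the width is a parameter defaulting to 1 kb.

## Feature overlap

Each TSTR is summarized in a 1 kb window around its peak center:

- conservation: the score of the most constrained overlapping phastCons
  element (any overlap counts; an optional minimum-score filter exists
  because "strong constraint" could also be read as a cutoff);
- CAGE: overlap with any candidate TSS, CAGE peak midpoints extended 1 kb
  each side;
- ChIP enrichment: per mark (p300, H3K27ac), the window's mean coverage —
  input-subtracted after normalizing both tracks to genome-wide mean 1, or
  raw, a strategy switch, since "relative coverage" is not defined
  precisely upstream — is compared against the 95th percentile of
  background coverages over 1 kb bins tiling a 1 Mb background span.
  "Equal to or greater" counts as enriched. Note the degenerate case: on an
  exactly constant background the 95th percentile equals the mean and
  everything is "enriched"; real and simulated backgrounds have variance.

Classes (none / H3K27ac-only / p300-only / both) feed per-class summaries,
cumulative DI curves, TSS-distance distributions, and Fisher's exact
enrichment tests (two-sided, via the standard hypergeometric convention).

## Coverage profiles

Metaprofiles average read depth in 25 bp bins across 10 kb windows centered
on anchors (positions of maximal ChIP coverage, leftmost on ties),
separately for forward-strand, reverse-strand and combined reads, scaled
per million mapped reads. The per-bin mean is trimmed to the 5th–95th
percentile band across anchors. Trimming is rank-based and deliberately
asymmetric in its rounding — floor(0.05 n) values dropped at the low tail,
ceil(0.05 n) at the high tail — because coverage outliers are one-sided:
depth is bounded below by zero and heavy-tailed above. A consequence is
that adding a single extreme high-coverage anchor leaves the retained set,
hence the profile, exactly unchanged. Trimming per-bin across anchors (not
per-anchor) is itself a strategy choice; the alternative reading is
available but not default. Loess smoothing (span 0.1 ≈ 40 bins,
unspecified upstream) uses locally weighted linear regression, which
reproduces constants and straight lines exactly.

Heatmap matrices cover ±25 kb around TSTR centers in 25 bp bins (2,000
columns), input-corrected and depth-normalized, centered and scaled by the
matrix-wide mean and SD per dataset, rows ordered none → H3K27ac-only →
p300-only → both.

## Neighbor correlation

Genes are expressed as RPKM over their merged exon union. Each called TSTR
is paired with its 1st–5th nearest genes by |peak center − TSS| (strand
ignored; ties break on gene id; TSS chosen as the anchor for consistency
with the TSS-distance analysis — gene-body-edge distance is an option) and
with one random same-chromosome gene. Specificity indices of gene and TSTR
are both oriented by the TSTR's assigned tissue. Per rank, pairs are sorted
by gene SI, grouped into bins of 20, and Pearson R is computed over bin
means; a final partial bin is kept if it holds at least half a bin, else it
merges into the previous one (the source procedure is silent; the choice is
recorded in output metadata). With bin size 1 the statistic reduces to the
plain Pearson correlation over pairs.

## The simulator

The generator produces everything downstream stages consume: a small
multi-chromosome genome; non-overlapping gene models with exonic reads and
a 10% intronic rate; rRNA loci with heavy coverage excluded from N; planted
intergenic loci with configured per-tissue mean counts and Bernoulli strand
assignment; uniform genome-wide stray reads (0.003/bp); ChIP coverage as
Poisson(5) background per 25 bp bin plus triangular bumps (height 60,
half-width 500 bp) at flagged loci, with a matched pure-background input
track; phastCons elements at conserved loci plus ~400 background elements
kept clear of loci; CAGE peaks likewise; and a validated-enhancer catalog.
Items are laid out left to right with random gaps (minimum 3 kb), which
guarantees planted loci are intergenic — the annotation filter must retain
100% of them.

Default study conditions: 2 × 1 Mb genome, 40 genes, two rRNA loci, 100
tissue-specific loci (active-tissue mean 150 reads, other tissue 30 — a
5-fold proportion difference with the weaker side at 30 expected reads)
and 100 non-specific loci (40/40). Catalog enhancers are drawn from
specific loci (p = 0.3) and, at p = 0.2, from non-specific loci with a
random activity label — enhancers can be active without tissue-biased
transcription, which holds catalog concordance near the ~80% observed for
in-vivo enhancer sets rather than a trivial 100%. Conservation is planted
at 0.70 for specific vs 0.28 for non-specific loci, CAGE at 0.5 vs
background, both mirroring the enrichments the analysis is meant to detect.

Count noise defaults to negative binomial with dispersion 0.1 (variance
m + 0.1 m²): a single pooled library per tissue leaves the true
overdispersion unconstrained, so a mildly overdispersed default is the
conservative choice. Poisson noise is available and is used for
statistical-calibration experiments, because the two-proportion z-test
assumes binomial sampling variance: under NB(0.1) at ~40 expected reads
the test's type-I error rate is inflated roughly 25-fold, an inherent
property of proportion tests on overdispersed counts, not an implementation
artifact. Calibration results obtained under Poisson therefore say nothing
about false-positive control on overdispersed real data — on real tissue
RNA-seq the p < 0.01 cutoff is a ranking device more than an error rate.

A separate named condition set, `SimConfig.correlation_study()`, serves the
neighbor-correlation analysis: 4 × 1 Mb, 400 short genes vs 144 loci
(approximating the gene-to-enhancer ratio of real annotations, so a TSTR's
nearest gene is usually the gene its expression is coupled to), specific
high means drawn U(36, 400) so loci span a spectrum of fold changes, and
gene expression biased toward the nearest specific locus's tissue with
strength proportional to that locus's specificity, decaying exp(−d/30 kb).
Under the fixed 5-fold defaults TSTR specificity is nearly constant and a
correlation is undefined; the drawn-fold conditions make the rank-1
correlation estimable (typically R ≈ 0.6–0.9, decaying with rank, ~0 for
random genes).

What the simulator does not emulate: base-level sequence, mappability
structure beyond a uniqueness flag, fragment-length variation, pre-mRNA
splice structure beyond exon/intron rates, chromatin-domain correlation
between marks, or replicate structure (replicates exist only as independent
seeds, matching the single pooled library per tissue). Passing tests
demonstrate correctness of the computations and calibration under the
stated generative model, not performance on real tissue data.

## Numerical conventions and problem sizes

All coordinates are 0-based half-open. bedGraph output is fixed at six
decimals for byte-stable artifacts. All randomness flows from named integer
seeds; identical configuration and seed give byte-identical output bundles,
and every report carries the configuration hash (output paths excluded so
relocated reruns compare equal). Test and acceptance runs use the 2 Mb /
200-locus conditions above (seconds per pipeline run) and 10,000 sampled
null regions for calibration; these sizes give binomial standard errors
comfortably inside the asserted tolerances.

## Known limitations

- Threshold-based discovery only; no FDR model for window counts (the
  background module calibrates the threshold instead).
- The z-test's error control assumes binomial counts; see the
  overdispersion caveat above.
- ChIP peaks are consumed, not called; BAM input requires conversion to
  BED upstream.
- The 12/15 concordance example is labelled a Fisher test in its source but
  matches the doubled-tail exact binomial; the binomial construction is
  what is implemented.
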