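# Methods

This note documents the models, thresholds and numerical choices behind
`pmakit`, and what the synthetic data generator does and does not
emulate.

## Methylation model and region scoring

A methylome is a destranded table of per-CpG counts (methylated,
unmethylated). Plus- and minus-strand records of one CpG dinucleotide are
merged by summing counts at read time; calls below the per-sample
coverage floor are then dropped. The floor is 5× for conventional WGBS
and 1× for allele-split low-input PBAT libraries, where allele-assignable
reads are scarce — both configurable per sample
(`min_coverage_public` / `min_coverage_allelic` in the pipeline config).

Methylation over a region is the **unweighted mean of per-CpG levels**,
not the read-weighted pooled fraction. This makes region levels robust to
uneven coverage; with deep, even coverage the two converge.

A region is **informative** only if it contains at least `min_cpgs`
covered CpGs (2 for 600-bp bins and promoter windows, 4 for the 2/20-kb
global bins) *and* at least one pair of those CpGs is separated by
strictly more than one sequencing read length (default 100 bp, a
per-library parameter). Two CpGs closer than a read length can be covered
by the identical read stack and contribute no independent evidence; the
span rule guarantees at least two independent read observations.
Non-informative regions are a reported state (`no-coverage`,
`unassessed`), never silently zero.

Sliding bins start at coordinate 0 with step = width − overlap (600/100
by default); the final bin is clipped to the chromosome end and dropped
if shorter than the step, so no bin is mostly off-chromosome.

## PMA definitions

- **Bin-level:** a co-informative bin with sperm < 20 % and
  (2C paternal − sperm) ≥ 30 percentage points. The hypomethylated
  denominator uses the same < 20 % rule restricted to co-informative
  bins — bins unscoreable in either sample are excluded from numerator
  *and* denominator. Thresholds are percentage points, not ratios, and
  boundaries follow the printed inequalities exactly: sperm at exactly
  20.0 % is not hypomethylated; a gain of exactly 30.0 is PMA.
- **Promoter-level:** the same gain rule evaluated on TSS ± 300 bp
  windows that survived the filter funnel.
- Merged PMA regions are maximal unions of overlapping PMA bins; a merged
  region is category `TSS` when it overlaps any TSS ± 300 bp window by
  ≥ 1 bp. Levels over merged regions are recomputed from the methylomes.
- Base-pair enrichment over annotation classes assigns each PMA base pair
  to one class by the precedence TSS > enhancer > intragenic >
  intergenic (the classes are conceptually exclusive; precedence resolves
  annotation overlap), and the same carve-up defines the genome-wide
  expected proportions for the goodness-of-fit χ².

## Promoter annotation

The observed/expected CpG ratio of a window is
`obs · L / (#C · #G)`, zero when the window lacks C or G. Windows are
classed high (≥ 0.75), intermediate (≥ 0.12, inclusive) or low;
high + intermediate are "CGI promoters". The window for the ratio is
TSS ± 300 bp, the same window used everywhere else; the classical human
promoter-class scheme uses other windows, so the thresholds are exposed
as parameters rather than hard-coded.

CpG-island detection implements the standard three criteria (GC > 50 %,
obs/exp > 0.6, length > 200 bp) as a 200-bp sliding-window flag, merge of
flagged runs, trimming of each run to its outermost CpG dinucleotides,
and post-hoc re-verification of all three criteria on each trimmed
interval. The criteria are classical; the flag-merge-trim algorithm is
this package's choice and is pinned by an exhaustive naive rescan in the
test suite. `N` bases count toward length but never toward C/G/CpG
tallies.

## Filter funnel

Strain consistency of sperm methylation is not numerically defined in the
vocabulary it comes from; we operationalise it as: consistent-low = both
strains < 20 %, consistent-high = both > 80 %, strain-specific
hypomethylation = < 20 % in one strain and > 50 % in the other, with
`inconsistent` and `unassessed` as residual labels. All three bounds are
configurable. Downstream stages keep consistent-low promoters only.

The H3K4me3 gate keeps promoters with sperm RPKM ≥ 1 (inclusive), where
RPKM = overlapping reads · 10⁹ / (library size · window length) and a
read counts if it overlaps the window by ≥ 1 bp (midpoint assignment is
available as an option). Allele-split ChIP tracks carry their own library
sizes.

Allele assessability requires ≥ 1 variant inside the window (any record
type, by position — genotypes are not parsed) plus informativeness in
both sperm and embryo-paternal methylomes.

Persistence classes at the ICM stage: < 5 % hypomethylated, 5–20 %
intermediate, ≥ 20 % retained. The boundary values are assigned 5 →
intermediate and 20 → retained, resolving the overlap of the printed
ranges in favour of the inclusive "≥ 20 %" retention rule.

## Statistics

Welch's two-sided unequal-variance t-test (Welch–Satterthwaite df);
Pearson χ² goodness-of-fit (df = k − 1) and 2×2 (df = 1) **without
continuity correction** — the source analyses say only that chi-squared
tests were used, and the uncorrected Pearson statistic is the
conventional default at these counts; Benjamini–Hochberg step-up
adjustment; squared Pearson correlation. Statistics are computed from
closed forms; tail probabilities use log-space-safe survival functions so
p-values far below double-rounding thresholds (1e−200 and smaller) are
reported as computed. Degenerate Welch inputs (both variances zero)
return the limiting p of 1 (equal means) or 0 (different means).

## Differential expression

The original analyses used an off-the-shelf negative-binomial DE package;
re-implementing it is out of scope. The caller here is fully specified
and self-contained: per gene and allele, fold = (mean library-normalised
KO count + 0.5) / (mean library-normalised WT count + 0.5) — the 0.5
pseudocount stabilises folds at duplicate-level replication — and the
p-value is a conditional binomial exact test of the pooled KO count
against the pooled KO library share. BH adjustment runs across all genes
of one stage × allele contrast; a call requires |log₂ fold| ≥ 1 and
q ≤ 0.1 (both boundaries inclusive). Under negative-binomial
overdispersion the pooled binomial p-value is anti-conservative, but the
two-fold requirement dominates specificity: on null simulations the
caller's positive rate stays well below the nominal 10 % FDR (measured in
the acceptance suite). Validation is planted-effect recovery, not numeric
identity with any particular NB implementation.

The candidate screen takes the conjunction: CGI promoter, ≥ 1 exonic
variant, paternal upregulation called at 4C, maternal fold < 2 at 4C
(significance not required — "no substantial maternal change" is a fold
criterion), no paternal upregulation at ICM, WT 2C total promoter
methylation − max(sperm, oocyte) ≥ 18 points, and matKO 2C total
methylation < 4 %. Transcription-initiation-site verification by
transcript assembly is not implemented and is noted in reports. gDMR
parent-of-origin is operationalised as a ≥ 40-point gamete methylation
margin (oocyte vs sperm).

## Synthetic data generator

The generator is the package's study-conditions definition, not a tuning
surface. Defaults: 200 genes on two 260-kb chromosomes, 20 planted PMA
promoters, 15× mean coverage per allele per CpG, read length 100 bp,
planted paternal 2C gain +0.40, seed 42.

- **Sequence.** Background sequence is a first-order Markov chain with
  G-after-C probability 0.08 at GC 0.42 (≈ 1 CpG per 60 bp — near
  genomic density, CpG-suppressed relative to independence). Promoter
  windows are composed per class: high (iid GC-rich, obs/exp ≈ 1.0),
  intermediate (obs/exp ≈ 0.3), low (strongly CpG-suppressed,
  obs/exp ≈ 0.1). Planted promoters are resampled until they hold ≥ 4
  CpGs. Class proportions 35/35/30 high/intermediate/low.
- **Variants.** Substitutions only, at 0.005/bp (near the B6×DBA SNV
  density); INDELs are omitted — the filters test variant *presence*, and
  coordinate lift-over would add complexity without analytic value. SNVs
  never fall on, create, or (via adjacent pairs) combine into a CpG, so
  both haplotypes share one CpG set and one truth table. Every promoter
  window and every gene carries one forced variant so assessability is
  coverage-limited, not variant-limited.
- **Methylomes.** Per CpG and allele, coverage ~ Poisson(15) and
  methylated reads ~ Binomial(coverage, truth); optional beta-binomial
  overdispersion is off by default (no published noise model exists for
  low-input PBAT at these stages). Stage profiles: sperm CGI promoters
  2 %, sperm background 80 %; oocyte bimodal (2 % / 85 % at a 15 %
  hyper fraction); paternal background decays 80 → 40 (2C) → 25 (ICM) to
  echo the global post-fertilization loss; maternal background 40 (gamete)
  → 32 (2C) → 25 (ICM); androgenetic background 20 %, parthenogenetic
  25 %; matKO maternal background 5 %. Planted promoters reach 42 % on
  the 2C paternal allele and in androgenetic blastocysts, cycle
  retained/intermediate/hypo (30/10/2 %) in ICM, and revert to 2 % in
  matKO. Imprinted gDMRs (6 maternal, 3 paternal — scaled to the mouse
  imprint catalog's maternal bias) are methylated ~90 % in the methylated
  gamete, maintained at ~85 % on the inherited allele, and maternal gDMRs
  collapse to 5 % in matKO.
- **ChIP tracks.** Enriched windows receive Poisson read counts targeting
  RPKM ≈ 16 at promoters and ≈ 2 over 20-kb domains against an RPKM 0.05
  background, library size 10⁶. Planted PMA promoters lose paternal
  H3K4me3 in 2C and carry zygotic H3K9me3, mirroring the chromatin
  correlates of methylation acquisition.
- **Expression.** Two replicates per condition; allele counts are
  gamma-Poisson (NB) with dispersion 0.05 around per-gene lognormal
  baselines (mean 100 per allele); planted genes multiply the
  (4C, paternal) mean by 4 in matKO only. Totals are maternal + paternal
  sums.

What the generator does **not** emulate: read-level bisulfite conversion
and alignment bias, INDELs, mappability gaps, X-chromosome dosage,
replicate-level batch effects, and the long-tailed coverage
heterogeneity of real PBAT. Passing recovery tests therefore demonstrates
the correctness and calibration of the *analysis logic* under the stated
sampling model, not robustness to alignment artefacts.

## Problem sizes and determinism

The default fixture (200 genes, ~36 k CpGs, 15 methylome tracks) runs the
full pipeline in seconds; the null differential-expression calibration
uses 1000 genes × 10 count simulations. All randomness flows from a
single integer seed through independent, tag-derived generator streams
(`SeedSequence([seed, crc32(tag), …])`), so any sample can be regenerated
in isolation and identical configurations produce byte-identical
datasets and reports (verified by checksum in the tests).

## Known limitations

- The genome-wide quantities (PMA bin fraction, total PMA kbp, global
  methylation change) depend on the synthetic genome's gene density and
  CpG layout and are not calibrated to full-genome magnitudes; they are
  reported as measured on the miniature genome.
- The strain-consistency bounds and the gDMR parent-of-origin margin are
  operationalisations of qualitative descriptions; both are configurable.
- The DE caller's binomial p-value ignores biological overdispersion
  (see above); it is a screen, with specificity carried by the fold rule
  and validity established by planted-truth and null simulations.
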