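# Methods

`ploidyseq` implements the analysis chain of an embryo-transcriptome study
design: karyotype validation from RNA-seq variant allele fractions, an
expressed-core characterization of normal embryos, per-aneuploidy
negative-binomial differential expression, chromosome-normalized dosage
summaries, and cross-aneuploidy recurrence. A synthetic cohort generator
reproduces the statistical structure of such a cohort so that every stage
is testable end to end without access to patient data.

## Ploidy inference from allele fractions

At a biallelic site on a chromosome present in `k` copies, the alternate
allele occupies `j` of the copies (`j = 1..k`), so read-level variant
allele fractions (VAFs) concentrate at `j/k`. The per-chromosome VAF
density therefore has one peak near 1 for haploid chromosomes, peaks near
1/2 and 1 for diploid, and a peak near 2/3 (plus a low peak and one near 1)
for triploid.

Only high-confidence variants enter the density: **depth ≥ 50 and variant
quality ≥ 500**, both inclusive. VAF is alternate depth over the record's
DP. The density estimate is a 1024-bin histogram on [0, 1] smoothed with a
Gaussian kernel (σ = 0.04 on the allele-fraction axis, configurable) with
edge reflection at 0 and 1, so the homozygous peak sitting exactly at 1 is
not attenuated. Local maxima with topographic prominence below 10% of the
global maximum are discarded. Histogram smoothing is equivalent to a
reflected kernel density estimate up to the 1e-3 binning resolution and is
O(n + grid), which keeps whole-cohort validation in seconds.

Classification matches the detected peaks against closed template windows:

| window | interval | meaning |
|---|---|---|
| hom | [0.85, 1.00] | homozygous-alt peak shared by every ploidy |
| dip_het | [0.45, 0.55] | diploid heterozygous peak (1/2 ± 0.05) |
| trip_mid | [0.6167, 0.7167] | triploid discriminator (2/3 ± 0.05) |
| trip_low | [0.28, 0.58] | low triploid peak; wide enough for 1/3 or 1/2 |

Triploid requires an occupied `trip_mid` plus `hom`; diploid requires
`dip_het` plus `hom` with `trip_mid` empty; haploid requires all peaks in
`hom`. In every case **each detected peak must fall inside a window of the
chosen template**; any unassigned peak, or fewer than 50 variants on the
chromosome, yields `indeterminate`. A peak exactly on a window edge belongs
to the window. The all-peaks-assigned rule is what catches mosaics: a
50/50 diploid/trisomic mixture places its mixture classes at 0.4, 0.6 and
1.0 — 0.4 and 0.6 sit outside every window, so the chromosome cannot be
typed and the embryo is excluded rather than mistyped. The ±0.05 window
half-width is the narrowest that still tolerates peak-location jitter at
the 50-variant support floor; widening it toward the mixture classes would
trade mosaic sensitivity for nothing.

The triploid low peak deserves a note: the genotype model predicts it at
1/3, while plots of real data are sometimes described with the low peak at
1/2 (e.g. when a genome-wide diploid background bleeds into the panel).
`trip_low` accepts both; classification keys on the 2/3 peak, which the
two descriptions share.

Chromosome Y is never ploidy-called — it is variant-poor in RNA-seq
practice. Male identity comes from expression instead: an embryo is
Y-expressing when at least one Y gene reaches the expression cutoff. The
sex call combines the X ploidy with Y presence: (2, no Y) = XX, (1, Y) =
XY, (1, no Y) = XO, (3, no Y) = XXX, anything else unknown. An embryo is
`validated` when every chromosome call matches its screening label and
nothing is indeterminate; indeterminate chromosomes give
`excluded_mosaic_or_indeterminate`; determinate conflicts give `mismatch`.
Only validated embryos enter any downstream table.

## Expression quantification

FPKM(g, s) = counts(g, s) × 10⁹ / (length_bp(g) × total_counts(s)), with
the per-million denominator taken from the count-matrix column sums so the
quantity is self-contained and reproducible. A gene is *expressed* at
FPKM ≥ 10 (inclusive). The expressed core of a sample set is the
intersection of per-sample expressed sets; the overlap fraction is
|core| / |union| (the union is one defensible reading of an overlap
denominator that is not otherwise pinned down). Per-chromosome expressed
fractions divide by each chromosome's annotated gene count, removing gene
content from the comparison.

## Differential expression

One aneuploidy group against the normal group, re-implementing the
standard bulk RNA-seq NB pipeline:

- **Size factors** by median-of-ratios: reference = geometric mean across
  samples over genes with nonzero counts everywhere; factor = median ratio
  to the reference.
- **Dispersion** per gene by method of moments on normalized counts,
  pooled across the two groups by residual degrees of freedom. The raw
  gene-wise estimate at 2–5 replicates per group is extremely noisy, and a
  normal-reference Wald statistic built on it has t-like tails that break
  FDR control (at 2,000 genes, BH rejects in most null data sets). The
  estimate is therefore floored at the 0.9 quantile of gene-wise estimates
  from well-measured genes (normalized mean ≥ 50) — a deliberately
  conservative stand-in for full empirical-Bayes shrinkage. Restricting
  the floor to well-measured genes matters: at low means the moment
  estimator is dominated by Poisson noise of scale 1/mean, which would
  inflate the floor and destroy power globally. Final floor 1e-8.
- **Group means** are count-sum over size-factor-sum (the Poisson MLE); a
  group with zero counts uses a half-count pseudo-rate so fold changes
  stay finite with appropriately wide uncertainty.
- **Wald test**: z = Δlog-mean / se, with se from the NB GLM information
  I = Σ μ/(1 + αμ) per group; two-sided p-values from the normal
  reference; **Benjamini–Hochberg** adjustment across all tested genes
  (genes with zero counts in all used samples are excluded). Significance
  is padj < 0.05. Volcano classes additionally use |log2FC| > 2.
- Contrasts are **sex-aware**: each aneuploidy is tested against same-sex
  normals (falling back to all normals when fewer than two match).
  Without this, an all-female aneuploid group against mixed-sex normals
  calls every Y gene "down" on sex alone.

Deliberate simplifications versus a full DESeq2 fit — no dispersion trend,
no log2FC shrinkage, no outlier refitting, no independent filtering beyond
all-zero removal — change per-gene p-values but preserve the contracts the
analysis rests on (null FDR control, dosage-direction recovery). The test
suite cross-checks fold changes and planted-gene discoveries against
pydeseq2 on a small fixture.

## Dosage summaries and recurrence

The bubble matrix normalizes each (aneuploidy, chromosome) DE count by
both the chromosome's gene content and the aneuploidy's total DE genes;
its diagonal dominance statistic is the fraction of aneuploidies whose
own gained/lost chromosome attains the row maximum in the expected
direction (ties count as dominant; all-zero rows are excluded from both
numerator and denominator). Aneuploidies are ranked by total DE genes,
ties broken lexicographically.

Recurrence restricts to aneuploidies with ≥ 100 DE genes (inclusive),
computes per-gene fractions of eligible trisomies/monosomies in which the
gene is up / down / unchanged (genes absent from a contrast's table count
as unchanged, keeping fractions comparable), selects genes changing in
≥ 60% (inclusive) of a class, and intersects classes. "Deregulated" means
significant with the sign of the fold change; the |log2FC| > 2 threshold
is volcano coloring, not a recurrence requirement.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis is designed
to detect; its defaults are the study conditions of every test.

- **Genome**: chromosomes "1".."22" and "X", 200 genes each, plus 40 genes
  on "Y"; gene lengths uniform 500–10,000 bp.
- **Counts**: NB (gamma–Poisson) with gene baselines log-uniform on
  5–2000 and dispersion 0.02. The dispersion is at the low end of bulk
  RNA-seq practice, deliberately: cohorts of this design detect thousands
  of DE genes from two or three embryos per aneuploidy, which is only
  possible if between-embryo dispersion is small. Library size factors
  are log-uniform on 0.7–1.4 per sample.
- **Dosage**: every gene on a gained chromosome has mean × 1.5, on a lost
  chromosome × 0.5 (X scales with the sex complement; Y genes are silent
  except in XY embryos — no dosage compensation is modeled).
- **Trans-dysregulation**: a configurable fraction (default 0.10, per
  karyotype overridable) of off-chromosome genes receive a log2 shift
  drawn N(0, 1), fixed per karyotype so replicates agree. The study-like
  design gives viable aneuploidies (trisomy 21, 18, XXX, XO) a 0.005
  fraction, emulating their near-normal transcriptomes.
- **Planted recurrence**: 6 pan-aneuploidy up and 18 down genes
  (|log2FC| = 2) applied in every aneuploid karyotype, drawn from
  autosomal genes in the upper half of baseline expression — recurrent
  genes are detectable by construction; a knockdown of a gene expressed
  at 5 counts is invisible to any test and would emulate nothing.
- **Variants**: 500 per chromosome (the achieved expressed-variant
  density is not documented for this design; 500 is an order-of-magnitude
  guess, flagged here), depth uniform 50–200, alternate copies uniform on
  {1..ploidy}, reads Binomial(depth, alt copies/ploidy), quality
  10 × depth (so the two confidence filters align at their boundaries; a
  different monotone map can be injected). Ploidy-1 chromosomes emit VAF
  exactly 1 — the generative model has no reference-bias noise.
- **Mosaics**: a second karyotype contributes a configurable cell
  fraction (default 0.5). Copy-number changes are modeled one copy at a
  time, the changed copy being the alternate haplotype with probability
  (alt copies)/(ploidy); the expected VAF is the copy-weighted mixture
  across cell lines, which is what places mosaic peaks off every pure
  template (0.4 / 0.6 / 1.0 for diploid/trisomic at 50/50). Counts mix
  the component means at the cell fraction. A loss-then-regain history is
  not modeled; a 50/50 monosomy/disomy mixture in this model is
  genuinely confounded with other signatures, so mosaic tests use
  disomy/trisomy mixtures.
- **Determinism**: all randomness flows from one seed through named
  streams (annotation, baselines, per-karyotype trans effects,
  per-replicate counts and variants); identical configurations give
  byte-identical cohorts, and individual replicates are reproducible in
  isolation.

What the generator does *not* emulate: alignment and calling artifacts,
reference bias, batch effects, allele-specific expression, isoform
structure, segmental aneuploidy, or quantitative mosaic fractions other
than the configured mixture. Passing tests therefore demonstrate that the
analysis logic is correct under the stated statistical model, not that
the thresholds are optimal for any particular sequencing protocol.

## Problem sizes used by the test and acceptance runs

Peak-template checks use 2,000 variants per chromosome at depth 50–200.
Karyotype recovery runs all 44 autosomal aneuploidies plus XO/XXX over 20
seeds at the default 500 variants per chromosome, with one 50/50 mosaic
per seed. Null-FDR checks use 2,000 genes at 5 + 5 replicates over 50
seeds; power checks plant 4-fold effects in 100 genes at dispersion 0.05.
Dosage-diagonal checks use full 22-aneuploidy cohorts (3 replicates vs 5
normals, trans fraction 0.05) over 10 seeds per direction. The worked
examples in the test suite are computed by hand in their docstrings.

## Known limitations

- At duplicate-level replication the +0.58 log2 cis gain of a trisomy
  sits at the edge of detectability: the full study-like cohort shows
  partial trisomy up-dominance (0.41) while monosomy down-dominance
  (effect −1.0 log2) is complete. Three replicates per aneuploidy push
  both above 0.9.
- The Wald test with moment dispersions is conservative by construction;
  per-gene p-values are not numerically comparable to a full
  empirical-Bayes fit.
- Label parsing covers the cohort vocabulary (euploid, single autosomal
  trisomy/monosomy, XO/XXX), not arbitrary ISCN strings.
- Multi-allelic records are skipped rather than decomposed; indels are
  excluded from VAF densities by default.
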