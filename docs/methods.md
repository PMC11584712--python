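# Methods

This note documents the statistical model, the defaults and why they were
chosen, the synthetic-data generator's scope, and the numerical decisions a
maintainer would want to know about.

## Design and model

The experiment has six conditions: each of two paralogous transcription
factors (TF1, TF2) is overexpressed (CRISPRa) and knocked out (CRISPR-KO),
and each CRISPR system has its own non-targeting control (ctrl-OE,
ctrl-KO). Six replicates per condition is the default throughout.

Counts are modelled with a single joint cell-means negative-binomial GLM:
one coefficient per condition, a log link, and a log size-factor offset
shared across conditions,

    y_gs ~ NB(mean = sf_s · q_g,cond(s), dispersion α_g),
    Var(y) = μ + α μ².

Because the design matrix is a condition indicator, the fit decouples by
condition into one-dimensional problems solved by vectorized Fisher
scoring across all genes at once (convergence: max coefficient change
< 1e−8 in natural-log units, ≤ 100 iterations). The per-condition variance
is the inverse observed information; the condition blocks are independent,
so the contrast variance is a weighted sum.

The factor effect is the combined contrast
(TF-OE − ctrl-OE) − (TF-KO − ctrl-KO), reported in log2 units. It adds
concordant OE/KO signal and cancels any shift shared between a targeting
condition and its matched control — the stress response to transduction
and CRISPR-system activity. Inference is a two-sided Wald test against the
standard normal, Benjamini–Hochberg adjusted; DEG calling uses strict
inequalities padj < 0.05 and |log2FC| > 0.58. Genes with fewer than 10
counts summed over all samples are excluded before any estimation
(inclusive threshold: a row total of exactly 10 is kept).

Normalization is median-of-ratios against the per-gene geometric mean over
samples, using only genes with all-positive counts as the reference; a
pseudo-reference fallback (geometric mean with a 0.5 pseudo-count) is
available for sparse matrices and is used inside the bootstrap, where
resampling can empty the all-positive reference set.

Dispersion is a pooled within-condition method-of-moments estimate
(weighted by degrees of freedom), shrunk halfway toward a least-squares fit
of the trend α(μ) = a0 + a1/μ, floored at 1e−8. The 0.5 shrinkage weight is
a pragmatic middle ground for n = 6: raw moment estimates are too noisy,
the trend alone ignores genuine gene-level differences. Conditions whose
counts are all zero for a gene receive a pseudo-fraction coefficient
log((Σy + 0.5)/Σsf) and a ridge (1e−8) on the information so the contrast
stays finite with an honest, very large variance.

Effect-size shrinkage: an optional normal-prior posterior-mean shrinkage
(prior variance by moments) can be applied to log2FC estimates; the default
is the unshrunken MLE. The thresholds are strict either way.

## Bootstrap null for DEG-set overlap

The observed statistic is the Jaccard index J = |A ∩ B| / |A ∪ B| of the
two factors' DEG sets (convention: J = 0 when the union is empty). The
expected overlap under "both factors regulate the same genes" is estimated
by a constrained bootstrap: within every one of the six conditions,
replicates are drawn with replacement; draws with fewer than three distinct
samples are rejected and redrawn. For each bootstrap replicate the full DE
analysis is rerun and DEGs are recalled at the main thresholds; the
pairwise Jaccard distribution *within* one factor's replicates is that
factor's expected-overlap distribution.

One deliberate refinement: within a bootstrap replicate, the dispersion is
estimated from the *distinct* samples drawn, not the resampled matrix with
duplicates. Duplicated columns carry no information about biological
variance; including them deflates the moment estimator, which inflates
bootstrap false positives and biases the expected J downward. With the
deduplicated dispersion, simulations in which both factors share all
targets give a median observed/expected ratio of ≈ 100% with full CI
coverage. The Wald standard errors still count duplicated samples (that is
what a bootstrap replicate is), so single replicates retain a small
false-call rate (~1% of the universe under a global null) — visible in the
test suite's bounds and irrelevant at the level of the pairwise-J
distribution.

Summaries per category (up / down / all = union per replicate):

* expected J per factor = mean of its within-factor pairwise J values;
* 95% basic bootstrap interval (2θ̂ − q₀.₉₇₅, 2θ̂ − q₀.₀₂₅), clipped to
  [0, 1], with θ̂ = the distribution mean (a within-factor J has no
  single-dataset analog, so the mean is the natural center; percentile
  intervals are available);
* the observed J's interval uses the cross-factor pairwise bootstrap J
  distribution reflected around the observed value;
* one-sample Z test z = (mean − observed)/sd(ddof=1), two-sided by default
  (the sidedness is configurable; the original report does not state it);
* O/E ratio = 100 · observed / mean(expected_TF1, expected_TF2), one
  decimal.

The number of bootstrap replicates defaults to B = 100; pairwise
comparisons are capped at 10,000 pairs by seeded subsampling. Fisher exact
overlap tests use the 2×2 membership table over the tested-gene universe
(after the count filter, never the full annotation) and report the
conditional-MLE odds ratio with exact CI (the R `fisher.test` convention)
plus the sample odds ratio ad/bc. Transcriptome-wide similarity is also
summarized as the Pearson correlation of the two factors' Wald Z-scores
over the shared tested universe, with a 100-resample percentile CI over
genes.

Off-target exclusion: guide off-target candidates are kept at CFD > 0.1
(strict) with exonic or intronic location; a kept gene differentially
expressed for *both* factors cannot be the off-target of one specific guide
and is flagged `shared_effect_not_offtarget`.

## Peak integration

Coordinates are uniformly 0-based half-open. A peak's position is its
narrowPeak summit when present, else the interval midpoint. Distances to
the nearest TSS are signed by gene strand; the promoter is TSS ± 5 kb
inclusive, and peak→gene links use a 1 Mb inclusive window (both choices
inclusive at the boundary). Genes with several listed TSSs collapse to the
first (a minimum-distance mode exists). H3K27ac-style interval filtering
keeps peaks with ≥ 1 bp overlap under half-open semantics. Function
prediction scores each gene with the distance-decayed regulatory potential
S_g = Σ_peaks exp(−(0.5 + 4Δ)), Δ = |distance|/100 kb, and compares DEG
strata (padj < 0.05, no fold-change cutoff, for power) against non-DE
genes with one-sided two-sample KS tests. This replaces the rank-product
machinery of full binding-and-expression target analysis with its published
distance weight plus a plain test; exact replication of that tool is a
non-goal.

## Synthetic data: what it emulates and what it does not

The generator draws per-gene baselines from a log-normal (meanlog 4.0,
sdlog 1.5 — typical bulk RNA-seq), dispersions from the trend
α(μ) = 0.05 + 2/μ, and size factors log-normal (sd 0.15) renormalized to
geometric mean 1. Counts are gamma-Poisson. Two designated genes carry the
perturbed factors themselves: log2FC 4.2 and 5.2 under their own OE and
residual fractions 0.35 and 0.47 under their own KO, matching the
motivating study's reported values. Target genes (defaults 190 and 120,
with 20% of the smaller set shared, 30% downregulated) receive an effect at
OE drawn |N(1.0, 0.5)| in log2, mirrored at KO with half the magnitude
(the study reports weaker KO than OE effects); the combined contrast's
true value is 1.5× the OE effect. Stress genes (10% of genes, effects
N(0, 0.5) per system) shift targeting and control conditions of a system
identically — exactly what the contrast is built to cancel.

The effect-size default deserves a note: it was set so that the generator
reproduces the study's *expected-overlap regime* — within-factor bootstrap
J of roughly 0.4–0.5, i.e. a moderate-power DEG landscape with substantial
flicker near the |log2FC| > 0.58 threshold — which is the regime in which
the overlap question is actually posed.

Not emulated: read-level data (FASTQ/alignment), UMI or single-cell
structure, batch effects beyond library size, gene length effects,
correlated gene-gene noise, and within-condition biological heterogeneity
beyond the NB dispersion (the study does not report it; dispersion defaults
are chosen, not fitted). Passing tests therefore demonstrate correctness of
the estimators and the calibration of the bootstrap logic under the NB
model, not robustness to every artifact of real sequencing data.

The peak generator lays genes on synthetic chromosomes (200 kb spacing,
500 genes per chromosome), gives 90% of direct targets one peak at a
distance uniform on [0, 100 kb] from the TSS, and background peaks to 5% of
other genes. Under that distance law ~5% of target peaks are
promoter-proximal; the fixture exercises the interval machinery and the
function-prediction contrast, not the empirical promoter fraction of any
particular ChIP experiment.

## Problem sizes and reproducibility

Simulation-based checks run at deliberately modest scale: 600–1,000 genes
for unit and property tests, 800 genes with B = 30 over 20 seeded runs for
the calibration and divergence surfaces, and 5,000 genes with B = 100 for
the end-to-end acceptance run. These sizes keep the full suite under a
minute of compute while leaving every statistical conclusion
Monte-Carlo-stable; all quantities scale with gene count only through set
sizes.

Every random stage is seeded; one global seed spawns per-stage child seeds
via `numpy.random.SeedSequence`, so reports are byte-reproducible and
stages can be rerun in isolation. Reports are JSON with a schema version;
tables are plain TSV.

## Known limitations

* The NB GLM has no outlier handling (no Cook's-distance replacement) and
  no covariates beyond condition.
* Bootstrap replicates inherit the small-sample behavior of n = 6 with
  duplicates; their individual false-call rate is ~1%, which slightly
  widens the expected-J distributions.
* The basic-bootstrap CI for expected J centers on the distribution mean
  for lack of a full-data analog; this is a convention, stated above, not
  a theorem.
* The adaptive-shrinkage estimator used by the motivating study for
  reported fold changes is not implemented; the optional shrinkage here is
  a single normal prior.
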