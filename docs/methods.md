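# Methods

`timepheno` implements an immunofunctional phenotyping workflow for bulk
tumor transcriptomes: a cytolytic-activity score, a percentile-based
three-class phenotype, microenvironment contrasts, ranked differential
expression feeding pre-ranked GSEA, and phenotype-stratified survival
analysis.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic cohorts can and cannot show.

## CYT score

The cytolytic activity score of sample *s* is the geometric mean of the
granzyme-A and perforin transcripts in TPM:

    CYT(s) = sqrt((GZMA_s + eps) * (PRF1_s + eps))

computed in log space.  RSEM estimated abundances are converted to TPM by
renormalizing each sample to proportions and multiplying by 1e6; the
conversion is invariant to positive per-column rescaling, so unnormalized
exports are accepted.  The pseudocount `eps` (default 0.01 TPM,
configurable) exists because a geometric mean is zero (and its log
undefined) at a zero count; at typical GZMA/PRF1 levels of 1-1000 TPM its
effect is negligible, and downstream phenotyping depends only on the cohort
ranking, which the pseudocount preserves.

Microarray cohorts distributed as per-gene z-scores carry signed values on
which a geometric mean is undefined.  For those, `rank_based_cyt` scores
each sample by the mean of the two genes' within-cohort fractional
mid-ranks, a value in (0, 1].  This surrogate is invariant to any strictly
increasing per-gene transform and feeds the percentile classification with
exactly the information it uses — the cohort ordering.  It is a declared
surrogate, not an attempt to reconstruct absolute TPM from z-scores.

## Phenotype calibration

Two cohort-specific cutoffs define three phenotypes:

* **HTI** (hot T-cell infiltrated): CYT above its cutoff — high cytolytic
  activity alone defines the group;
* **CTI** (cold T-cell infiltrated): CD8+ T-cell fraction above its cutoff,
  CYT below — lymphocytes present but functionally quiet;
* **NI** (non-inflamed): both below.

"Retain the top *x* of the cohort" is implemented as the empirical quantile
at probability 1 − *x* (linear interpolation between order statistics, the
common default in scientific software) with a strict `>` membership test.
Defaults are `cd8_top_fraction = 0.85` and `cyt_top_fraction = 0.40` for
RNA-seq cohorts; microarray-style cohorts use a much smaller hot fraction
(0.08).  The two CYT fractions are user parameters, not derived quantities:
the calibration objective behind them (phenotype ordering of CD8 and CYT)
is not formalized enough to optimize, so the package exposes them and
audits the result instead — `calibrate_and_classify` reports the *realized*
top-fractions (strictly-above counts / n).  On tie-free data these match
the request to within 1/n; point masses (zero-inflated CD8 fractions) pull
them below it, because ties at the cutoff fall below the strict `>` bar.
Cutoffs are calibrated per cohort and never transferred.

## Microenvironment contrasts

Immune-cell fractions and per-sample features are compared between
phenotype pairs with two-sided Mann-Whitney U tests.  When n1·n2 ≤ 400 and
the pooled data are tie-free, the exact null enumeration is used.  The
large-sample / tied path is a normal approximation with tie-corrected
variance, continuity correction, and a fourth-cumulant Edgeworth term

    P(U >= u) ~ Phi~(z) + phi(z) * (gamma2 / 24) * (z^3 - 3z),
    gamma2 = -(6/5) (m^2 + n^2 + mn + m + n) / (mn(m + n + 1)),

which brings the worst-case disagreement with exact enumeration at group
sizes 8-20 from about 1e-2 down to about 5e-4.  Star annotations follow the
conventional strict thresholds (1e-4, 1e-3, 1e-2, 0.05).  No multiplicity
correction is applied across a panel by default — the stars are per-panel
descriptive annotations — but a Benjamini-Hochberg column is available.
Clinical contingency tables use chi-square (Fisher's exact for sparse 2×2
tables, expected cell < 5); "unknown" levels survive parsing as an explicit
category and are excluded per-analysis, with the exclusion recorded.

## Differential expression and ranking

Two-group comparisons use Welch's t on a log-like scale (TPM is
log2(x + 1)-transformed first; z-score and log2 input is used as-is), with
log2 fold change as the difference of group means and Benjamini-Hochberg
adjustment across genes.  Welch's t was chosen over a moderated
(empirical-Bayes) statistic: variance moderation matters at a handful of
samples per group, and the phenotype groups here number in the hundreds,
where the two statistics converge; the choice is recorded in the output.
Genes with zero variance in both groups have no defined t — they are
flagged, given the conventional (t, p) = (0, 1) when the means also agree,
and excluded from ranking.  Volcano classification calls a gene up/down at
|log2FC| > log2(1.5) and p < 0.05 (raw p by default; a switch uses the
adjusted column).  The GSEA ranking is the t score, descending, ties broken
lexicographically; swapping the group pair negates both FC and t exactly.

## Pre-ranked GSEA

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking the ranking, set members add |score|^p normalized by the set's
total weight (p = 1 by default, the standard weighted statistic), misses
subtract 1/(N − Nh); ES is the signed maximum deviation, and the leading
edge is the member run up to (ES ≥ 0) or after (ES < 0) the extremum.
Ties between equal positive and negative deviations resolve positive.  If
every member score is exactly zero the weights degenerate; the walk falls
back to equal weights.

Significance uses a gene-set permutation null (pre-ranked mode has no
phenotype labels to permute): `n_perm` random same-size sets (default
1000), drawn from one seeded generator in collection order, so a fixed
seed gives bit-identical output.  NES divides ES by the mean magnitude of
same-sign null ES; the nominal p is the same-sign null tail fraction (sets
with no same-sign null get p = 1/(n_perm + 1) and a flag).  FDR q is the
standard sign-stratified ratio of pooled-null to observed NES tail
fractions, clipped to [0, 1] and monotone-corrected so a more extreme NES
never carries a larger q.  The significance filter keeps |NES| > 1.7 and
q < 0.01 (both configurable).  Permutation p-values are granular at
1/n_perm, so reported q values below ~1e-3 should be read as "below
resolution", not as precise quantities.

## Survival

Kaplan-Meier estimation and the k-group log-rank test (observed minus
expected events with hypergeometric variance per distinct event time,
df = k − 1) are delegated to lifelines; Greenwood variances accompany each
curve.  Censorings tied with events at the same time are handled by the
standard convention (censorings after events).  Receptor subtypes are
derived with HER2+ taking precedence (HER2-positive regardless of hormone
receptors), then HR+HER2− (ER and/or PgR positive), then TN; incomplete
receptor data yields "unknown", which is excluded from subtype strata.  The
survival panel crosses endpoints with {whole cohort, HR+HER2−, HER2+, TN},
comparing the three phenotypes; cells with fewer than two phenotype groups
or no events are skipped and logged.  No Cox model is fitted — the
workflow reports curves and log-rank p only.

## Synthetic cohorts

The generator draws, per sample, a phenotype (defaults 0.40 / 0.46 / 0.14
for HTI / CTI / NI, mirroring the TCGA-like split), then a shared standard
normal "immune activity" factor *u* that couples everything immune:

* log2 GZMA and log2 PRF1 are Gaussian with phenotype means (6.0, 3.5,
  3.0; SD 0.8) and loading 0.6 on *u*;
* the CD8 fraction is a zero-inflated Beta: zero with probability 0.15
  scaled by phenotype (×1.0 NI, ×0.2 CTI, ×0.1 HTI), otherwise a Beta
  quantile (HTI (6,14), CTI (5,15), NI (1.5,20)) evaluated at a Gaussian
  copula point with loading 0.6 on *u*;
* the remaining immune mass is split over the other 21 cell types by a
  Dirichlet(2, ..., 2) draw.

The two loadings were calibrated once, against the targeted CD8-CYT
Spearman correlation of ~0.5, and frozen.  Background genes are lognormal
on TPM (per-gene baseline uniform on log2 2-8, noise SD 1.0 in log2);
planted sets of 40 genes are shifted +1.0 log2 in their target phenotypes
(an interferon-response-like set up in HTI; two estrogen-response-like sets
up in CTI and NI), and 20 unplanted random sets accompany them in the GMT.
Survival is exponential with per-month hazards (0.004, 0.006, 0.008),
a deliberate HTI-vs-NI hazard ratio of 0.5, censored by an independent
Uniform(0, 180 months) horizon; PFS uses 1.5× the OS hazard.  TMB,
mutation-rate, neoantigen and checkpoint features are lognormal (Poisson
for counts) with a +0.5 log2 HTI shift.  Columns are renormalized to TPM
at the end, so scoring consumes the matrix without special-casing.

`null_config` removes every label dependence (shared CD8/CYT parameters,
zero planted effects, equal hazards, no feature shift) for type-I
calibration; `separable_config` gives disjoint CYT and CD8 supports per
phenotype, under which calibrated classification recovers the true labels
exactly; `worked_fixture` is a 12-sample, 30-gene deterministic cohort
whose CYT values are integer geometric means and whose classification
(3 HTI / 4 CTI / 5 NI at fractions 0.5 / 0.25) can be checked by hand.

What the generator does **not** emulate: gene-gene correlation beyond the
planted block structure, batch effects, realistic mutation spectra,
platform-specific microarray noise, or competing risks.  Passing tests
therefore demonstrate correctness of the computations and calibration of
the tests under the generator's assumptions — not robustness to the full
messiness of real cBioPortal cohorts.

## Problem sizes and runtime choices

The test suite runs desk-scale: classification invariants on 1000 random
cohorts of n ≤ 60; GSEA oracle equivalence on 200 instances of ≤ 50 genes;
null calibrations with 1000 permutations / 500 replicates; full-pipeline
planted-signal recovery at n = 1000 samples × ~2000 genes over a 20-seed
grid.  The acceptance script reproduces the whole pipeline at the TCGA-like
scale (n = 1075) with 1000 GSEA permutations.  These sizes were chosen so
every stochastic check has comfortable statistical resolution while the
whole suite completes in well under ten minutes on one CPU.

## Known limitations

* The rank-based CYT surrogate for z-score cohorts preserves ordering, not
  magnitude; CYT values are not comparable across cohorts, and no
  cross-cohort harmonization is attempted.
* Gene-set permutation (not phenotype permutation) is the only GSEA null;
  it ignores inter-gene correlation and is mildly anti-conservative on
  strongly correlated sets.
* Duplicate gene symbols collapse to the maximum-variance row — a
  deterministic, auditable convention, but not a reconciliation of probe-
  or transcript-level identity.
* The contingency tests treat samples as independent; no pairing or
  stratification is supported.
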