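# Methods

## Signature definitions

**DUX4 signature score.** Raw counts are depth-normalized by the
median-of-ratios method: for each gene with a strictly positive count in
every sample, compute the geometric mean across samples (in log space; any
zero excludes the gene from the reference); each sample's size factor is the
median over reference genes of the count/geometric-mean ratio, with the
median of an even-length list taken as the mean of the two central values.
The DUX4 score of a biopsy is the sum of its size-factor-normalized counts
over the DUX4 target-gene list (nominally 57 genes). Target genes absent
from the matrix contribute zero and are reported in a warning — a gene lost
to an annotation change simply drops out of the sum; only an empty
intersection is an error. A biopsy is DUX4-positive when its score strictly
exceeds the threshold (default 20 normalized reads; a score of exactly 20 is
negative). All parametric statistics and ROC analyses use
log10(score + 1), not the raw score.

**PAX7 score.** The whole normalized matrix is transformed by log10(x + 1)
and quantile-normalized across samples (see below). The PAX7 score of a
biopsy is the two-sample t-statistic contrasting the values of the
PAX7-induced target genes against the PAX7-repressed target genes within
that single sample — positive when induced targets exceed repressed ones.
The unequal-variance (Welch) form is the default, consistent with the
package's blanket Welch policy for t-tests; a pooled-variance variant is
exposed because the original score definition states only "t-statistic".
If both gene sets are constant and equal the score is 0 by convention; if
constant and unequal the statistic is undefined and a degenerate-input error
is raised. Within the FSHD group, the k highest-scoring biopsies are labeled
PAX7-HIGH and the k lowest PAX7-LOW (default k = 10; reduced to floor(n/2)
with a warning when fewer than 2k biopsies exist). Ties at a boundary are
broken by ascending biopsy id, HIGH taking priority, so labels are
deterministic.

**Quantile normalization.** The reference distribution is the mean of
within-sample order statistics. Tied values within a sample all receive the
mean of the reference values over the ranks the tie occupies. This keeps
constant columns fixed and makes the transform idempotent; the usual
"sorted columns identical across samples" property consequently holds
exactly only for tie-free columns. Whether to normalize the full matrix or
only the signature genes was an open choice; the default is the full matrix
(the description "our data" reads as the whole table), with a restriction
flag (`ScoreConfig.restrict_qn_to_targets`) for the target-union variant.

**Fat-fraction correction.** The reference analysis reports that correcting
DUX4 scores for fat fraction raises them in fat-infiltrated biopsies but
does not give a formula. This package uses the minimal "per unit non-fat
tissue" rescaling, corrected = score / (1 − f/100), which is exact if target
expression is proportional to residual muscle volume. This is a package
design choice, not a reproduced formula; it is monotone, identity at f = 0,
and undefined at f ≥ 100. It is off by default.

**Myogenic content index.** Mean log10(normalized count + 1) over marker
genes (default MYOD1, MYOG, MYH3, MYH8), emitted for correlation analyses
only; it never rescales the signature scores.

## Biomarker evaluation

Fat positivity is fat fraction strictly above 15% (15.0% exactly is
normal). The combined biomarker is positive when TIRM or fat is positive;
negative only when both are negative; a pair with one missing member is
positive if the observed member is positive and missing otherwise.
Confusion tables are built over FSHD biopsies with both labels observed;
excluded pairs are counted. Sensitivity supports two denominators: the
table's own positives, or a cohort-wide positive total that includes
signature-positive biopsies lacking biomarker data. The cohort-total
convention is the default because the reference cohort counts its one
TIRM-unevaluated positive biopsy in the denominator (5/19). Note the
reference text's use of "specificity" for the fraction of biomarker-positive
biopsies that are signature-positive denotes what is formally PPV; both are
computed and labeled. Fisher's exact p-values are two-sided by the standard
minimum-likelihood rule (total probability, at fixed margins, of tables at
most as probable as the observed one), via `scipy.stats.fisher_exact`.

The bundled reference contingency counts (`fshdsig.reference`) are the
printed per-group DUX4-classification frequencies of the original cohort.
One printed frequency (DUX4-positives among fat-negative biopsies) is
internally inconsistent with the cohort's positive total; the bundled table
uses the counts consistent with 19 total positives and the printed
sensitivities (9/19, 11/19).

## Statistical machinery

Group comparisons are gated by normality: a continuous variable is compared
with a two-sided Welch t-test only when Shapiro–Wilk p > 0.05 in **both**
groups (the original workflow also inspected QQ plots; visual inspection is
not automatable, so the gate here is the test alone — a documented
deviation); otherwise, and for ordinal variables, a two-sided Mann–Whitney U
test with tie correction is used. Binary variables go to Fisher's exact
test, including two study-specific binarizations: MRC (normal grade = 5.0
versus reduced) and inflammation (score 0 versus > 0). Raw p-values are
reported; a Benjamini–Hochberg helper exists but is off by default, and no
correction is made for the paired VL/TA biopsies from one participant
(mirrored from the reference workflow and flagged as a limitation).
Variables with more than two unordered categories are excluded from the
correlation matrix; cells with fewer than 3 pairwise-complete observations
or zero variance are reported as undefined.

ROC analysis uses the rank definition (AUC = tie-credited probability that a
positive outscores a negative), computed via scikit-learn's `roc_curve`;
AUC is reported as-is, so a score that is *lower* in the positive class
yields AUC < 0.5 and AUC(s) + AUC(−s) = 1.

## Synthetic cohort model

One seeded generator produces raw counts, metadata and ground truth.

* **Counts.** Gene baseline means are drawn log-normally and scaled so the
  expected library size matches `mean_library_size` (default 3 × 10⁶ reads —
  a desk-scale stand-in for the ~3 × 10⁷ of real libraries; the choice is a
  scale, not a structure, parameter). Per-sample depth factors are
  log-normal (σ = 0.12, geometric mean 1). Counts are negative binomial
  with dispersion α = 0.05 (var = μ + αμ²), sampled after all signal is
  injected on the expected-count scale so normalization faces realistic
  overdispersion.
* **DUX4 bursts.** Each FSHD biopsy is burst-active with probability 0.487
  (the observed positive fraction 19/39). A burst's mass is log-uniform on
  (20.3, 807.8) normalized reads (the observed positive-score range) and is
  allocated over a Binomial(57, ½) random subset of the targets by symmetric
  Dirichlet weights. Every biopsy, controls included, carries leakage
  calibrated so the expected burst-free score is 6.44 (the observed control
  mean); with α = 0.05 the 99th percentile of control scores stays near 12,
  comfortably below the threshold. Because the default mass range starts at
  the threshold itself, a near-threshold burst can sample below 20: default
  conditions give recall ≈ 0.99. Perfect recovery is expected (and tested)
  when masses start at 50.
* **Pathology axis.** A latent u ~ Uniform(0,1) per FSHD biopsy (0 in
  controls) multiplies PAX7-induced means by exp(−u) and repressed means by
  exp(+u) (pax7_effect = 1), lowers MYOD1/MYOG and raises MYH3/MYH8, raises
  fat fraction (group Beta means 5.36% control / 9.4% FSHD baseline, plus
  18.23·u, matching the 18.49% FSHD mean), and drives histology,
  inflammation, CSS, MRC, 6-MWT and MFM through noisy monotone maps at the
  participant level. Burst state and u are independent by default (the two
  signatures showed no clear mutual correlation); `burst_pathology_coupling`
  couples them if desired.
* **TIRM.** Bernoulli with probability 0.263 given a burst (the observed
  5/19) and 0.02 otherwise; controls are negative.
* **Induced/repressed baselines.** Repressed targets are drawn ~7-fold
  higher than induced ones so the control-range PAX7 score sits near −7, in
  the region the real assay occupies.

What the generator does **not** emulate: batch effects, library-preparation
bias, cell-type mixtures (deconvolution is out of scope), annotation
differences, missing clinical fields, and any multi-axis pathology
structure — the single-u design makes all clinical correlations emerge from
one axis, which is a deliberate simplification. Passing tests therefore
demonstrate the pipeline's correctness and calibration under the assumed
generative structure, not performance on real tissue data.

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 50–500 biopsies at 150–2000
genes and 10⁵–3 × 10⁶ reads per library — sizes chosen so the whole suite
exercises every stage, including 1000+-replicate Monte-Carlo calibration
checks, in well under a minute each. All randomness flows from a single
`numpy.random.default_rng(seed)` with a documented draw order; pipeline
outputs are byte-reproducible for a fixed seed, and a frozen-digest
regression test pins the default-seed fixtures.

## Known limitations

* The exact published 57-gene DUX4 list and the PAX7 target lists live in
  controlled/supplementary material and are treated as input files; the
  shipped sets are synthetic placeholders for simulation and testing.
* The fat-fraction correction formula is this package's choice (see above).
* Sensitivity/PPV are reported without confidence intervals; only the exact
  test's p-value quantifies uncertainty.
* Participant-level pairing of VL/TA biopsies is not modeled in the group
  comparisons (matching the reference behavior).
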