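# Methods

This note records the statistical models behind `flaresig`, the assumptions
of the synthetic-study generator, and the choices made where the design was
genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modelled

A digital molecular-counting panel (nCounter-like) of 511 immune-response
genes plus 6 positive spike-in probes (a titration ladder at relative
concentrations 128, 32, 8, 2, 0.5, 0.125) and 6 negative background probes,
measured on FFPE kidney biopsies: 4 normal controls and 19 lupus-nephritis
(LN) flares grouped by later induction-therapy outcome — 5 complete (CR),
10 partial (PR) and 4 non-responders (NR). Assays run in two batches of 9
and 10 LN lanes, with all four control samples assayed in both batches.

## Normalisation chain

1. **Positive-control scaling.** Counting efficiency differs per lane.
   The per-assay factor is `GM_ref / GM(assay)`, where `GM(assay)` is the
   geometric mean of that assay's positive-probe counts and `GM_ref` the
   geometric mean of those means; the factors therefore have geometric mean
   1. Geometric (not arithmetic) means because the ladder spans three
   decades; the geometric mean weights its rungs evenly on the log scale.
2. **Background filter.** Pooled mode (default): threshold
   `mean + k·SD` (sample SD, n−1) over all scale-adjusted negative-probe
   counts across all assays, `k = 2` by default; a gene is kept iff its
   mean scale-adjusted count is ≥ the threshold ("at least" ⇒ a gene
   exactly at threshold is kept). A `per_sample` mode (assay-wise
   thresholds, gene kept if it clears them in ≥ half the assays) is offered
   because "expression level" is ambiguous about the unit of comparison.
3. **log2(x + pseudocount)**, pseudocount 1, so a zero count maps to 0.
4. **Quantile normalisation**, classic rank-mean algorithm; ties receive
   the mean of the rank means over their tied positions (Bolstad
   convention). Idempotent; after it every column's sorted vector is
   identical.

**Ordering.** Scaling → filter → log2 → quantile, recorded step-by-step in
the matrix's provenance list. When anchor-based batch correction is in use
the quantile step is deferred until after correction: quantile
normalisation equalises marginal distributions across columns, and a batch
whose genes carry additive log2 offsets has a widened marginal — equalising
first attenuates exactly the offsets the anchor estimator measures. The
workflow therefore runs scale → filter → log2 → anchor-correct → quantile
(provenance shows the five steps in order).

## Batch standardisation

Because the control samples are assayed in both batches, they anchor a
direct estimator: per gene, `offset(b) = mean over anchors of
(value in b − value in reference batch)`; the reference batch is the
lexicographically first. Correction subtracts the offset — additive on the
log2 scale only, no variance rescaling. With 4 anchors the estimator's
variance is `2σ²/4` per gene (σ² the per-observation residual variance),
which at the generator's default noise keeps the offset RMSE below
0.25 log2 units (checked against planted truth in the tests).
Alternatively batch enters the linear model as a covariate; the model
constructor refuses to add the covariate to an already anchor-corrected
matrix (double correction), detected via provenance.

The generator's `replicate_controls` flag distinguishes controls
*re-assayed* per batch (independent counting noise; default) from control
*data reused* across batches (duplicated columns, in which case anchor
differences are zero by construction).

## Moderated differential expression

Per gene g, OLS of log2 expression on group indicators (control reference;
optional batch covariate): coefficient vector, residual variance s²_g,
shared residual df d = n − rank(X). Variance smoothing follows the standard
empirical-Bayes moderated-t construction: a scaled inverse-χ² prior
(d₀, s₀²) on the true variances makes the sample variances marginally
s₀²·F(d, d₀); the hyperparameters are estimated by matching the mean and
variance of log s²_g to that law's digamma/trigamma moments, with the
trigamma inversion done by Newton iteration. When the observed log-variance
spread does not exceed the χ² sampling spread the prior df is infinite
(capped at 10⁶ when forming the t df); a degenerate all-equal ensemble
returns the common value as s₀² so that moderation is a fixed point there.
The posterior variance is s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and the
moderated statistic `t = c·β / sqrt(s̃²_g · c(XᵀX)⁻¹cᵀ)` has d + d₀ df;
p-values are two-sided (sidedness is a convention choice; two-sided is the
conservative default).

**Multiple testing.** Expected-false-positive (per-family error-rate)
control: α = k/m makes the expected count of false positives among m true
nulls equal k; the reference setting is k = 4 of m = 400 genes, i.e.
α = 0.01. No Benjamini–Hochberg correction is layered on top. A gene is
called differentially expressed when additionally its fold change is ≥ 2
(or ≤ 0.5 — folds are reported on the linear scale with down-regulation as
a fraction below 1). A looser preset (1.5-fold, α = 0.05) feeds gene-set
enrichment. The calibration of the whole chain is measured, not assumed:
the acceptance script simulates null studies end-to-end and checks the mean
significant count against m·α.

**Signatures.** The per-group significant sets are decomposed into exact
Venn regions (pairwise disjoint, covering the union). RT-PCR concordance
converts ΔΔCt to fold = 2^(−ΔΔCt) and reports the fraction of genes whose
platform and PCR fold changes agree in direction.

## PCA profiling

Assays are observations, genes variables; centering on, unit scaling off by
default (log2 expression values are already on comparable scales). The SVD
of the centred matrix gives scores `U·S`, orthonormal loadings `V`, and
variance fractions `s²/Σs²`; numerically null components (e.g. the one lost
to centering) are dropped. Sign convention: each component's
largest-magnitude loading is made positive, because loading plots are
sign-sensitive. The top-k ranking (default k = 20, PC1) orders by absolute
loading with lexicographic tie-break and clamps k to the gene count.
Cluster separation is the mean silhouette of assays in a chosen score
subspace — an operationalisation of "the groups clustered separately" that
a test can assert on.

## Gene-set enrichment

One-sided hypergeometric tail P(X ≥ overlap) on the 2×2 table against a
stated background (set members intersected with the background first);
overrepresentation, not depletion, is the default test, with a two-sided
flag. Values are reported unadjusted, as −log₁₀ p. For gene sets annotated
with expected member directions, the activation z-score over the N
direction-annotated significant genes is
`z = (n_consistent − n_inconsistent)/√N`, with activated / suppressed
called at z ≥ 2 / z ≤ −2 (configurable); the proprietary pathway knowledge
base this style of scoring is associated with is replaced by user-supplied
signed GMT sets.

## Clinical statistics

Welch's t (group sizes 4–10 with no variance-homogeneity guarantee),
one-way ANOVA for multi-group comparisons, and the *exact* Wilcoxon
rank-sum test (full enumeration is feasible and correct at combined
n ≤ 12); Bonferroni adjustment `min(1, p·n_comparisons)` over the stated
comparison count. Categorical variables: two-sided Fisher's exact test by
the point-probability rule. All tests two-sided.

## Synthetic-study generator

Endogenous gene g in assay a (sample s, batch b) is negative binomial with
mean `lane_a · 2^(baseline_g + effect_{g,group(s)} + offset_{g,b})` and
dispersion 0.03; negative probes are Poisson(10 · lane_a); positive probes
follow the ladder × a calibration constant (200 counts per concentration
unit) with technical dispersion 0.005. Baselines are uniform on log2
(6, 12); lane factors are log-normal (log-SD 0.15) and fold FFPE capture
efficiency into the same multiplier; per-gene batch-2 offsets are
N(0, 0.5²). The last 111 of the 511 endogenous genes are simulated at
background level, leaving 400 expressed — the panel size the error-control
convention refers to. All randomness comes from one seeded generator
stream drawn in a fixed order, so a seed pins every count.

Default planted signatures mirror the emulated study's reported structure:
a 19-gene core shared by CR, PR and NR (12 up / 7 down at ±2 log2 — core
effect sizes are not published; ±2 is typical of interferon/complement
induction in LN kidney) plus 3 CR-unique, 20 NR-unique and 7 PR-unique
genes whose log2 effects are the log2 of the published per-group fold
changes (2.23 down to 0.11). The noise parameters were fixed from platform
characteristics (counting chemistry with ~17–20% extra-Poisson technical
CV on FFPE) before any calibration experiment was run.

**What the generator does not model.** Per-patient biological variability
(each sample's expected expression equals its group mean — the dispersion
is technical), RNA-degradation gradients along the panel, probe-specific
efficiency, cross-hybridisation, and count saturation. Passing
ground-truth-recovery tests therefore demonstrates correctness of the
algorithms under the stated noise model, not performance on real biopsies,
where between-patient heterogeneity would lower sensitivity at these group
sizes.

## Problem sizes and numerical choices

The calibration experiment uses 500 null studies of 400 genes (n = 5 vs 4),
enough for a Monte-Carlo standard error of ~0.1 on the mean false-positive
count; p-value uniformity pools ≥ 5000 null genes for the
Kolmogorov–Smirnov check; variance-smoothing recovery uses 5000 simulated
variances. Tolerances mirror estimator precision at those sizes (offset
RMSE < 0.25 at 4 anchors; planted-effect median absolute error < 0.3 log2
at n = 5 vs 4). Ties in quantile normalisation and loading ranks are broken
deterministically (rank-mean averaging; lexicographic gene order). The
trigamma inverse uses Newton iteration with the standard asymptotic
endpoints (1/x below 10⁻⁶, 1/√x above 10⁷). Degenerate inputs — constant
genes under scaling, single-assay quantile normalisation, all-zero variance
ensembles, rank-deficient designs, zero positive-control counts — raise
validation errors naming the offending object rather than proceeding.

## Known limitations

- The anchor estimator assumes batch effects are additive on log2 and
  shared by all samples in a batch; gene-specific batch × group
  interactions are not modelled.
- Expected-false-positive control bounds the *mean* number of false
  positives, not the family-wise error rate or FDR.
- The activation z-score treats member genes as independent; correlated
  pathway members inflate |z|.
- With n = 4–5 per group, a gene planted exactly at the two-fold gate is
  called significant only about half the time its p-value clears α — the
  fold filter is a reporting convention, and sensitivity statements in the
  tests are therefore made at the p-threshold gate.
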