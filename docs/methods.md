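# Methods

## Model and procedure

The pipeline tests, for every (knockout *i*, biomarker *k*) pair within a
cohort of n′ cell lines, the null hypothesis that expected essentiality is
equal in mutant and wild-type lines.  Stages:

1. **Ingestion and alignment** — essentiality, mutation and expression
   matrices are restricted to the intersection of cell-line ids (in the
   essentiality matrix's column order); ids are matched case-sensitively
   after whitespace trimming to avoid silent mismatches.  Raw variant
   tables are dichotomized per (sample, gene): the indicator is 1 iff at
   least one variant survives the filters (minimum allelic fraction 0.1;
   silent, non-coding, common-polymorphism and putative-neutral variants
   excluded — all configurable, since panel-cleaning conventions vary).
2. **Imputation** — missing essentiality entries are filled by
   nearest-neighbor averaging: the mean over the k = 10 nearest knockout
   rows (Euclidean distance on co-observed columns, scaled by the fraction
   of co-observed columns) of their values in that column, with a row-mean
   fallback when no neighbor observes the column.  Observed entries are
   never modified.
3. **Essential-gene selection** — a knockout enters testing iff it is
   essential (score ≤ −2) in ≥ 20% of cohort lines (25% in the AML preset),
   essential in ≤ 10% of non-cohort lines (cancer-type specificity), and
   expressed (> 1 TPM) in ≥ 75% of cohort lines.  The −2 cutoff is the
   conventional strong-dependency magnitude for DEMETER-like scores; the
   10% specificity ceiling quantifies "non-essential in other cancer
   types", which is otherwise qualitative.  Expression is evaluated on
   cohort samples only, because the criterion exists to guarantee the gene
   was expressed in the screened cells.
4. **Moderated t-test** — per pair, Δ = mean(mutant) − mean(wild-type) and
   an equal-variance t whose per-knockout pooled variance s²_i is shrunk
   toward a prior: posterior = (d₀s₀² + dᵢs²ᵢ)/(d₀ + dᵢ), with t gaining d₀
   degrees of freedom.  (d₀, s₀²) are estimated by moment-matching
   log s² against the scaled-F sampling model (digamma/trigamma closed
   forms, trigamma inverted by Newton iteration); the implementation
   reproduces Bioconductor limma's eBayes t and p to machine precision on
   shared inputs (cross-checked in the test suite).  Moderation is pooled
   across knockouts *within one biomarker's test family*; the pooling scope
   is a configuration choice, and per-biomarker pooling keeps each group's
   correction self-contained.  Pairs with fewer than 2 mutant or 2
   wild-type lines are emitted flagged `skipped`, never dropped silently.
   Degenerate case: when the log-variance spread is zero the prior is
   (d₀ = ∞, s₀² = geometric mean of the sample variances), so identical
   sample variances return exactly their common value.
5. **Grouped correction** — p-values are split into one group per
   biomarker.  Within each group π₀ is estimated (Storey's λ-tail family;
   the deterministic plug-in bootstrap MSE rule over λ ∈ {0.05,…,0.95} by
   default, robust at small group sizes) and the local FDR
   lfdr(p) = min(1, π₀/f(p)) is computed with a monotone mixture-density
   estimate.  Groups with fewer than 50 tests fall back to the pooled
   all-tests model and are flagged.
6. **Calling and typing** — LEDs are rows with p < 0.05, lfdr ≤ 0.6 and
   |Δ| > 2 (strict), ranked by p ascending with ties broken by |Δ|
   descending then lexicographic ids.  Δ < 0 → pLED, Δ > 0 → nLED; a
   biomarker with called partners of both signs is a dual dependency and
   all its records are promoted to dLED (their sign class is kept in a
   separate column).  The optional relation filter requires a network edge
   with combined score ≥ 400 (inclusive) between biomarker and essential
   gene (direct mode) or a shared neighbor at that score; self-pairs always
   pass.  It is off by default and on in the AML preset — it is a
   biological plausibility double-check, not a statistical one, and should
   be dropped when hunting novel relationships.

## Local-FDR density estimate

f is a quantile-binned histogram (≈ √n/12 bins, clamped to [4, 100]) fitted
under a non-increasing constraint by width-weighted isotonic regression —
the discrete Grenander estimator.  Quantile bins concentrate resolution in
the zero-peak where the mixture density moves; the bin count keeps enough
points per bin that a flat (null) histogram stays near density 1
everywhere, so null lfdr values stay near 1 rather than dipping on chance
fluctuations (the raw ECDF Grenander estimator is badly anti-conservative
at the smallest p-values).  The fit integrates to 1 by construction, so
lfdr ∈ (0, 1] and is non-decreasing in p without ad-hoc clipping.  All p
identical degenerates to lfdr = π₀ with a warning.

Consequence of the coarse-binning choice: a *pooled* analysis of a few
hundred tests with a small signal fraction cannot resolve its zero-peak —
which is the statistical reason grouping by biomarker helps, and why groups
below 50 tests (which fall back to pooling) lose the advantage.

## Covariate-weighted BH

The FDR-scale analogue applies BH at level α to p/w with per-group weights
w_g ∝ (1 − π₀_g), normalized so the test-weighted mean weight is 1.  The
critical design choice is the estimator of 1 − π₀_g.  Broad-tail estimators
(fixed λ = 0.5, or the λ-grid bootstrap) are noise-dominated at realistic
group sizes (~10² tests): lucky null groups draw weights comparable to true
hubs, and groups whose mutation pattern happens to correlate with a hub's
("shadow hubs") inherit genuine essentiality shifts, get up-weighted, and
push the realized FDR far above nominal.  The default estimator is
therefore the Storey complement at a small λ (10⁻³) — the excess fraction
of p ≤ λ over the uniform expectation, so only clearly active tests
register — zeroed unless the sub-λ count is significantly above its
uniform-null binomial expectation (Bonferroni-corrected familywise 0.05
across groups).  When no group passes the guard, or all groups carry equal
signal, every weight is 1 and the procedure is plain BH.  This is a
deliberately simple single-fit weighting over the fixed biomarker grouping;
no cross-fitted hypothesis weighting is attempted.

Measured at the simulator's default conditions (50 replicates): mean
truth-measured FDR 0.154 at nominal 0.20 with power 0.996, versus 0.38–0.47
for the broad-tail weight variants.

## Synthetic screens

`simulate_screen` emulates the generative structure the grouped analysis
presumes: per biomarker and cell line, mutation status is
Bernoulli(prevalence 0.3); per knockout, scores are baseline (−1) plus
Gaussian noise (sd 1); each of the 5 hub biomarkers shifts 40 knockouts'
scores in its mutant lines by ±3 (signs 50/50 so that pLED/nLED/dLED typing
is exercised); the remaining 95 biomarkers shift nothing.  Defaults (60
cell lines, 100 knockouts, 100 biomarkers) are a desk-scale rendering of a
screen cohort; a Student-t (5 df) noise option stresses the moderated test
with heavy tails, and the expression matrix is constant 10 TPM so the
expression filter is inert unless deliberately exercised.  With effect size
0 the generator is an exact null (p-values uniform, KS-tested in the
suite).

What the generator does *not* emulate — and what passing tests therefore do
not establish about real screens: off-target structure and screen-quality
artifacts, copy-number confounding, correlated mutation co-occurrence
(real mutational processes co-occur far more than Bernoulli columns),
heteroscedastic per-knockout noise, and cohort substructure.  One realistic
pathology it *does* reproduce, at small n: random correlations between
mutation columns leak true effects into other biomarkers' tests (the
"shadow hub" effect above), which is why the FDR guarantees are verified
empirically against planted truth rather than assumed from BH theory.

## Numerical and interface choices

- π₀ is clamped to [1/m, 1]; fewer than 20 p-values falls back to the fixed
  λ = 0.5 estimate with a warning.
- q-values: q_i = π₀ · min_{p_j ≥ p_i} m·p_j/rank(p_j); π₀ = 1 reproduces
  BH exactly.  BH/Bonferroni/Holm use statsmodels' textbook
  implementations.
- Ties in p are broken by |Δ| descending then lexicographic ids in every
  rank-based output; result tables are emitted in deterministic
  (knockout, biomarker) order, so reruns are byte-identical.
- Tests with identical group means give t = 0, p = 1; a biomarker whose
  every testable knockout has zero residual variance is an error naming the
  biomarker.
- AUROC is the rank statistic with ties averaged; AUPR is step-wise average
  precision; Fisher enrichment is the exact hypergeometric tail
  (scipy).  The top-k enrichment universe is the union of the two compared
  rankings (2k when disjoint).
- Matrix I/O accepts ""/NA/NaN as missing on read and always writes NA;
  readers accept gzip; CSV vs TSV is inferred from the extension.

## Problem sizes

Simulation-based checks use 50 replicates of the 60 × 100 × 100 default
screen (10⁴ tests per replicate) — large enough that hub structure is
resolvable per group, small enough that each replicate runs in well under a
second.  Full-scale screens (10⁶–10⁷ tests) change none of the algorithms,
only the runtime.

## Known limitations

- The moderated test assumes equal group variances within a pair; no Welch
  variant is provided.
- No covariate adjustment (tissue, MSI status, copy number) inside the
  linear model; the grouping covariate is the biomarker identity only.
- The weighted-BH FDR guarantee is empirical, not finite-sample-proven,
  because the weights are estimated from the same p-values (single fit);
  the small-λ guard is what keeps the weight/test dependence negligible.
- Per-group lfdr at group sizes just above the fallback threshold (~50–100
  tests) is noisy; the p and |Δ| gates, not the lfdr gate alone, carry the
  error control there.
- Knowledgebase matching is exact on gene symbols (plus optional one-hop
  network expansion); synonym and ontology resolution is the caller's
  responsibility.
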