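# Methods

This note documents the models, defaults and numerical choices behind
`lipidprs`, and what the synthetic cohort does and does not emulate.

## SNP quality control and panel selection

**Hardy–Weinberg exact test.** Conditional on the observed allele
counts, the heterozygote count under random mating follows the
Levene–Haldane distribution; the two-sided p-value sums the
probabilities of all heterozygote configurations no more probable than
the observed one (with a 1 + 10⁻¹² relative tolerance on the
comparison, so ties at the observed probability are included despite
floating-point rounding). Probabilities are computed with log-gamma
arithmetic and renormalised, which keeps the test exact to ~10⁻¹⁴ for
the genotype totals used here; the suite verifies agreement with an
exact-rational enumeration oracle to 10⁻¹² for totals up to 200.
Monomorphic SNPs return p = 1 (only one configuration exists). The
inclusion threshold is p ≥ 10⁻³ by default and configurable — a common
QC convention; the test flavour and α for genotype QC are a package
choice.

**MAF and LD.** Allele frequencies are computed over non-missing
dosages and folded. LD is the squared Pearson correlation of unphased
dosages over pairwise-complete subjects (composite LD): phase is not
available in dosage data, and for the pairwise r² ≥ 0.8 pruning rule
this composite estimate is the standard surrogate. A zero-variance
vector makes r² undefined; it is treated as 0 for clumping with a
logged warning, since an invariant SNP cannot be correlated with
anything.

**Association and clumping.** Per-SNP weights come from univariate
additive logistic regression of the dichotomised clinical threshold
(the weight-fitting outcome is logistic, not linear, so scores are in
log-odds units per risk allele). Clumping is the canonical greedy
p-ranked variant: survivors are sorted by ascending association p with
ties broken lexicographically by rsID (making the output invariant to
input column order), the best-ranked SNP is retained and all remaining
SNPs with r² ≥ 0.8 against it are excluded. No genome positions are
used: the panels carry no coordinates, so clumping is purely
LD-driven rather than windowed. Each excluded SNP carries exactly one
reason — its first failing filter in the order HWE → MAF → association
→ LD.

**Missing dosages** are handled pairwise-complete for r² and
mean-imputed for regression and scoring; both choices are logged.

**Separation.** A separated or non-converged univariate fit returns a
flagged non-finite β with p = 1 rather than raising; at the
weight-fitting stage such SNPs are dropped with a logged reason.

## Scoring and stratification

The wPRS is the weighted sum of risk-allele dosages. "Number of risk
alleles" is implemented by orientation: a SNP with negative fitted β has
its dosage flipped to 2 − d and its weight stored as the positive
magnitude, so all weights are non-negative and the counted allele is
always the risk allele. The high/low split uses the empirical 90th
percentile with the linear-interpolation quantile convention; membership
in the high group is by score ≥ cutoff, so ties at the cutoff can make
the high group slightly larger than 10%. Stratification of HDL scores
is within sex by default (the panels and clinical thresholds are
sex-specific); the TG score is pooled. The combined high-risk group is
the intersection of the TG-high and HDL-high sets, not a score sum.

## Association models

Linear models are OLS; logistic models are maximum-likelihood fits with
Wald 95% intervals on the log-odds scale (the reported intervals are
symmetric in log-OR). The default adjustment set is age, sex, BMI,
T2DM and CVD medical treatment; sex enters as a male indicator, and
near-duplicate covariates (|r| > 0.9999) are rejected with both names.
An unadjusted logistic fit with a single binary regressor reproduces the
closed-form 2×2 cross-product odds ratio, which the suite checks to
10⁻⁶. Results carry the event count and a sparse-data warning below 10
events per parameter; no automatic penalised (Firth-type) correction is
applied, keeping the estimates plain maximum likelihood. No
multiple-testing correction is applied by default.

**Power.** The F-test power uses noncentrality λ = f²·n (the
convention of the standard power tools for fixed-effects linear
regression), numerator df as given (default 1, the single-predictor
case) and denominator df n − df_num − 1; at f² = 0 it returns α
exactly.

## Stratified comparisons

Trait comparisons use the two-sided Mann–Whitney U test: exact null
enumeration when the smaller group has ≤ 8 observations and there are
no ties, otherwise the normal approximation with tie and continuity
corrections. Categorical compositions use the Pearson chi-square test
without continuity correction (a Yates flag is available), warning when
any expected count falls below 5. Two comparison axes are computed per
exposure: high-vs-low genetic risk within each exposure level, and
between exposure levels within each risk group. Missing exposure values
form an explicit level that is summarised but never silently dropped;
empty cells mark their comparison undefined rather than being omitted.
Binary exposure cutoffs: coffee and sugar-sweetened beverages at none
vs ≥ 1 cup/day, wine at none vs 1–3 drinks/week, obesity at
BMI ≥ 30 (inclusive), HbA1c at ≥ 5.7% (inclusive).

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
calibrated to the study's descriptive table:

* **Genotypes** are Binomial(2, p) per SNP — exact Hardy–Weinberg
  proportions. LD is induced by index-SNP copying: a dependent SNP
  copies its index's genotype with probability c and draws
  independently otherwise, giving pairwise r ≈ c. This controls the
  pairwise r² the pruning rule consumes; it is not a haplotype model.
* **Sex** is assigned by exact count (round(fraction·n) females,
  positions permuted), so the flowchart-replica cohort reproduces its
  printed composition (3861/5584 = 69.1% female) deterministically.
* **Traits.** HDL-C is normal; TG and HbA1c are lognormal (right-
  skewed), with (μ, σ) solved from the target mean/SD. Genetic, sex
  and exposure contributions are *additive in mg/dL* on top of the
  noise and are mean-centred, so the declared baseline mean is the
  marginal trait mean and baseline SDs are solved by subtracting the
  analytic shift variances from the target variances. Additive mg/dL
  effects keep the planted per-unit-score slopes exactly recoverable by
  OLS; the rare negative TG value this can produce (≈0.3% of subjects)
  is floored at 0.1 mg/dL. Default targets: TG 130.5 ± 65.8,
  HDL-C 52.9 ± 12.5, BMI 31.3 ± 5.8, HbA1c 5.1 ± 2.7, age 58.0 ± 14.2,
  total cholesterol 183.4 ± 48.6, LDL-C 109.2 ± 37.2 (mg/dL except BMI
  kg/m², HbA1c %, age years).
* **Planted genetic effects.** Each trait carries per-SNP score
  weights and a per-unit score effect (defaults −4.07 mg/dL HDL-C and
  +26.47 mg/dL TG per unit of the true weighted score); sex shifts are
  −11.5 (HDL-C) and +18.5 (TG) mg/dL for males. The per-SNP allele
  frequencies and weights are fixed plausible common-variant values.
* **Exposures** are independent Bernoulli flags at the study
  prevalences (smoking 9.1%, SSB 16.7%, coffee 75.8%, wine 30.8%,
  T2DM 8.4%, treatment 10%); obesity and high HbA1c are derived from
  their continuous traits. Exposure effects may differ between the
  high and low genetic-risk strata of their trait, supporting three
  patterns: additive (equal), amplification (larger when high) and
  ceiling (zero when high). Defaults are additive.
* **Binary outcomes** follow declared logistic models on named cohort
  columns; the default CVD model is intercept-only at logit(0.087).

A single integer seed expands into named per-stage substreams
(genotypes / phenotypes / registry), so identical (spec, seed) give
identical cohorts while stages remain independently reproducible.

What the generator does **not** emulate: realistic human LD maps,
population structure or relatedness, imputation error, genuinely
correlated lifestyle exposures (independence is assumed and
configurable only through the declared effects), measurement error in
self-reported biochemistry, or any CVD–score association unless one is
declared. Passing tests therefore demonstrate that the estimators
recover what this generative model plants at the study's sample size —
not that the substantive cohort findings generalise.

## Problem sizes used in the checks

The test suite and acceptance script run at the study's analytic size
(n = 5584) for parameter recovery, stratified-pattern and calibration
checks; CI coverage uses 500 replicates (300 in the acceptance script),
null-calibration checks use 1000–2000 replicates at n = 400–5000, and
the Monte-Carlo oracles for LD and power use 2×10⁵ and 10⁵ draws.
These sizes put Monte-Carlo error well inside the asserted tolerances
(2 SE for planted-parameter recovery, 3 SE for calibration rates).

## Known limitations

* The 43 HDL and 57 TG *candidate* SNP lists behind the shipped panels
  are not enumerated anywhere public, so the original selection cannot
  be replayed; only the retained rsID lists are packaged, and the
  alleles in those files are synthetic placeholders (weights are
  re-fitted in-cohort regardless).
* VCF support is minimal and GT-based (no INFO-field dosages, no
  PLINK binary).
* Clumping is position-blind; with dense genome-wide input a windowed
  implementation would be preferable.
* Wald intervals can undercover with very sparse events; results carry
  event counts and warnings instead of automatic corrections.
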