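# lipidprs

Weighted polygenic risk scores (wPRS) for blood lipid traits —
triglycerides (TG) and HDL cholesterol (HDL-C) — with gene–environment
stratified analysis of lifestyle and metabolic modifiers, and CVD odds
models. Written for epidemiologists and biostatisticians who want a
tested, reproducible implementation of the classic clumping-and-
thresholding PRS workflow on cohort genotype/phenotype data, plus a
synthetic cohort generator so every stage can be exercised and validated
without access to any private registry.

## The method

For each trait a SNP panel passes quality control and
clumping-and-thresholding selection:

1. **Hardy–Weinberg equilibrium**: exact conditional test per SNP
   (Levene–Haldane distribution of the heterozygote count given allele
   counts); SNPs with p < 10⁻³ are excluded.
2. **Minor allele frequency**: MAF < 0.01 excluded.
3. **Association**: univariate additive logistic regression of the
   clinical threshold outcome (TG ≥ 150 mg/dL; HDL-C < 40 mg/dL in males
   / < 50 mg/dL in females) on dosage; p ≥ 0.05 excluded.
4. **Clumping**: survivors ranked by ascending association p; the best
   SNP is retained and all remaining SNPs with composite LD r² ≥ 0.8
   against it are excluded; repeat.

Per-subject scores are then

```
wPRS_s = Σ_i  d̃_si · β̂_i
```

where `β̂_i` is the in-cohort univariate logistic log-odds ratio and
`d̃_si` the risk-allele dosage (SNPs with negative fitted β are
re-oriented so every weight is non-negative). Subjects at or above the
empirical 90th percentile of the score form the high-risk group.
Downstream analyses include per-unit linear effects of the wPRS on trait
levels (OLS, adjusted for age, sex, BMI, T2DM, and CVD medical
treatment), adjusted logistic odds ratios for threshold outcomes and
CVD, the TG/HDL-C ratio (> 2 adverse), two-axis stratified comparison
tables (Mann–Whitney U / chi-square), and noncentral-F power for
Cohen's f².

The package ships the three literature SNP panels (13 male-HDL,
10 female-HDL, 19 TG rsIDs) as TSV files; weights are always re-fitted
in-cohort.

## Worked example

```python
import lipidprs as lp

# flowchart-replica registry: 12,626 records, exclusion cascade
registry = lp.default_registry(seed=1)
survivors, report = lp.apply_exclusions(registry)
print(report.n_final)                  # 5584

# synthetic cohort at the eligible size
spec = lp.default_simspec(n_subjects=report.n_final, seed=1)
genotypes, cohort = lp.simulate_cohort(spec)
print((cohort.sex == "F").mean())      # 0.6914 (3861 females)

# SNP QC and clumping against the TG >= 150 mg/dL outcome
outcome = lp.define_threshold_outcome(cohort, "TG")
records = lp.clump_and_threshold(genotypes, outcome)
panel = lp.fit_weights(genotypes, outcome,
                       [r for r in records if r.status == "retained"])

# score, stratify at the 90th percentile, and model
scores = lp.stratify(lp.compute_wprs(genotypes, panel))
res = lp.linear_trait_on_score(cohort, scores, "tg")
print(round(res.beta, 2), round(res.p, 4))
```

Running this prints `5584`, `0.6914398280802292`, and a positive
per-unit TG effect in mg/dL with p < 0.0001 (`40.87 0.0` at seed 1): subjects with a one-unit higher fitted wPRS average that many
mg/dL more TG after covariate adjustment. The full pipeline
(`lp.run_pipeline(lp.RunConfig(...))` or `lipidprs report` on the
command line) writes every intermediate artifact — exclusion report,
dosage CSV/VCF, QC panels, weights, scores, association tables,
stratified tables — into an output directory together with a run log.

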