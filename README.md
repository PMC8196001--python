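# bilicausal

Statistical machinery for asking whether serum total bilirubin causally
protects against hypertension, using a common *UGT1A1*-region variant as the
genetic instrument. The package implements the full chain of analyses that
such a study runs — descriptive group comparisons, kinship-aware mixed-model
GWAS with conditional analysis, Bayesian fine mapping, REML SNP heritability
with LD-informed weights, additive Bayesian network structure learning, and
two-stage least-squares Mendelian randomization with instrument diagnostics,
inverse-variance-weighted meta-analysis and analytic power — and exercises
them end-to-end on synthetic cohorts whose causal architecture
(variant → bilirubin → hypertension) is fully known.

It is written for statistical geneticists and methods students who want a
compact, tested, pure-Python reference implementation of this pipeline, with
every stage checkable against the generative truth.

## The models

**Mixed-model association.** Bilirubin is residualized on age and sex, the
residuals are rank-based inverse-normal transformed
(Φ⁻¹((r − 3/8)/(n + 1/4))), and each variant is tested under

  y = Xβ + g·b + u + ε,  u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

where K is the genetic relatedness matrix from standardized dosages. The
variance components are estimated once on the null model by REML and held
fixed for the per-variant generalized-least-squares Wald tests (the EMMAX
approximation). Ancestry principal components enter as fixed effects when
their kinship eigenvalues are significant under a Tracy–Widom test. Scan
calibration is summarized by λ_GC = median(χ²)/0.4549.

**Fine mapping.** For a region with marginal z-scores z and LD matrix R, the
Bayes factor of a causal configuration c compares
z_c ~ N(0, R_cc) against z_c ~ N(0, R_cc + n·s²·R_cc R_cc), averaged over a
prior-sd grid {0.1, 0.2, 0.4}. Posteriors over all configurations up to
`max_causal` give each variant a marginal posterior inclusion probability
(PIP); binary functional annotations can tilt the per-variant prior odds.

**SNP heritability.** Var(Y) = σ²_g G + σ²_e I with G a weighted GRM, each
SNP weighted by the reciprocal of its local LD score so redundantly tagged
variants are down-weighted; ĥ²_snp = σ̂²_g/(σ̂²_g + σ̂²_e) by REML, with a
delta-method SE from the profile likelihood.

**Additive Bayesian network.** Each of seven nodes (variant dosage,
bilirubin, hypertension, sex, age, BMI, T2D) has a GLM conditional
distribution (identity or logit link); DAGs are scored by BIC-penalized
log-likelihood and searched by greedy hill climbing from random starts. The
majority consensus keeps directed edges present in ≥ 50% of searches.

**Mendelian randomization.** Stage one: OLS of exposure on instrument dosage
plus covariates (instrument strength = partial F; F > 10 rule). Stage two:
logistic regression of hypertension on the fitted exposure, giving a causal
log-odds per exposure SD. The exclusion restriction is probed by regressing
the outcome on the instrument adjusting for the exposure. Studies combine by
fixed-effect IVW; analytic power for a binary outcome uses the mRnd
non-centrality formula from (n, α, prevalence K, OR per SD, instrument R²).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
1500-sample, 5000-variant cohort (causal variant at EAF 0.49 explaining ~12%
of bilirubin variance, total exposure heritability ~0.385, hypertension
prevalence ~0.26, OR 0.46 per SD of bilirubin), caching stage outputs under
`results/run/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_gwas_scan.py
python analysis/07_mendelian_randomization.py
```

prints (abridged):

```
"realized_eaf": 0.491, "realized_iv_r2": 0.122, "realized_h2": 0.391,
"realized_prevalence": 0.2687

top variant: rs_causal  beta (SE) = 0.463 (0.040)  p = 3.07e-30
lambda_GC = 0.938; 20 significant PC(s)
conditional on rs_causal: 0 genome-wide-significant signal(s) remain

study1: F = 88.00, beta = -0.277 (-0.818, 0.265), exclusion OR = 1.22 (0.94, 1.57)
study2: F = 102.91, beta = -0.290 (-0.756, 0.176), exclusion OR = 1.15 (0.89, 1.50)
IVW combined: beta = -0.284 (-0.638, 0.069), p = 0.1147
analytic power at the realized design: 0.968
```

Reading the output: the scan finds exactly the planted variant (β is on the
SD scale of the transformed trait; λ_GC near 1 indicates a calibrated scan),
conditioning on it removes all genome-wide-significant signal, the
instrument is strong in both half-cohorts (F ≫ 10), the exclusion
diagnostic CIs include OR = 1, and the combined causal estimate is negative
(higher bilirubin, lower hypertension odds). At this demo size the causal CI
is wide; this particular draw does not reach p < 0.05 even though average
power at the design is high — the repeated-cohort experiments in
`tests/test_acceptance.py` show the estimator's coverage across 100
replicates at the full study size. `analysis/04_fine_mapping.py` gives the
planted variant a PIP of ~1.0, and `analysis/06_bayesian_network.py`
recovers the mediation topology variant → bilirubin → hypertension with no
direct variant → hypertension edge.

The same stages are available as a CLI (`bilicausal simulate|table1|gwas|
finemap|h2|abn|mr|meta|power|run`); `bilicausal run --config cfg.yaml`
executes everything with digest-based stage caching and writes a
reproducibility manifest.

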