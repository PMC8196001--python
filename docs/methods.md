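# Methods

This note documents the models implemented in `bilicausal`, the synthetic
cohort that exercises them, the numerical choices, and what the passing
tests do and do not establish about real data.

## Synthetic cohort

The generator (`bilicausal.simdata`) produces the data structure every
downstream stage assumes, with all generative quantities recorded so
recovery can be tested exactly.

**Genotypes.** Variants sit on one chromosome at fixed spacing (default
10 kb) in LD blocks of `ld_block_size` (default 20). Within a block,
haplotype alleles come from a Gaussian copula: a compound-symmetric latent
normal with correlation `within_block_rho` (default 0.7), thresholded at
Φ⁻¹(allele frequency). Thresholding attenuates the latent correlation (a
phi-coefficient effect), so realized genotype r² within blocks is roughly
0.1–0.25 at the default settings — weaker than the latent 0.7, which is the
tunable knob, not the realized value. Subpopulation allele frequencies
follow the Balding–Nichols model: for ancestral frequency p and divergence
F_ST, subpopulation frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F). Defaults
are two subpopulations at F_ST = 0.02, the mild structure expected between
two West African recruitment sites. The causal variant is pinned at its
configured frequency (0.49) in every subpopulation so the instrument's
frequency is controlled. Cryptic relatedness comes from full-sib pairs
(default 50 of 2000 samples): each pair draws whole haplotypes from four
shared parental haplotypes — no recombination, so sibs share 0, 1 or 2
haplotypes per locus.

**Exposure.** The standardized exposure is

X = a·Z + polygenic + covariate effects + 0.3·U + noise,

with the causal term rescaled in-sample so Var(a·Z)/Var(X) equals
`target_iv_r2` (default 0.12) and the polygenic term rescaled to
`polygenic_h2` (default 0.265); total exposure SNP heritability is their sum,
0.385. The polygenic background is spread over half of the variants
*outside* the causal variant's LD block, so the causal locus carries exactly
one association signal — matching the single-signal conditional-analysis
design the pipeline is meant to reproduce. Covariate effects default to a
male–female bilirubin difference of +0.25 SD (men higher), small age and BMI
slopes; the confounder U is standard normal with loadings 0.3 on X and 0.5
on the outcome liability, large enough that naive regression is visibly
biased. Reported bilirubin is an affine map of X to a plausible mg/dL scale
(mean 0.55, SD 0.22, floored at 0.01); every analysis is scale-free (INT or
log transform), and truth records use the standardized scale.

**Outcome.** Hypertension is Bernoulli with
logit P(Y=1) = α + log(OR_per_SD)·X/SD(X) + 0.5·U + covariate effects,
OR_per_SD = 0.46 by default. α is solved by bisection on the
population-averaged logistic mean to tolerance 1e-4, so realized prevalence
matches the 0.26 target in expectation. `log_or_per_sd` is deliberately the
**conditional** (on U and covariates) coefficient, exactly as written; see
"Non-collapsibility" below for what that implies for two-stage estimates.

**What the generator does not emulate:** recombination and coalescent LD
decay, imputation uncertainty (info scores are consumed, never produced),
X-chromosome inheritance, missingness patterns, and measurement error in the
exposure. Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed model classes, not robustness to every
real-data pathology.

## Trait preparation and mixed-model scan

Bilirubin is regressed on age and sex; the residuals are rank-based
inverse-normal transformed with the Blom offset c = 3/8 (configurable), ties
receiving average ranks. The scan holds the REML variance components of the
null model fixed (one eigendecomposition of K; Brent search over the log
variance ratio on [−12, 12] after a 64-point grid, with a Newton polish so
the interior score gradient is < 1e-9) and tests each variant by GLS using
the Frisch–Waugh projection in the rotated space — the EMMAX approximation.
Per-variant residual scale is re-estimated, so with K = I the scan reduces
*exactly* to per-variant OLS with t-distributed p-values (tested to 1e-6
relative). Wald tests are reported because the target analyses report β and
SE. Conditional scans append the index variant's dosage to the fixed
effects; perfect proxies of it become collinear and are returned flagged
with NaN statistics rather than dropped silently.

Ancestry PC count uses sequential Tracy–Widom tests of kinship eigenvalues
with Patterson's moment-matched effective marker count. TW1 p-values come
from Chiani's shifted-gamma approximation (shape 46.446, scale 0.18605,
shift 9.84801; CDF accurate to ~1e-3), entirely adequate for an α = 0.05
eigenvalue test. With LD and family structure present the TW test is
intentionally liberal (it detects real eigenstructure, including family
axes), so the demo cohort selects many PCs; this costs degrees of freedom
but not validity.

Known LMM subtlety: testing variants that are themselves in the GRM deflates
their statistics (proximal contamination). The calibration experiments
therefore build the GRM from a disjoint half of the panel
(leave-out-the-tested-region convention), which restores nominal type-I
error (0.059 at α = 0.05 over 10⁴ null tests) while naive OLS on the same
related cohort rejects at 0.087.

## Heritability

Weights are inverse local LD scores: w_j = 1/Σ_{k∈window(j)} r²_jk with the
self term included (window 1 Mb default), computed by banded lag
accumulation. This is a deliberate simplification of LDAK's
quadratic-program weights that preserves the qualitative behaviour
(redundantly tagged SNPs down-weighted; perfect duplicates split weight
exactly). The weighted GRM is K = ZWZᵀ/Σw, which reduces bit-exactly to the
unweighted GRM at unit weights and is invariant to weight rescaling. REML
uses the same eigendecomposition machinery as the scan; the SE of h² is the
inverse observed information of the profile restricted likelihood in h²
(central differences, step 1e-4); boundary estimates are flagged and a
101-point grid search agrees with the optimizer to 3 decimals on small
fixtures. MAF > 0.05 and no MAF-dependent effect-size scaling (plain
standardization); the trait enters log-transformed by convention with age,
sex, BMI and T2D covariates. Note that because the simulated trait is
additive on the *linear* scale, REML on log bilirubin is attenuated
(~0.27 vs 0.385 generative); recovery experiments therefore run on the
linear scale, and the log convention is kept for the pipeline as the
field-standard treatment of a right-skewed assay.

## Fine mapping

Log Bayes factors use log-scale multivariate normal algebra with
`solve`/`slogdet` (never explicit inverses); singular LD submatrices are
ridge-regularized starting at 1e-8 with the epsilon logged. The prior-sd
grid default {0.1, 0.2, 0.4} is averaged with equal weights on the natural
scale. Configuration priors are independent Bernoulli with π = 1/m by
default; annotations act as fixed multiplicative prior-odds factors (no
annotation-weight estimation). `max_causal` defaults to 1 — the analyses
this package targets found a single signal — and enumeration is guarded at
10⁶ configurations. With max_causal = 1 the posterior satisfies
P(null) + Σ PIP = 1 to 1e-10, and the implementation matches an independent
scipy-density enumeration oracle to 1e-12 at m = 8.

## Bayesian network

Node scores are GLM log-likelihoods minus (k/2)·log n. Gaussian nodes use
the closed-form normal likelihood at the MLE variance (k counts
coefficients plus the variance); bernoulli nodes use a logistic fit with a
ridge-stabilized fallback on separation or non-convergence, so degenerate
fits yield finite flagged scores instead of crashes. Collinear parent
columns are detected by pivoted QR and dropped, so duplicated parents score
as one. Search is steepest-ascent hill climbing over add/delete/reverse
moves from a random sparse start (edge probability 0.15), deterministic
given the seed; moves are screened by an ancestor walk so every returned
structure is acyclic (asserted). Consensus runs `n_searches` independent
searches (default 200 — a desk-scale stand-in for the 20,000 a production
run would use; the consensus is already stable at 200 on the test
scenarios), sharing one score cache, with directed edges kept at frequency
≥ threshold (default 0.5). Genotype nodes are constrained parentless
(fixed at conception); max_parents defaults to 4.

## Mendelian randomization

Two-stage predictor substitution: stage one OLS of exposure on instrument
dosage plus covariates (partial F and partial R² for the instrument alone);
stage two logistic regression of the outcome on the fitted exposure plus the
same covariates. The naive ML SE is primary; a joint bootstrap (resampling
rows and redoing both stages) is available because plug-in SEs ignore
first-stage uncertainty. An identity-link second stage is provided and
equals the Wald ratio β_ZY/β_ZX exactly in the single-instrument,
no-covariate case (tested to 1e-10).

**Non-collapsibility.** Because the outcome model is logistic, the
two-stage estimate targets the effect *marginalized* over the unexplained
exposure residual and the confounder. With a 12%-R² instrument this omitted
liability variance is ≈ 0.53, so the estimand is attenuated by ≈ 9% relative
to the conditional log-odds coefficient (measured: mean estimate −0.700 vs
conditional −0.777 over 100 replicate cohorts at n = 3000, with the
empirical SD matching the naive SE). Confidence-interval coverage of the
*conditional* parameter is therefore ≈ 88–91% rather than 95% — an inherent
property of predictor-substitution MR with binary outcomes, not an
implementation defect; coverage of the estimator's own asymptotic estimand
is nominal.

**Exclusion diagnostic.** Regressing the outcome on the instrument while
adjusting for the exposure tests the no-direct-path assumption, but the
exposure is a collider between the instrument and any unmeasured confounder:
with the default confounder loadings the diagnostic's CI covers OR = 1 in
only ~77/100 valid-instrument replicates, versus ~96/100 when no such
confounder exists. The coverage guarantee holds in the no-open-backdoor
case; under confounding the diagnostic is mildly anti-conservative — a
limitation shared by the analysis design this package reproduces.

**Meta-analysis and power.** Fixed-effect IVW with Cochran's Q and I².
Analytic binary-outcome power follows the mRnd formulation: the odds ratio
per exposure SD is mapped to a risk-scale effect b = K(OR/(1 + K(OR−1)) − 1)
at prevalence K, its variance is (K(1−K) − b²)/(N·R²), and power is the
upper tail of a noncentral χ²(1) at the α threshold. At R² → 0 power equals
α exactly. The formula agrees with a 2000-replicate simulation oracle within
0.015 at a mid-power design (n = 500, OR = 0.6, R² = 0.05).

## Pipeline

Stages run in dependency order (simulate → table1 → gwas → conditional →
finemap → h2 → abn → mr → meta → power). Each stage's cache key is the
SHA-256 of its config block, the seed, and its input-file digests; a stage
is skipped when the key and its recorded output digests are unchanged, so an
unchanged rerun recomputes nothing and outputs are byte-identical across
directories given the same seed. The manifest records the config snapshot,
package version, per-stage wall time, file digests and the realized
generative parameters of the simulated cohort. The MR stage splits the
cohort into two pseudo-studies and combines them by IVW, mirroring a
two-study design; the exposure is standardized so the causal β is per SD.
Demo problem sizes (1500 samples × 5000 variants; 200 network searches) keep
a full run to well under a minute on one CPU while leaving every stage's
statistical behaviour testable.

## Descriptive statistics

Group comparisons use Pearson chi-square tests *without* continuity
correction (goodness-of-fit for the group split, 2×2 independence for binary
traits) and Welch's unequal-variance t with Satterthwaite df for continuous
traits, computable from printed group summaries alone. These exact
conventions are required to reproduce published descriptive p-values; with
Yates correction or a pooled-variance t they do not match. The 2×2 statistic
equals n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) algebraically, which is tested as an
identity.

## Known limitations

- Single-variance-component EMMAX approximation: no per-variant REML, no
  logistic mixed models, no rare-variant tests.
- LD weights are inverse local LD scores, not LDAK's exact solver output.
- ABN scores are BIC approximations to exact marginal likelihoods; edge
  frequencies are search-frequency votes, not posterior probabilities.
- Fine mapping enumerates configurations (guarded at 10⁶); no stochastic
  search or credible-set machinery.
- 2SPS MR with a binary outcome estimates a marginal, slightly attenuated
  effect (see above); no MR-Egger/weighted-median pleiotropy-robust
  estimators.
- The hypertension indicator is an abstract binary outcome; no distinction
  between threshold- and medication-based definitions.
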