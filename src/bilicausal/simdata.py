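"""Synthetic cohort generator.

Produces genotype/phenotype data with the statistical structure the
downstream analyses assume: one common causal variant for the exposure
(serum bilirubin), a polygenic background, LD blocks, two-subpopulation
structure (Balding-Nichols), cryptic relatedness through sibling pairs, a
shared confounder of exposure and outcome, and a binary outcome
(hypertension) generated from a logistic model on the standardized exposure.

Default parameters mirror the study architecture: causal effect-allele
frequency 0.49, 12% of exposure variance explained by the causal variant,
total exposure SNP heritability 0.385 (so a polygenic share of 0.265),
outcome prevalence 0.26, and an outcome odds ratio of 0.46 per SD of
exposure (log OR ~ -0.777).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix, PhenotypeTable


@dataclass
class SimConfig:
    """Generative parameters for a simulated cohort.

    ``target_iv_r2`` is the fraction of exposure variance explained by the
    causal variant (the instrument); ``polygenic_h2`` is the additional
    fraction explained by the polygenic background, so total exposure SNP
    heritability is their sum. ``exposure_effect`` is only used when
    ``target_iv_r2`` is None (fixed per-allele effect instead of a
    calibrated one).
    """

    n_samples: int = 2000
    n_variants: int = 5000
    causal_index: int = 2500
    causal_eaf: float = 0.49
    exposure_effect: float = 0.59
    target_iv_r2: float | None = 0.12
    polygenic_h2: float = 0.265
    outcome_prevalence: float = 0.26
    log_or_per_sd: float = math.log(0.46)
    ld_block_size: int = 20
    within_block_rho: float = 0.7
    n_subpops: int = 2
    fst: float = 0.02
    n_sib_pairs: int = 50
    seed: int = 42
    # confounder U loadings on exposure and outcome liability
    confounder_on_x: float = 0.3
    confounder_on_y: float = 0.5
    # covariate effects on the standardized exposure (male > female bilirubin)
    sex_effect_x: float = 0.25
    age_effect_x: float = 0.005
    bmi_effect_x: float = -0.01
    # covariate effects on the outcome log-odds
    sex_effect_y: float = 0.1
    age_effect_y: float = 0.03
    bmi_effect_y: float = 0.05
    # fraction of non-causal variants carrying polygenic effects
    polygenic_fraction: float = 0.5
    # base-pair spacing between adjacent variants (one chromosome)
    variant_spacing_bp: int = 10_000
    # optional direct instrument -> outcome path (pleiotropy), log-odds per allele
    direct_z_on_y: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0 <= self.causal_index < self.n_variants:
            raise ValueError("causal_index out of range")
        if not 0 < self.causal_eaf < 1:
            raise ValueError("causal_eaf must be in (0, 1)")
        iv_r2 = self.target_iv_r2 or 0.0
        if not 0 <= iv_r2 < 1:
            raise ValueError("target_iv_r2 must be in [0, 1)")
        if not 0 <= self.polygenic_h2 < 1:
            raise ValueError("polygenic_h2 must be in [0, 1)")
        if iv_r2 + self.polygenic_h2 >= 1:
            raise ValueError("polygenic_h2 + target_iv_r2 must be < 1")
        if not 0 < self.outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.n_sib_pairs < 0 or 2 * self.n_sib_pairs > self.n_samples:
            raise ValueError("n_sib_pairs must satisfy 0 <= 2*n_sib_pairs <= n_samples")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: dict = field(default_factory=dict)
    config: SimConfig | None = None


def _haplotypes(rng, freqs_per_subpop, subpop, block_size, rho, n_hap_per_sample, n):
    """Gaussian-copula haplotypes: latent MVN with compound symmetry per block."""
    m = freqs_per_subpop.shape[1]
    total_haps = n * n_hap_per_sample
    haps = np.empty((total_haps, m), dtype=np.int8)
    sub_of_hap = np.repeat(subpop, n_hap_per_sample)
    thresholds = stats.norm.ppf(freqs_per_subpop)  # allele=1 if latent < threshold
    sqrt_rho = math.sqrt(rho)
    sqrt_1mr = math.sqrt(1.0 - rho)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        width = stop - start
        if rho > 0:
            shared = rng.standard_normal((total_haps, 1))
            latent = sqrt_rho * shared + sqrt_1mr * rng.standard_normal((total_haps, width))
        else:
            latent = rng.standard_normal((total_haps, width))
        haps[:, start:stop] = latent < thresholds[sub_of_hap, start:stop]
    return haps


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate a genotype panel with LD blocks, structure, and relatedness.

    Variants sit on one chromosome at fixed spacing and are grouped in LD
    blocks; within a block, haplotype alleles come from a Gaussian copula
    with latent correlation ``within_block_rho``. Subpopulation allele
    frequencies follow the Balding-Nichols model with divergence ``fst``
    (the causal variant is pinned at ``causal_eaf`` in every subpopulation
    so the instrument frequency is controlled). The first ``2*n_sib_pairs``
    samples form full-sib pairs drawing whole haplotypes from shared
    parents. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants

    ancestral = rng.uniform(0.05, 0.95, size=m)
    ancestral[config.causal_index] = config.causal_eaf
    if config.fst > 0 and config.n_subpops > 1:
        a = ancestral * (1.0 - config.fst) / config.fst
        b = (1.0 - ancestral) * (1.0 - config.fst) / config.fst
        freqs = rng.beta(a, b, size=(config.n_subpops, m))
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
        freqs[:, config.causal_index] = config.causal_eaf
    else:
        freqs = np.tile(ancestral, (config.n_subpops, 1))

    subpop = rng.integers(0, config.n_subpops, size=n)
    # sib pairs share a subpopulation (families do not straddle subpops)
    for k in range(config.n_sib_pairs):
        subpop[2 * k + 1] = subpop[2 * k]

    # unrelated portion: 2 haplotypes per sample
    haps = _haplotypes(rng, freqs, subpop, config.ld_block_size,
                       config.within_block_rho, 2, n)
    dosage = (haps[0::2, :] + haps[1::2, :]).astype(float)

    # sib pairs: draw 4 parental haplotypes, each child takes one per parent
    if config.n_sib_pairs:
        pair_sub = subpop[: 2 * config.n_sib_pairs : 2]
        parental = _haplotypes(rng, freqs, pair_sub, config.ld_block_size,
                               config.within_block_rho, 4, config.n_sib_pairs)
        for k in range(config.n_sib_pairs):
            pat = parental[4 * k : 4 * k + 2]
            mat = parental[4 * k + 2 : 4 * k + 4]
            for c in range(2):
                child = pat[rng.integers(2)] + mat[rng.integers(2)]
                dosage[2 * k + c, :] = child

    samples = [f"S{i:05d}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * config.variant_spacing_bp,
            "id": [f"var{j:05d}" for j in range(m)],
            "ref": "A",
            "alt": "G",
            "eaf": dosage.mean(axis=0) / 2.0,
            "info": np.nan,
        }
    )
    variants.loc[config.causal_index, "id"] = "rs_causal"
    g = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    g.subpop = subpop  # carried for diagnostics; not part of the public type
    return g


def _scale_to_sd(x: np.ndarray, sd: float) -> np.ndarray:
    """Center and rescale a component to an exact in-sample SD."""
    x = x - x.mean()
    s = x.std()
    if s == 0:
        return np.zeros_like(x) if sd == 0 else x  # degenerate: leave at zero
    return x * (sd / s)


def _solve_intercept(eta_no_intercept: np.ndarray, prevalence: float,
                     tol: float = 1e-4) -> float:
    """Bisection on the population-averaged logistic mean."""

    def mean_p(alpha: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(alpha + eta_no_intercept)))).mean())

    lo, hi = -30.0, 30.0
    if not (mean_p(lo) <= prevalence <= mean_p(hi)):
        raise RuntimeError("intercept solver failed to bracket the target prevalence")
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if abs(mean_p(mid) - prevalence) < tol:
            return mid
    return 0.5 * (lo + hi)


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig) -> PhenotypeTable:
    """Simulate exposure, covariates, confounder, and binary outcome.

    The standardized exposure is X = a*Z + polygenic + covariate effects +
    U + noise, with the causal and polygenic components rescaled so their
    in-sample variance shares equal ``target_iv_r2`` and ``polygenic_h2``.
    The outcome is Bernoulli with logit P(Y=1) = alpha + log_or_per_sd *
    X/SD(X) + confounder and covariate terms; alpha is solved by bisection
    so the population-averaged prevalence matches ``outcome_prevalence``.
    The confounder U loads on both X and Y, so naive regression of Y on X
    is biased.
    """
    config.validate()
    if config.causal_index >= genotypes.n_variants:
        raise ValueError("causal_index out of range for the supplied genotypes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = genotypes.n_samples
    z = genotypes.dosage[:, config.causal_index]

    # covariates: male fraction, age and BMI distributions as in a West
    # African adult cohort; T2D is common because of case enrichment
    sex = (rng.random(n) < 0.33).astype(int)  # 1 = male
    age = rng.normal(55.3, 12.8, size=n)
    bmi = np.clip(rng.normal(30.0, 5.9, size=n) - 4.5 * sex, 14, 60)  # males lower
    t2d = (rng.random(n) < 0.54).astype(int)
    u = rng.standard_normal(n)

    iv_r2 = config.target_iv_r2
    if iv_r2 is None:
        causal_term = config.exposure_effect * (z - z.mean())
    else:
        causal_term = _scale_to_sd(z, math.sqrt(iv_r2))
    realized_iv_var = float(causal_term.var())

    if config.polygenic_h2 > 0 and genotypes.n_variants > 1:
        # the causal variant's whole LD block is excluded from the polygenic
        # background, so the locus carries a single association signal
        block = config.causal_index // config.ld_block_size
        lo = block * config.ld_block_size
        hi = min(lo + config.ld_block_size, genotypes.n_variants)
        others = np.setdiff1d(np.arange(genotypes.n_variants), np.arange(lo, hi))
        if others.size == 0:
            others = np.setdiff1d(np.arange(genotypes.n_variants),
                                  [config.causal_index])
        k = max(1, int(round(config.polygenic_fraction * others.size)))
        chosen = rng.choice(others, size=k, replace=False)
        effects = rng.standard_normal(k)
        raw = genotypes.dosage[:, chosen] @ effects
        poly = _scale_to_sd(raw, math.sqrt(config.polygenic_h2))
    else:
        poly = np.zeros(n)

    cov_x = (
        config.sex_effect_x * (sex - sex.mean())
        + config.age_effect_x * (age - age.mean())
        + config.bmi_effect_x * (bmi - bmi.mean())
    )
    conf_x = config.confounder_on_x * u
    explained = realized_iv_var + config.polygenic_h2 + conf_x.var() + cov_x.var()
    noise_var = 1.0 - explained
    if noise_var <= 0:
        raise ValueError(
            f"variance budget exceeded: explained fraction {explained:.3f} >= 1"
        )
    noise = _scale_to_sd(rng.standard_normal(n), math.sqrt(noise_var))
    x = causal_term + poly + cov_x + conf_x + noise

    sd_x = x.std()
    eta = (
        config.log_or_per_sd * (x / sd_x)
        + config.confounder_on_y * u
        + config.sex_effect_y * (sex - sex.mean())
        + config.age_effect_y * (age - age.mean())
        + config.bmi_effect_y * (bmi - bmi.mean())
        + config.direct_z_on_y * (z - z.mean())
    )
    alpha = _solve_intercept(eta, config.outcome_prevalence)
    p_y = 1.0 / (1.0 + np.exp(-(alpha + eta)))
    y = (rng.random(n) < p_y).astype(int)

    bilirubin = np.maximum(0.55 + 0.22 * x, 0.01)  # mg/dL-like positive scale

    df = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "bilirubin": bilirubin,
            "hypertension": y,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "t2d": t2d,
        }
    )
    pheno = PhenotypeTable(df)
    var_x = float(x.var())
    pheno.components = {  # generative components, for realized_truth
        "x_std": x,
        "u": u,
        "causal_var": realized_iv_var,
        "poly_var": float(poly.var()),
        "var_x": var_x,
        "alpha": alpha,
        "expected_prevalence": float(p_y.mean()),
    }
    return pheno


def realized_truth(cohort: SimulatedCohort) -> dict:
    """Recompute realized generative quantities from the simulated data.

    realized_iv_r2 and realized_h2 come from the variance decomposition of
    the generative components; realized_prevalence is exactly mean(Y).
    """
    comp = getattr(cohort.phenotypes, "components", None)
    if comp is None:
        raise ValueError("cohort phenotypes lack generative components")
    cfg = cohort.config
    eaf = float(cohort.genotypes.dosage[:, cfg.causal_index].mean() / 2.0)
    return {
        "realized_eaf": eaf,
        "realized_iv_r2": comp["causal_var"] / comp["var_x"],
        "realized_h2": (comp["causal_var"] + comp["poly_var"]) / comp["var_x"],
        "realized_prevalence": float(np.mean(cohort.phenotypes.df["hypertension"])),
        "expected_prevalence": comp["expected_prevalence"],
        "outcome_intercept": comp["alpha"],
    }


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Genotypes + phenotypes + realized truth in one call."""
    g = simulate_genotypes(config)
    p = simulate_phenotypes(g, config)
    cohort = SimulatedCohort(genotypes=g, phenotypes=p, config=config)
    cohort.truth = realized_truth(cohort)
    cohort.truth["config"] = asdict(config)
    return cohort
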