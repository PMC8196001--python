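"""SNP-based heritability by REML with LD-informed SNP weights.

The variance-component model is Var(Y) = sigma_g^2 G + sigma_e^2 I, with G a
kinship matrix built from *weighted* standardized genotypes. Each SNP's
weight is the reciprocal of its local LD score (sum of r^2 with neighbours in
a physical window, self included), so redundantly tagged SNPs are
down-weighted — a simplification of LDAK's quadratic-program weights that
preserves the down-weighting behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._reml import reml_fit, profile_rll
from .assoc import KinshipMatrix, standardized_dosage
from .genio import GenotypeMatrix


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2_snp: float
    se_h2: float
    loglik: float
    n_iter: int
    boundary: bool = False


def ld_weights(g: GenotypeMatrix, window_bp: int = 1_000_000) -> np.ndarray:
    """Inverse local-LD-score weights: w_j = 1 / sum_{k in window} r^2_jk.

    The self term (r^2 = 1) is included, so weights are at most 1; perfectly
    tagged duplicates split weight equally. Variants must be position-sorted
    within chromosome.
    """
    pos = g.variants["pos"].to_numpy()
    chrom = g.variants["chrom"].to_numpy()
    m = g.n_variants
    for c in np.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            raise ValueError("variants must be position-sorted within chromosome")

    dos = g.dosage
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (dos - mu) / sd_safe
    n = z.shape[0]

    ld_score = np.ones(m)  # self term
    ld_score[sd == 0] = 1.0
    # banded accumulation: correlations between columns at lag d
    max_lag = m - 1
    for d in range(1, max_lag + 1):
        same_chrom = chrom[:-d] == chrom[d:]
        within = (pos[d:] - pos[:-d] <= window_bp) & same_chrom
        if not within.any():
            # lags only grow in physical distance within a chromosome, but a
            # new chromosome resets distance, so only stop when no pair at
            # this lag shares a chromosome
            if not same_chrom.any():
                break
            continue
        r = (z[:, :-d] * z[:, d:]).sum(axis=0) / n
        r2 = r**2
        contrib = np.where(within, r2, 0.0)
        ld_score[: m - d] += contrib
        ld_score[d:] += contrib
    return 1.0 / ld_score


def weighted_kinship(g: GenotypeMatrix, weights: np.ndarray) -> KinshipMatrix:
    """K = Z W Z^T / sum(w) with W the diagonal weight matrix.

    With unit weights this reduces exactly to the unweighted kinship
    Z Z^T / m; scaling all weights by a constant leaves K unchanged, and the
    mean diagonal stays ~1 under Hardy-Weinberg standardization.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != g.n_variants:
        raise ValueError("one weight per variant required")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite and nonnegative")
    total = weights.sum()
    if total == 0:
        raise ValueError("all weights are zero")
    z, keep = standardized_dosage(g, maf_min=0.0)
    w = weights[keep]
    k = (z * w) @ z.T / w.sum()
    return KinshipMatrix(matrix=k, samples=list(g.samples))


def reml_h2(y: np.ndarray, k: KinshipMatrix, covariates: np.ndarray,
            return_fit: bool = False):
    """REML estimate of SNP heritability under Var(Y) = sg^2 K + se^2 I.

    The SE of h^2 comes from the observed information of the profile
    restricted likelihood in h^2 (delta method on the variance ratio).
    Boundary estimates (h^2 ~ 0 or ~ 1) are flagged.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    fit = reml_fit(y, c, k=k.matrix)

    # observed information in h2 by central differences on the profile RLL
    y_rot = fit.eigvecs.T @ y
    x_rot = fit.eigvecs.T @ c
    h2 = fit.h2
    step = min(1e-4, h2 / 2 if h2 > 0 else 1e-4, (1 - h2) / 2 if h2 < 1 else 1e-4)
    if step > 0 and not fit.boundary:
        f0 = profile_rll(h2, fit.eigvals, y_rot, x_rot)
        fp = profile_rll(h2 + step, fit.eigvals, y_rot, x_rot)
        fm = profile_rll(h2 - step, fit.eigvals, y_rot, x_rot)
        info = -(fp - 2 * f0 + fm) / step**2
        se = math.sqrt(1.0 / info) if info > 0 else float("nan")
    else:
        se = float("nan")
    vc = VarianceComponents(
        sigma_g2=fit.sigma_g2,
        sigma_e2=fit.sigma_e2,
        h2_snp=fit.h2,
        se_h2=se,
        loglik=fit.loglik,
        n_iter=fit.n_iter,
        boundary=fit.boundary,
    )
    return (vc, fit) if return_fit else vc


def h2_pipeline(g: GenotypeMatrix, pheno_df, trait: str = "bilirubin",
                covars: tuple = ("sex", "age", "bmi", "t2d"),
                maf_min: float = 0.05, window_bp: int = 1_000_000,
                log_trait: bool = True) -> VarianceComponents:
    """Genotype-to-h2 convenience wrapper: filter MAF, weight, REML.

    Defaults follow the analysis convention: common variants (MAF > 0.05)
    and log-transformed bilirubin with age, sex, BMI and T2D covariates.
    """
    from .genio import filter_variants

    gf = filter_variants(g, maf_min=maf_min, info_min=0.0)
    w = ld_weights(gf, window_bp=window_bp)
    k = weighted_kinship(gf, w)
    yv = pheno_df[trait].to_numpy(dtype=float)
    if log_trait:
        yv = np.log(np.maximum(yv, 1e-6))
    c = np.column_stack([np.ones(len(yv))] +
                        [pheno_df[k_].to_numpy(dtype=float) for k_ in covars])
    return reml_h2(yv, k, c)
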