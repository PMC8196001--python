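"""Kinship-aware genome-wide association.

The trait is prepared in two steps (regress on age and sex, then rank-based
inverse-normal transform of the residuals), variance components are
estimated once on the null model by REML, and each variant is tested by a
generalized-least-squares Wald test with the spectral decomposition of
sigma_g^2 K + sigma_e^2 I held fixed — the EMMAX approximation. The number
of ancestry principal components is chosen with Tracy-Widom tests of the
leading kinship eigenvalues (Patterson normalization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import reml_fit
from .genio import GenotypeMatrix

# Chiani (2014) shifted-gamma approximation to the Tracy-Widom F1 law
_TW1_K = 46.44604884387787
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848007781128567

#: median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

GENOME_WIDE_P = 5e-8


@dataclass
class KinshipMatrix:
    matrix: np.ndarray
    samples: list[str]

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("kinship matrix not symmetric")
        w = np.linalg.eigvalsh(m)
        if w.min() < -1e-8:
            raise ValueError(f"kinship matrix not PSD: min eigenvalue {w.min():.3g}")


@dataclass
class AssocResult:
    df: pd.DataFrame  # chrom pos id ea oa eaf beta se p n (+ flags)
    lambda_gc: float
    h2_null: float = float("nan")
    delta: float = float("nan")
    extras: dict = field(default_factory=dict)


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on a covariate matrix (include the intercept)."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if np.isnan(y).any() or np.isnan(c).any():
        raise ValueError("missing values must be resolved before residualizing")
    rank = np.linalg.matrix_rank(c)
    if rank < c.shape[1]:
        raise ValueError(f"rank-deficient covariates: rank {rank} < {c.shape[1]} columns")
    beta, *_ = np.linalg.lstsq(c, y, rcond=None)
    return y - c @ beta


def rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - c)/(n - 2c + 1)).

    Blom offset c = 3/8 by default; ties get average ranks.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.all(values == values[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def prepare_trait(pheno_df: pd.DataFrame, trait: str = "bilirubin",
                  resid_covars: tuple = ("age", "sex")) -> np.ndarray:
    """Two-step trait preparation: residualize on age/sex, then INT."""
    y = pheno_df[trait].to_numpy(dtype=float)
    c = np.column_stack([np.ones(len(y))] +
                        [pheno_df[k].to_numpy(dtype=float) for k in resid_covars])
    return rank_inverse_normal(residualize(y, c))


def standardized_dosage(g: GenotypeMatrix, maf_min: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized dosages: center 2*EAF, scale sqrt(2*EAF*(1-EAF)).

    Returns (Z, keep_mask); monomorphic variants and MAF < maf_min are dropped.
    """
    eaf = g.eaf_from_dosage()
    maf = np.minimum(eaf, 1 - eaf)
    keep = (maf > 0) & (maf >= maf_min)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic variants pass the MAF filter")
    e = eaf[keep]
    z = (g.dosage[:, keep] - 2.0 * e) / np.sqrt(2.0 * e * (1.0 - e))
    return z, keep


def kinship(g: GenotypeMatrix, maf_min: float = 0.01) -> KinshipMatrix:
    """Genetic relatedness matrix K = Z Z^T / m from standardized dosages."""
    z, keep = standardized_dosage(g, maf_min)
    k = (z @ z.T) / keep.sum()
    return KinshipMatrix(matrix=k, samples=list(g.samples))


def tw_pvalue(x: float) -> float:
    """Upper-tail p under the Tracy-Widom F1 law (shifted-gamma approximation)."""
    return float(stats.gamma.sf(x + _TW1_ALPHA, _TW1_K, scale=_TW1_THETA))


def tracy_widom_stats(eigvals: np.ndarray, max_k: int = 20) -> pd.DataFrame:
    """Sequential Tracy-Widom statistics for leading eigenvalues.

    At step i, the i-th eigenvalue is tested as the leading eigenvalue of the
    remaining spectrum using Patterson's moment-matched effective marker
    count.
    """
    lam = np.sort(np.asarray(eigvals, dtype=float))[::-1]
    lam = lam[lam > 1e-10 * lam[0]]
    rows = []
    for i in range(min(max_k, lam.size - 2)):
        rest = lam[i:]
        L = rest.size
        s1, s2 = rest.sum(), (rest**2).sum()
        denom = L * s2 - s1**2
        if denom <= 0:
            break
        n_eff = (L + 1) * s1**2 / denom
        ell = L * rest[0] / s1
        mu = (math.sqrt(n_eff - 1) + math.sqrt(L)) ** 2 / n_eff
        sigma = ((math.sqrt(n_eff - 1) + math.sqrt(L)) / n_eff) * (
            1.0 / math.sqrt(n_eff - 1) + 1.0 / math.sqrt(L)
        ) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        rows.append({"component": i + 1, "eigenvalue": rest[0], "tw": x,
                     "p": tw_pvalue(x)})
    return pd.DataFrame(rows)


def significant_pcs(g: GenotypeMatrix, alpha: float = 0.05,
                    k: KinshipMatrix | None = None,
                    max_k: int = 20) -> tuple[np.ndarray, int]:
    """Leading principal components with Tracy-Widom p < alpha.

    PCs are eigenvectors of the kinship matrix; testing stops at the first
    non-significant eigenvalue.
    """
    if g.n_samples <= 10:
        raise ValueError("need more than 10 samples")
    if k is None:
        k = kinship(g, maf_min=0.01)
    lam, u = np.linalg.eigh(k.matrix)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    tw = tracy_widom_stats(lam, max_k=max_k)
    n_sig = 0
    for p in tw["p"]:
        if p < alpha:
            n_sig += 1
        else:
            break
    return u[:, :n_sig], n_sig


def lmm_assoc(g: GenotypeMatrix, y_transformed: np.ndarray,
              covariates: np.ndarray, k: KinshipMatrix,
              test_variants: np.ndarray | None = None) -> AssocResult:
    """EMMAX-style mixed-model association scan.

    Variance components are estimated once on the null model (covariates
    only) by REML; each variant then gets a GLS Wald test with the null
    spectral decomposition held fixed. ``covariates`` must include an
    intercept column.
    """
    y = np.asarray(y_transformed, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if not np.any(np.all(np.isclose(c, c[0, :]), axis=0) & (np.abs(c[0, :]) > 0)):
        raise ValueError("covariates must include an intercept column")
    n = y.size
    fit = reml_fit(y, c, k=k.matrix)
    w = fit.eigvals + fit.delta
    s = 1.0 / np.sqrt(w)
    u = fit.eigvecs
    y_t = s * (u.T @ y)
    c_t = s[:, None] * (u.T @ c)

    if test_variants is None:
        test_idx = np.arange(g.n_variants)
    else:
        test_idx = np.asarray(test_variants)
    dos = g.dosage[:, test_idx]
    g_t = s[:, None] * (u.T @ dos)

    q, _ = np.linalg.qr(c_t)
    y_perp = y_t - q @ (q.T @ y_t)
    g_perp = g_t - q @ (q.T @ g_t)

    den = (g_perp**2).sum(axis=0)
    raw = (g_t**2).sum(axis=0)
    collinear = den <= 1e-10 * np.maximum(raw, 1e-300)
    den_safe = np.where(collinear, 1.0, den)
    beta = (g_perp * y_perp[:, None]).sum(axis=0) / den_safe
    p_cov = c.shape[1]
    dof = n - p_cov - 1
    rss = float(y_perp @ y_perp) - beta**2 * den_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / den_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    beta[collinear] = np.nan
    se[collinear] = np.nan
    pvals[collinear] = np.nan

    v = g.variants.iloc[test_idx]
    df = pd.DataFrame(
        {
            "chrom": v["chrom"].to_numpy(),
            "pos": v["pos"].to_numpy(),
            "id": v["id"].to_numpy(),
            "ea": v["alt"].to_numpy(),
            "oa": v["ref"].to_numpy(),
            "eaf": g.eaf_from_dosage()[test_idx],
            "beta": beta,
            "se": se,
            "p": pvals,
            "n": n,
            "collinear": collinear,
        }
    )
    ok = df["p"].dropna().to_numpy()
    lam_gc = genomic_control(ok) if ok.size >= 100 else float("nan")
    return AssocResult(df=df, lambda_gc=lam_gc, h2_null=fit.h2, delta=fit.delta,
                       extras={"reml": fit})


def genomic_control(pvals: np.ndarray) -> float:
    """lambda_GC: median association chi-square over its null median (0.4549)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size < 100:
        raise ValueError("need at least 100 p-values")
    chi2 = stats.chi2.isf(pvals, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


def conditional_scan(g: GenotypeMatrix, y_transformed: np.ndarray,
                     covariates: np.ndarray, k: KinshipMatrix,
                     condition_on: str) -> AssocResult:
    """Association scan conditioning on an index variant.

    The index variant's dosage joins the fixed effects and the variant is
    excluded from the output; perfect proxies of the index variant come back
    flagged ``collinear`` with NaN statistics.
    """
    j = g.index_of(condition_on)
    zc = g.dosage[:, j]
    if np.all(zc == zc[0]):
        raise ValueError(f"conditioning variant {condition_on!r} is monomorphic")
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    caug = np.column_stack([c, zc])
    test_idx = np.setdiff1d(np.arange(g.n_variants), [j])
    return lmm_assoc(g, y_transformed, caug, k, test_variants=test_idx)
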