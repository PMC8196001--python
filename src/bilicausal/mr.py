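"""Two-stage least-squares Mendelian randomization with diagnostics.

Stage one regresses the exposure on the instrument (allele dosage, effect
allele = ALT) and covariates; instrument strength is the partial F for the
instrument (F > 10 is the conventional adequacy rule). Stage two is a
logistic regression of the binary outcome on the fitted exposure plus
covariates, so the causal estimate is on the log-odds scale. The exclusion
restriction is probed by regressing the outcome on the instrument adjusting
for the exposure. Studies combine by fixed-effect inverse-variance
weighting, and analytic power uses the mRnd binary-outcome non-centrality
formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class MRStudyResult:
    f_stat: float
    r2: float
    beta: float  # log-odds of outcome per unit exposure
    se: float
    ci: tuple[float, float]
    p: float
    n: int
    se_boot: float = float("nan")
    exclusion_or: float = float("nan")
    exclusion_ci: tuple[float, float] = (float("nan"), float("nan"))
    exclusion_p: float = float("nan")
    flags: dict = field(default_factory=dict)


@dataclass
class MetaResult:
    beta: float
    se: float
    ci: tuple[float, float]
    p: float
    weights: np.ndarray
    q: float
    i2: float


@dataclass
class PowerParams:
    n: int
    alpha: float
    prevalence: float
    or_per_sd: float
    r2: float

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.or_per_sd <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 <= self.r2 < 1:
            raise ValueError("r2 must be in [0, 1)")


def _with_covariates(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if not np.any(np.all(c == c[0, :], axis=0)):
        c = np.column_stack([np.ones(n), c])
    return c


def first_stage(x, z, covariates=None):
    """Regress exposure on instrument + covariates.

    Returns (fitted exposure, partial F for the instrument with 1 numerator
    df, partial R^2 for the instrument).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.all(z == z[0]):
        raise ValueError("instrument is constant")
    n = x.size
    c = _with_covariates(n, covariates)
    full = sm.OLS(x, np.column_stack([c, z])).fit()
    reduced = sm.OLS(x, c).fit()
    rss_f, rss_r = full.ssr, reduced.ssr
    df_resid = n - c.shape[1] - 1
    f = (rss_r - rss_f) / (rss_f / df_resid)
    r2 = (rss_r - rss_f) / rss_r
    return full.fittedvalues, float(f), float(r2)


def second_stage(y, x_hat, covariates=None):
    """Logistic regression of the binary outcome on the fitted exposure.

    Returns (beta, naive ML SE, 95% CI, p, flags). The naive SE ignores
    first-stage uncertainty; use :func:`mr_study` for a joint bootstrap SE.
    """
    y = np.asarray(y, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.allclose(x_hat, x_hat[0]):
        raise ValueError("fitted exposure is constant; causal effect not identified")
    n = y.size
    c = _with_covariates(n, covariates)
    design = np.column_stack([c, x_hat])
    flags = {}
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise ValueError("non-convergence")
        beta, se = float(fit.params[-1]), float(fit.bse[-1])
    except Exception:
        flags["separation"] = True
        with np.errstate(all="ignore"):
            model = sm.Logit(y, design)
            params = model.fit_regularized(alpha=1e-3, disp=0).params
            cov = np.linalg.pinv(-model.hessian(params))
            beta, se = float(params[-1]), float(math.sqrt(max(cov[-1, -1], 0)))
    ci = (beta - Z975 * se, beta + Z975 * se)
    p = 2.0 * float(stats.norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return beta, se, ci, p, flags


def second_stage_linear(y, x_hat, covariates=None) -> float:
    """Identity-link second stage (continuous outcome); returns beta.

    In the no-covariate single-instrument case this equals the Wald ratio
    beta_ZY / beta_ZX exactly.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c = _with_covariates(n, covariates)
    fit = sm.OLS(y, np.column_stack([c, np.asarray(x_hat, dtype=float)])).fit()
    return float(fit.params[-1])


def exclusion_check(y, z, x, covariates=None):
    """Outcome on instrument adjusting for exposure: exclusion-restriction probe.

    Returns (OR per effect-allele copy, 95% CI, p); OR ~ 1 is consistent with
    the instrument affecting the outcome only through the exposure.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    c = _with_covariates(n, covariates)
    design = np.column_stack([c, np.asarray(x, dtype=float), np.asarray(z, dtype=float)])
    with np.errstate(all="ignore"):
        fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    b, se = float(fit.params[-1]), float(fit.bse[-1])
    or_ = math.exp(b)
    ci = (math.exp(b - Z975 * se), math.exp(b + Z975 * se))
    p = 2.0 * float(stats.norm.sf(abs(b / se)))
    return or_, ci, p


def mr_study(x, z, y, covariates=None, n_boot: int = 0, seed: int = 0) -> MRStudyResult:
    """Full per-study MR: first stage, second stage, exclusion diagnostic.

    With ``n_boot > 0`` a joint bootstrap (resampling rows, redoing both
    stages) supplies an SE that accounts for first-stage uncertainty.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    x_hat, f, r2 = first_stage(x, z, covariates)
    beta, se, ci, p, flags = second_stage(y, x_hat, covariates)
    ex_or, ex_ci, ex_p = exclusion_check(y, z, x, covariates)
    se_boot = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = y.size
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            cb = None if covariates is None else np.asarray(covariates)[idx]
            try:
                xh, _, _ = first_stage(x[idx], z[idx], cb)
                b, *_ = second_stage(y[idx], xh, cb)
                draws.append(b)
            except Exception:
                continue
        if len(draws) > 10:
            se_boot = float(np.std(draws, ddof=1))
    return MRStudyResult(
        f_stat=f, r2=r2, beta=beta, se=se, ci=ci, p=p, n=y.size,
        se_boot=se_boot, exclusion_or=ex_or, exclusion_ci=ex_ci,
        exclusion_p=ex_p, flags=flags,
    )


def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Combined beta = sum(b/SE^2)/sum(1/SE^2), SE = 1/sqrt(sum(1/SE^2));
    Cochran's Q and I^2 quantify heterogeneity.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 1:
        raise ValueError("need at least one study")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    ci = (beta - Z975 * se, beta + Z975 * se)
    p = 2.0 * float(stats.norm.sf(abs(beta / se)))
    q = float((w * (betas - beta) ** 2).sum())
    k = betas.size
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 else 0.0
    return MetaResult(beta=beta, se=se, ci=ci, p=p, weights=w / w.sum(), q=q, i2=i2)


def mr_power_binary(params: PowerParams) -> float:
    """Analytic MR power for a binary outcome (mRnd formulation).

    The causal odds ratio per exposure SD is mapped to a risk-difference
    scale effect b = K*(OR/(1 + K*(OR-1)) - 1) at prevalence K; its sampling
    variance given an instrument explaining R^2 of the exposure is
    (K(1-K) - b^2)/(N*R^2), and power is the upper tail of a noncentral
    1-df chi-square at the alpha threshold with NCP = b^2/var.
    In the R^2 -> 0 limit the NCP vanishes and power equals alpha.
    """
    params.validate()
    k, or_ = params.prevalence, params.or_per_sd
    b = k * (or_ / (1.0 + k * (or_ - 1.0)) - 1.0)
    if params.r2 == 0:
        return params.alpha
    v = (k * (1.0 - k) - b * b) / (params.n * params.r2)
    ncp = b * b / v
    thresh = stats.chi2.ppf(1.0 - params.alpha, 1)
    return float(stats.ncx2.sf(thresh, 1, ncp))
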