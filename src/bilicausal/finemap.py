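"""Bayes-factor fine mapping over causal configurations.

Given marginal z-scores and the LD matrix for a region, an approximate
multivariate Bayes factor is computed for every causal configuration up to a
maximum number of causal variants: under the null the configuration's
z-scores are N(0, R_cc), under the alternative N(0, R_cc + n*s^2 R_cc R_cc)
— the CAVIARBF likelihood. Posterior inclusion probabilities marginalize the
configuration posterior, with per-variant priors optionally tilted by binary
functional annotations via fixed prior-odds multipliers.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

#: default prior standard deviation grid for the causal effect (z-score scale)
PRIOR_SD_GRID = (0.1, 0.2, 0.4)

#: configuration-enumeration guard
MAX_CONFIGS = 1_000_000


@dataclass
class RegionStats:
    """Marginal summary statistics for one region."""

    z: np.ndarray
    R: np.ndarray
    n: int
    ids: list[str] | None = None
    annotations: np.ndarray | None = None  # (m, a) binary

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        m = self.z.size
        if self.R.shape != (m, m):
            raise ValueError("LD matrix shape does not match z-scores")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite z-scores")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if self.ids is None:
            self.ids = [f"v{j}" for j in range(m)]

    @property
    def m(self) -> int:
        return self.z.size


@dataclass
class FineMapResult:
    df: pd.DataFrame  # id, logbf_single, pip
    config_log_posterior: dict
    prior: dict = field(default_factory=dict)
    log_posterior_null: float = float("nan")


def _mvn_logpdf_zero_mean(z: np.ndarray, cov: np.ndarray, ridge: float = 0.0):
    c = cov if ridge == 0 else cov + ridge * np.eye(cov.shape[0])
    sign, logdet = np.linalg.slogdet(c)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    sol = np.linalg.solve(c, z)
    return -0.5 * (z.size * math.log(2 * math.pi) + logdet + float(z @ sol))


def config_log_bf(stats: RegionStats, config, prior_sd=PRIOR_SD_GRID) -> float:
    """Log Bayes factor of a causal configuration against the null.

    When ``prior_sd`` is a sequence, Bayes factors are averaged (on the
    natural scale, via log-sum-exp) over the grid with equal weights.
    Singular LD submatrices are ridge-regularized with a logged epsilon.
    """
    config = sorted(config)
    if len(config) < 1:
        raise ValueError("configuration must contain at least one variant")
    sds = np.atleast_1d(np.asarray(prior_sd, dtype=float))
    if np.any(sds <= 0):
        raise ValueError("prior_sd must be positive")
    r_cc = stats.R[np.ix_(config, config)]
    z_c = stats.z[config]
    ridge = 0.0
    for attempt in range(6):
        try:
            log_null = _mvn_logpdf_zero_mean(z_c, r_cc, ridge)
            logs = []
            for sd in sds:
                s = stats.n * sd * sd
                cov1 = r_cc + s * (r_cc @ r_cc)
                logs.append(_mvn_logpdf_zero_mean(z_c, cov1, ridge))
            break
        except np.linalg.LinAlgError:
            ridge = 1e-8 if ridge == 0 else ridge * 100
            logger.warning("singular LD submatrix for config %s; ridge=%g",
                           config, ridge)
    else:
        raise np.linalg.LinAlgError(f"LD submatrix irreparably singular: {config}")
    return float(logsumexp(logs) - math.log(len(logs)) - log_null)


def pip(stats: RegionStats, max_causal: int = 1,
        prior_inclusion: float | None = None,
        annotation_log_prior_odds: np.ndarray | None = None,
        prior_sd=PRIOR_SD_GRID) -> FineMapResult:
    """Marginal posterior inclusion probabilities over causal configurations.

    The posterior over all configurations of size 0..max_causal is
    proportional to prior(config) * BF(config) with independent per-variant
    inclusion priors (default 1/m), each variant's prior odds optionally
    multiplied by exp(annotation_log_prior_odds @ annotations_j).
    PIP_j sums the posterior over configurations containing j; with
    max_causal = 1, P(null) + sum(PIP) = 1.
    """
    m = stats.m
    if max_causal < 1:
        raise ValueError("max_causal must be >= 1")
    n_configs = sum(math.comb(m, k) for k in range(1, max_causal + 1))
    if n_configs > MAX_CONFIGS:
        raise ValueError(
            f"{n_configs} configurations exceed the enumeration guard "
            f"({MAX_CONFIGS}); reduce max_causal or the region size"
        )
    pi0 = 1.0 / m if prior_inclusion is None else float(prior_inclusion)
    if not 0 < pi0 < 1:
        raise ValueError("prior inclusion probability must be in (0, 1)")
    log_odds = np.full(m, math.log(pi0 / (1 - pi0)))
    if annotation_log_prior_odds is not None:
        if stats.annotations is None:
            raise ValueError("annotation effects supplied without annotations")
        log_odds = log_odds + stats.annotations @ np.asarray(
            annotation_log_prior_odds, dtype=float
        )
    # independent-inclusion prior: log prior(config) = const + sum_{j in c} log_odds_j
    keys, logpost = [()], [0.0]  # null configuration: BF = 1, no odds terms
    for size in range(1, max_causal + 1):
        for config in itertools.combinations(range(m), size):
            lp = float(sum(log_odds[j] for j in config))
            lp += config_log_bf(stats, list(config), prior_sd)
            keys.append(config)
            logpost.append(lp)
    logpost = np.asarray(logpost)
    logz = logsumexp(logpost)
    logpost -= logz
    pips = np.zeros(m)
    for key, lp in zip(keys, logpost):
        for j in key:
            pips[j] += math.exp(lp)
    single = np.array([config_log_bf(stats, [j], prior_sd) for j in range(m)])
    df = pd.DataFrame({"id": stats.ids, "logbf_single": single, "pip": pips})
    return FineMapResult(
        df=df,
        config_log_posterior={k: float(v) for k, v in zip(keys, logpost)},
        prior={"prior_inclusion": pi0, "prior_sd": tuple(np.atleast_1d(prior_sd)),
               "max_causal": max_causal},
        log_posterior_null=float(logpost[0]),
    )


def region_stats_from_assoc(assoc_df: pd.DataFrame, g, variant_ids,
                            maf_min: float = 0.01) -> RegionStats:
    """Assemble RegionStats from a scan result and genotypes for a region."""
    sub = assoc_df[assoc_df["id"].isin(variant_ids)].copy()
    maf = np.minimum(sub["eaf"], 1 - sub["eaf"])
    sub = sub[maf >= maf_min]
    ids = sub["id"].tolist()
    idx = [g.index_of(i) for i in ids]
    dos = g.dosage[:, idx]
    R = np.corrcoef(dos, rowvar=False)
    z = (sub["beta"] / sub["se"]).to_numpy()
    return RegionStats(z=z, R=R, n=int(sub["n"].iloc[0]), ids=ids)
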