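"""Descriptive (Table-1 style) group comparisons.

Continuous traits are compared with Welch's unequal-variance t test computed
from group summaries; binary traits with Pearson chi-square tests *without*
continuity correction. Those are the conventions needed to reproduce the
published descriptive p-values exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def chisq_gof(counts, probs) -> tuple[float, float]:
    """Pearson goodness-of-fit test.

    Parameters
    ----------
    counts : observed counts per category.
    probs : hypothesized probabilities (must sum to 1).

    Returns (statistic, p) with k-1 degrees of freedom and no continuity
    correction.
    """
    counts = np.asarray(counts, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if counts.shape != probs.shape:
        raise ValueError("counts and probs must have the same length")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("probs must sum to 1")
    expected = counts.sum() * probs
    if np.any(expected == 0):
        raise ValueError("expected count of zero")
    statistic = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=len(counts) - 1))
    return statistic, p


def chisq_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson independence test on a 2x2 table, 1 df, no continuity correction.

    Table layout::

        group1  group2
        a       c        (trait present)
        b       d        (trait absent)
    """
    table = np.array([[a, c], [b, d]], dtype=float)
    margins = [a + b, c + d, a + c, b + d]
    if any(m <= 0 for m in margins):
        raise ValueError("all 2x2 margins must be positive")
    n = table.sum()
    statistic = float(n * (a * d - b * c) ** 2 / np.prod(margins))
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def welch_t_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float, float]:
    """Welch two-sample t test from group summaries.

    Returns (t, Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def table1(pheno_df: pd.DataFrame, group: str = "sex",
           continuous=("age", "bmi", "bilirubin"),
           binary=("t2d", "hypertension")) -> pd.DataFrame:
    """Build a Table-1 style summary split by a binary grouping column."""
    g1 = pheno_df[pheno_df[group] == 1]
    g0 = pheno_df[pheno_df[group] == 0]
    rows = []
    stat, p = chisq_gof([len(g1), len(g0)], [0.5, 0.5])
    rows.append({
        "trait": "n", "group1": f"{len(g1)}", "group0": f"{len(g0)}",
        "test": "chisq_gof", "p": p,
    })
    for trait in binary:
        a, b = int(g1[trait].sum()), int((1 - g1[trait]).sum())
        c, d = int(g0[trait].sum()), int((1 - g0[trait]).sum())
        stat, p = chisq_2x2(a, b, c, d)
        rows.append({
            "trait": trait,
            "group1": f"{a} ({100 * a / len(g1):.2f}%)",
            "group0": f"{c} ({100 * c / len(g0):.2f}%)",
            "test": "chisq_2x2", "p": p,
        })
    for trait in continuous:
        t, df, p = welch_t_summary(
            g1[trait].mean(), g1[trait].std(ddof=1), len(g1),
            g0[trait].mean(), g0[trait].std(ddof=1), len(g0),
        )
        rows.append({
            "trait": trait,
            "group1": f"{g1[trait].mean():.2f} ({g1[trait].std(ddof=1):.2f})",
            "group0": f"{g0[trait].mean():.2f} ({g0[trait].std(ddof=1):.2f})",
            "test": "welch_t", "p": p,
        })
    return pd.DataFrame(rows)
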