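"""Nonparametric repeated-measures statistics with effect sizes.

Effect-size conventions: r = sqrt(chi2 / N) for the Friedman test with
N = total observations (rows x conditions), and r = |Z| / sqrt(N) for the
Wilcoxon signed-rank test with Z the standardized statistic and N the number
of contributing pairs. Bonferroni correction multiplies p by the number of
comparisons, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "friedman_test",
    "wilcoxon_pair",
    "bonferroni",
    "spearman_correlation",
    "friedman_effect_size",
    "wilcoxon_effect_size",
]


@dataclass
class GroupTestResult:
    test_name: str
    statistic: float  # chi2 (Friedman), standardized Z (Wilcoxon), rho (Spearman)
    n: int  # sample size used by the effect-size formula
    df: int | None
    p_raw: float
    p_corrected: float | None
    effect_size: float
    note: str | None = None


def friedman_effect_size(chi2: float, n_obs: int) -> float:
    """r = sqrt(chi2 / N), N = total observations."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return math.sqrt(chi2 / n_obs)


def wilcoxon_effect_size(z: float, n: int) -> float:
    """r = |Z| / sqrt(N)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(z) / math.sqrt(n)


def friedman_test(data: np.ndarray) -> GroupTestResult:
    """Friedman rank test over a participants x conditions matrix.

    Rows containing missing values are dropped (listwise deletion). The
    chi-square statistic includes the standard tie correction.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be a participants x conditions matrix, >= 2 conditions")
    complete = data[np.all(np.isfinite(data), axis=1)]
    n, k = complete.shape
    if n < 2:
        raise ValueError(f"need >= 2 complete rows, found {n}")
    ranks = np.apply_along_axis(sps.rankdata, 1, complete)
    col_sums = ranks.sum(axis=0)
    ssbn = float(np.sum(col_sums**2))
    ties = 0.0
    for row in complete:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (k * (k * k - 1) * n)
    if correction <= 0:
        chi2 = 0.0  # all rows fully tied: no rank information
    else:
        chi2 = (12.0 / (k * n * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / correction
        chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    n_obs = n * k
    return GroupTestResult(
        test_name="friedman",
        statistic=chi2,
        n=n_obs,
        df=df,
        p_raw=p,
        p_corrected=None,
        effect_size=friedman_effect_size(chi2, n_obs),
    )


def wilcoxon_pair(data_a: Sequence[float], data_b: Sequence[float]) -> GroupTestResult:
    """Paired Wilcoxon signed-rank test, reported as a standardized Z.

    Exact p for fewer than 20 non-zero pairs without ties in |differences|,
    normal approximation (with tie correction in the variance) otherwise.
    Zero differences are dropped. A fully tied pair of vectors yields the
    degenerate result p=1, effect size 0.
    """
    a = np.asarray(data_a, dtype=np.float64)
    b = np.asarray(data_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("data_a and data_b must be 1-D vectors of equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = a[keep] - b[keep]
    d = d[d != 0.0]
    n = d.shape[0]
    if n == 0:
        return GroupTestResult(
            test_name="wilcoxon", statistic=0.0, n=0, df=None,
            p_raw=1.0, p_corrected=None, effect_size=0.0,
            note="all differences zero",
        )
    if n < 5:
        raise ValueError(f"need >= 5 non-zero paired differences, found {n}")
    abs_ranks = sps.rankdata(np.abs(d))
    w_plus = float(abs_ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 <= 0 else (w_plus - mu) / math.sqrt(sigma2)
    has_ties = bool(np.any(counts > 1))
    if n < 20 and not has_ties:
        p = float(sps.wilcoxon(d, method="exact", alternative="two-sided").pvalue)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return GroupTestResult(
        test_name="wilcoxon",
        statistic=z,
        n=n,
        df=None,
        p_raw=p,
        p_corrected=None,
        effect_size=wilcoxon_effect_size(z, n),
        note=f"W+={w_plus:g}",
    )


def bonferroni(p_values: Sequence[float], k: int) -> list[float]:
    """Multiply each p by k, capped at 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [min(1.0, p * k) for p in p_values]


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Spearman rank correlation with two-sided p; pairwise deletion of NaN."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[keep], y[keep]
    n = xs.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, found {n}")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return GroupTestResult(
            test_name="spearman", statistic=math.nan, n=n, df=None,
            p_raw=1.0, p_corrected=None, effect_size=math.nan,
            note="degenerate: zero rank variance",
        )
    res = sps.spearmanr(xs, ys)
    rho = float(res.statistic)
    return GroupTestResult(
        test_name="spearman",
        statistic=rho,
        n=n,
        df=None,
        p_raw=float(res.pvalue),
        p_corrected=None,
        effect_size=rho,
    )
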