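"""Shared statistical kernels: Fisher exact, chi-squared, rank-sum."""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     side: str = "greater") -> float:
    """Exact hypergeometric tail p for the 2x2 table [[a, b], [c, d]].

    ``side='greater'`` tests enrichment of the top-left cell (more ``a``
    than expected given the margins); ``'less'`` the opposite tail;
    ``'two-sided'`` sums the probabilities of all tables as or less
    likely than the observed one (the standard Fisher convention).
    The hypergeometric pmf over the support is computed from log
    binomial coefficients (vectorized), which keeps the call cheap
    enough for exhaustive small-table verification.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1 = a + b
    col1 = a + c
    amin = max(0, col1 - (c + d))
    amax = min(row1, col1)
    support = np.arange(amin, amax + 1)
    logpmf = (_log_comb(row1, support) + _log_comb(n - row1, col1 - support)
              - _log_comb(n, col1))
    pmf = np.exp(logpmf)
    i = a - amin
    if side == "greater":
        return float(min(1.0, pmf[i:].sum()))
    if side == "less":
        return float(min(1.0, pmf[:i + 1].sum()))
    if side == "two-sided":
        # tolerance guards against ties lost to floating point
        p = float(pmf[pmf <= pmf[i] * (1 + 1e-9)].sum())
        return min(1.0, p)
    raise ValueError(f"unknown side {side!r}")


def chi2_2x2(table, correction: bool = False):
    """Pearson chi-squared on a 2x2 table, 1 df.

    Returns (statistic, p).  No continuity correction by default.  A
    table with a zero margin yields statistic 0 and p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    n = t.sum()
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    if n == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = row @ col / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def rank_sum_test(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration for small tie-free samples (both n <= 20),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan"), len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 20 and len(y) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), len(x), len(y)


def pearson_pairwise(x, y):
    """Pearson r over jointly defined (non-NaN) entries; returns (r, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 2:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan"), n
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, n


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-ranked ties; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan")
    return float(stats.spearmanr(xs, ys).statistic)
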