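"""Nonparametric comparison suite for paired and independent dosimetric samples.

Exact small-sample null distributions are computed by dynamic programming
(sign-flip enumeration for the Wilcoxon signed-rank test, label
enumeration for Mann-Whitney U); larger samples use the normal
approximation with continuity and tie corrections.  Two-sided p-values
double the smaller tail, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import ValidationError

#: largest n for which the exact signed-rank distribution is enumerated
WILCOXON_EXACT_N = 25
#: largest min(n, m) for which the exact U distribution is enumerated (no ties)
MWU_EXACT_N = 8


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    mode: str = "exact"  # exact | approx

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _two_sided_from_cdf(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the positive-rank sum over all sign assignments.

    ``ranks2`` are the |difference| midranks doubled so that tied
    (half-integer) midranks become integers; index w of the returned
    array counts sign vectors with doubled positive-rank sum w.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    paired_diffs: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Wilcoxon signed-rank test of paired differences against a symmetric
    zero-centered null.

    Zero differences are discarded (Wilcoxon's original policy).  The
    exact path enumerates all 2^n sign assignments of the |difference|
    ranks via dynamic programming (valid with tied ranks) for n <= 25;
    otherwise a normal approximation with continuity and tie corrections
    is used.
    """
    d = np.asarray(list(paired_diffs), dtype=float)
    if d.size == 0:
        raise ValidationError("empty paired sample")
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", (0,), "exact")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    use_exact = mode == "exact" or (mode == "auto" and n <= WILCOXON_EXACT_N)
    if use_exact:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        return TestResult(
            w_plus, _two_sided_from_cdf(p_le, p_ge), "wilcoxon_signed_rank", (n,), "exact"
        )
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank", (n,), "approx")
    cc = 0.5 * np.sign(w_plus - mean)  # continuity correction toward the mean
    z = (w_plus - mean - cc) / sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, "wilcoxon_signed_rank", (n,), "approx")


def _mwu_counts(n: int, m: int) -> np.ndarray:
    """Counts of the U statistic over all C(n+m, n) tie-free labelings.

    Recurrence on the largest pooled value: if it belongs to x it beats
    all j remaining y's, so f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u).
    """
    size = n * m + 1
    f = np.zeros((n + 1, m + 1, size), dtype=float)
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            f[i, j, :] = f[i, j - 1, :]
            f[i, j, j:] += f[i - 1, j, : size - j]
    return f[n, m]


def mann_whitney(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Mann-Whitney U test for two independent samples.

    Exact enumeration of the U null distribution when min(n, m) <= 8 and
    no ties straddle the two samples; otherwise a normal approximation
    with continuity and tie corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = mode == "exact" or (
        mode == "auto" and min(n, m) <= MWU_EXACT_N and not has_ties
    )
    if use_exact and has_ties:
        raise ValidationError("exact Mann-Whitney requires tie-free samples")
    if use_exact:
        counts = _mwu_counts(n, m)
        total = counts.sum()
        u_int = int(round(u_x))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        return TestResult(
            u_x, _two_sided_from_cdf(p_le, p_ge), "mann_whitney", (n, m), "exact"
        )
    mean = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (nm * (nm - 1.0)) if nm > 1 else 0.0
    var = n * m / 12.0 * (nm + 1.0 - tie_term)
    if var <= 0:
        return TestResult(u_x, 1.0, "mann_whitney", (n, m), "approx")
    cc = 0.5 * np.sign(u_x - mean)
    z = (u_x - mean - cc) / sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u_x, p, "mann_whitney", (n, m), "approx")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across k independent groups (tie-corrected,
    chi-squared reference with k-1 df)."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("need >= 2 non-empty groups")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # scipy raises on all-identical data; the null is trivially retained
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(a.size for a in arrays), "approx")
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal_wallis", tuple(a.size for a in arrays), "approx")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided t-distribution p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of equal length >= 3")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), "pearson", (x.size,), "exact")


class LinearFit:
    """OLS line with t-based 95% confidence and prediction bands."""

    def __init__(self, slope, intercept, r, x_mean, sxx, s2, n):
        self.slope, self.intercept, self.r = slope, intercept, r
        self._x_mean, self._sxx, self._s2, self._n = x_mean, sxx, s2, n

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def _half_width(self, x, extra: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        tcrit = sps.t.ppf(0.975, self._n - 2)
        se = np.sqrt(self._s2 * (extra + 1.0 / self._n + (x - self._x_mean) ** 2 / self._sxx))
        return tcrit * se

    def confidence_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """95% CI for the expected value at x."""
        hw = self._half_width(x, 0.0)
        return self.predict(x) - hw, self.predict(x) + hw

    def prediction_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """95% interval for an individual new observation at x."""
        hw = self._half_width(x, 1.0)
        return self.predict(x) - hw, self.predict(x) + hw


def linear_fit_with_bands(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares with t-based 95% confidence and prediction bands."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples of equal length >= 3")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("degenerate design: all x identical")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (x.size - 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r = slope * sqrt(sxx / syy) if syy > 0 else 0.0
    return LinearFit(slope, intercept, r, float(x.mean()), sxx, s2, int(x.size))
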