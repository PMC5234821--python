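"""Statistical primitives shared by the aggregate and glance analyses.

Pure functions, no I/O.  The nonstandard pieces — Passing–Bablok symmetric
regression, Zou's modified-asymptotic confidence interval for a difference
between dependent overlapping correlations, and the exact two-sided
binomial sign test — are implemented here; each has an independent
brute-force oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Interval",
    "OLSResult",
    "spearman_rho",
    "fisher_z_ci",
    "zou_diff_ci",
    "binom_test_exact",
    "theil_sen",
    "passing_bablok",
    "ols_fit",
]


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval."""

    low: float
    high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.low <= self.high:
            raise ValueError(f"interval bounds out of order: {self.low} > {self.high}")

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high

    @property
    def width(self) -> float:
        return self.high - self.low


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  Raises ``ValueError`` if either vector is
    constant (the correlation is undefined) or lengths differ / are < 3.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _z_quantile(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 * (1.0 + level)))


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> Interval:
    """Fisher-z confidence interval for a correlation coefficient.

    tanh(atanh(r) ± z_(1+level)/2 / sqrt(n-3)).  |r| = 1 degenerates to a
    zero-width interval at r.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if abs(r) == 1.0:
        return Interval(r, r, level)
    half = _z_quantile(level) / math.sqrt(n - 3)
    z = math.atanh(r)
    return Interval(math.tanh(z - half), math.tanh(z + half), level)


def _check_corr_matrix(r12: float, r13: float, r23: float) -> None:
    for r in (r12, r13, r23):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    m = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(m)[0] < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")


def zou_diff_ci(r12: float, r13: float, r23: float, n: int, level: float = 0.95) -> Interval:
    """Zou's CI for rho12 - rho13, two dependent overlapping correlations.

    Variables 2 and 3 are each correlated with the shared variable 1; r23
    is the correlation between them, from which the sampling correlation of
    the two Fisher-z estimates is computed (Olkin–Finn form).
    """
    _check_corr_matrix(r12, r13, r23)
    if n < 4:
        raise ValueError("need n >= 4")
    ci1 = fisher_z_ci(r12, n, level)
    ci2 = fisher_z_ci(r13, n, level)
    l1, u1 = ci1.low, ci1.high
    l2, u2 = ci2.low, ci2.high
    num = (r23 - 0.5 * r12 * r13) * (1.0 - r12**2 - r13**2 - r23**2) + r23**3
    den = (1.0 - r12**2) * (1.0 - r13**2)
    corr = num / den if den > 0 else 0.0
    corr = min(1.0, max(-1.0, corr))
    d = r12 - r13
    lo = d - math.sqrt((r12 - l1) ** 2 + (u2 - r13) ** 2 - 2.0 * corr * (r12 - l1) * (u2 - r13))
    hi = d + math.sqrt((u1 - r12) ** 2 + (r13 - l2) ** 2 - 2.0 * corr * (u1 - r12) * (r13 - l2))
    return Interval(lo, hi, level)


def binom_test_exact(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test p-value.

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of the observed count (the small-probability method; for
    p0 = 1/2 this equals doubling the one-sided tail, capped at 1).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    d = pmf[k]
    # relative tolerance guards against float noise in pmf equality
    p = float(pmf[pmf <= d * (1.0 + 1e-7)].sum())
    return min(1.0, p)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All pairwise slopes (y_j - y_i)/(x_j - x_i) over pairs with x_i != x_j."""
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(len(x), k=1)
    dx = dx[iu]
    dy = dy[iu]
    ok = dx != 0
    return dy[ok] / dx[ok]


def theil_sen(x, y) -> tuple[float, float]:
    """Theil–Sen line: median pairwise slope, intercept = median(y - m*x)."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya) or len(xa) < 2:
        raise ValueError("need >= 2 points of equal length")
    slopes = _pairwise_slopes(xa, ya)
    if len(slopes) == 0:
        raise ValueError("all x values identical")
    m = float(np.median(slopes))
    b = float(np.median(ya - m * xa))
    return m, b


def passing_bablok(x, y, level: float = 0.95) -> tuple[float, float, Interval, int]:
    """Passing–Bablok symmetric regression of y on x.

    Pairwise slopes are computed for every pair with distinct x; slopes
    exactly equal to -1 are discarded, and the estimate is the median of
    the remaining sorted slopes shifted up by K, the number of slopes
    below -1.  This shift makes the estimator equivariant under swapping
    the axes (slope -> 1/slope).  The CI uses the standard rank bounds
    from the normal approximation to Kendall's statistic.

    Returns ``(slope, intercept, slope_ci, n_slopes)``.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    npts = len(xa)
    if npts != len(ya) or npts < 3:
        raise ValueError("need >= 3 points of equal length")
    if np.ptp(xa) == 0:
        raise ValueError("all x values identical")
    slopes = _pairwise_slopes(xa, ya)
    slopes = slopes[slopes != -1.0]
    nslopes = len(slopes)
    if nslopes == 0:
        raise ValueError("no usable pairwise slopes")
    s = np.sort(slopes)
    K = int(np.sum(s < -1.0))

    def order_stat(idx1: int) -> float:
        # 1-indexed order statistic, clamped to the available range
        return float(s[min(max(idx1, 1), nslopes) - 1])

    if nslopes % 2 == 1:
        b = order_stat((nslopes + 1) // 2 + K)
    else:
        b = 0.5 * (order_stat(nslopes // 2 + K) + order_stat(nslopes // 2 + 1 + K))

    z = _z_quantile(level)
    c = z * math.sqrt(npts * (npts - 1) * (2 * npts + 5) / 18.0)
    m1 = int(round((nslopes - c) / 2.0))
    m2 = nslopes - m1 + 1
    ci = Interval(order_stat(m1 + K), order_stat(m2 + K), level)
    intercept = float(np.median(ya - b * xa))
    return b, intercept, ci, nslopes


@dataclass(frozen=True)
class OLSResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: Interval
    intercept_ci: Interval
    joint_p: float | None = None  # F test of a hypothesised (slope0, intercept0)


def ols_fit(
    x,
    y,
    level: float = 0.95,
    joint: tuple[float, float] | None = None,
) -> OLSResult:
    """Ordinary least squares of y on x with t-based CIs.

    When ``joint = (slope0, intercept0)`` is given, also runs the F test of
    the joint hypothesis slope = slope0 and intercept = intercept0, whose
    non-rejection region is the elliptical joint confidence region.
    """
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if len(xa) != len(ya) or len(xa) < 3:
        raise ValueError("need >= 3 points of equal length")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; fit is degenerate")
    X = sm.add_constant(xa)
    res = sm.OLS(ya, X).fit()
    conf = res.conf_int(alpha=1.0 - level)
    joint_p = None
    if joint is not None:
        slope0, intercept0 = joint
        ftest = res.f_test(([[0.0, 1.0], [1.0, 0.0]], [slope0, intercept0]))
        joint_p = float(ftest.pvalue)
    return OLSResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_ci=Interval(float(conf[1, 0]), float(conf[1, 1]), level),
        intercept_ci=Interval(float(conf[0, 0]), float(conf[0, 1]), level),
        joint_p=joint_p,
    )
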