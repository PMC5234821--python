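"""Oracle-equivalence and property tests for the statistical primitives.

Each nonstandard primitive is checked against an independent brute-force
implementation written step-by-step from its textbook definition, on many
small random instances.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tcifollow import statcore

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------


def oracle_spearman(x, y):
    """Spearman via explicit average-rank assignment and the Pearson formula."""

    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def oracle_theil_sen(x, y):
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                slopes.append((y[j] - y[i]) / (x[j] - x[i]))
    slopes.sort()
    m = len(slopes)
    slope = slopes[m // 2] if m % 2 else 0.5 * (slopes[m // 2 - 1] + slopes[m // 2])
    inter = sorted(yi - slope * xi for xi, yi in zip(x, y))
    k = len(inter)
    intercept = inter[k // 2] if k % 2 else 0.5 * (inter[k // 2 - 1] + inter[k // 2])
    return slope, intercept


def oracle_passing_bablok(x, y, level=0.95):
    """Step-by-step Passing–Bablok: shifted-median slope and rank-based CI."""
    n = len(x)
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    slopes.append(s)
    slopes.sort()
    N = len(slopes)
    K = sum(1 for s in slopes if s < -1.0)

    def at(idx1):  # 1-indexed, clamped
        return slopes[min(max(idx1, 1), N) - 1]

    if N % 2 == 1:
        b = at((N + 1) // 2 + K)
    else:
        b = 0.5 * (at(N // 2 + K) + at(N // 2 + 1 + K))
    z = stats.norm.ppf(0.5 * (1 + level))
    c = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = round((N - c) / 2.0)
    m2 = N - m1 + 1
    lo, hi = at(m1 + K), at(m2 + K)
    inter = sorted(yi - b * xi for xi, yi in zip(x, y))
    k = len(inter)
    a = inter[k // 2] if k % 2 else 0.5 * (inter[k // 2 - 1] + inter[k // 2])
    return b, a, lo, hi


def oracle_binom_two_sided(k, n, p0):
    """Two-sided exact binomial p by full pmf enumeration."""
    pmfs = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    d = pmfs[k]
    return min(1.0, sum(p for p in pmfs if p <= d * (1 + 1e-7)))


# ---------------------------------------------------------------------------
# oracle equivalence on random instances
# ---------------------------------------------------------------------------


def test_spearman_matches_oracle_and_scipy_on_random_instances(rng):
    for trial in range(200):
        n = rng.integers(3, 15)
        # integer values to force ties regularly
        x = rng.integers(0, 6, size=n).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        got = statcore.spearman_rho(x, y)
        assert got == pytest.approx(oracle_spearman(x, y), abs=1e-10)
        assert got == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-10)


def test_theil_sen_matches_bruteforce_on_random_instances(rng):
    for trial in range(200):
        n = rng.integers(2, 12)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        m, b = statcore.theil_sen(x, y)
        m0, b0 = oracle_theil_sen(list(x), list(y))
        assert m == pytest.approx(m0, abs=1e-12)
        assert b == pytest.approx(b0, abs=1e-12)


def test_passing_bablok_matches_bruteforce_on_random_instances(rng):
    checked = 0
    while checked < 200:
        n = int(rng.integers(3, 15))
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(scale=0.5, size=n)
        slope, intercept, ci, n_slopes = statcore.passing_bablok(x, y)
        b0, a0, lo0, hi0 = oracle_passing_bablok(list(x), list(y))
        assert slope == pytest.approx(b0, abs=1e-12)
        assert intercept == pytest.approx(a0, abs=1e-12)
        assert ci.low == pytest.approx(lo0, abs=1e-12)
        assert ci.high == pytest.approx(hi0, abs=1e-12)
        checked += 1


def test_exact_binomial_matches_enumeration_for_all_small_n():
    for n in range(1, 62, 5):
        for k in range(0, n + 1, max(1, n // 7)):
            got = statcore.binom_test_exact(k, n, 0.5)
            assert got == pytest.approx(oracle_binom_two_sided(k, n, 0.5), rel=1e-9)
    # non-central p0 exercises the small-probability summation branch
    for k, n, p0 in [(3, 10, 0.3), (9, 12, 0.7), (0, 8, 0.2)]:
        got = statcore.binom_test_exact(k, n, p0)
        ref = stats.binomtest(k, n, p0).pvalue
        assert got == pytest.approx(ref, rel=1e-9)


def test_ols_fit_matches_normal_equations(rng):
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.9])
    res = statcore.ols_fit(x, y)
    # direct normal-equations computation
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.intercept == pytest.approx(beta[0], abs=1e-10)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)
    resid = y - X @ beta
    r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    assert res.r_squared == pytest.approx(r2, abs=1e-12)


# ---------------------------------------------------------------------------
# named examples and degenerate behaviour
# ---------------------------------------------------------------------------


def test_spearman_rank_example_with_ties():
    # hand computation: x=(1,2,3,4) ranks (1,2,3,4); y=(2,2,5,4) ranks (1.5,1.5,4,3)
    got = statcore.spearman_rho([1, 2, 3, 4], [2, 2, 5, 4])
    assert got == pytest.approx(oracle_spearman([1, 2, 3, 4], [2, 2, 5, 4]), abs=1e-12)
    assert got == pytest.approx(0.7378647873726218, abs=1e-9)


def test_spearman_monotone_invariance_and_sign(rng):
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = statcore.spearman_rho(x, y)
    assert statcore.spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
    assert statcore.spearman_rho(x, -y) == pytest.approx(-base, abs=1e-12)
    assert statcore.spearman_rho(x, np.argsort(np.argsort(x)).astype(float)) == 1.0


def test_spearman_rejects_constant_vector():
    with pytest.raises(ValueError):
        statcore.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_fisher_ci_reproduces_published_bounds():
    ci = statcore.fisher_z_ci(0.57, 18)
    assert round(ci.low, 2) == 0.14
    assert round(ci.high, 2) == 0.82


def test_fisher_ci_symmetry_shrinkage_and_degeneracy():
    ci0 = statcore.fisher_z_ci(0.0, 20)
    assert ci0.low == pytest.approx(-ci0.high, abs=1e-12)
    assert statcore.fisher_z_ci(0.5, 10**6).width < 0.01
    wide = statcore.fisher_z_ci(0.5, 10)
    narrow = statcore.fisher_z_ci(0.5, 100)
    assert wide.width > narrow.width
    d = statcore.fisher_z_ci(1.0, 18)
    assert d.low == d.high == 1.0


def test_zou_diff_ci_degenerate_equality_and_dependency_narrowing():
    ci = statcore.zou_diff_ci(0.6, 0.6, 0.5, 18)
    assert ci.contains(0.0)
    # higher overlap correlation -> narrower interval, all else equal
    w_lo = statcore.zou_diff_ci(0.6, 0.4, 0.0, 18).width
    w_hi = statcore.zou_diff_ci(0.6, 0.4, 0.9, 18).width
    assert w_hi < w_lo
    # monotone in n
    assert statcore.zou_diff_ci(0.6, 0.4, 0.5, 10).width > statcore.zou_diff_ci(
        0.6, 0.4, 0.5, 40
    ).width


def test_zou_diff_ci_matches_independent_formula():
    """Second, independently coded evaluation of Zou's closed form."""

    def zou_ref(r12, r13, r23, n, level=0.95):
        z = stats.norm.ppf(0.5 * (1 + level))
        zr12, zr13 = np.arctanh(r12), np.arctanh(r13)
        se = 1 / math.sqrt(n - 3)
        l1, u1 = np.tanh(zr12 - z * se), np.tanh(zr12 + z * se)
        l2, u2 = np.tanh(zr13 - z * se), np.tanh(zr13 + z * se)
        c = ((r23 - 0.5 * r12 * r13) * (1 - r12**2 - r13**2 - r23**2) + r23**3) / (
            (1 - r12**2) * (1 - r13**2)
        )
        L = (
            r12
            - r13
            - math.sqrt(
                (r12 - l1) ** 2 + (u2 - r13) ** 2 - 2 * c * (r12 - l1) * (u2 - r13)
            )
        )
        U = (
            r12
            - r13
            + math.sqrt(
                (u1 - r12) ** 2 + (r13 - l2) ** 2 - 2 * c * (u1 - r12) * (r13 - l2)
            )
        )
        return L, U

    rng = np.random.default_rng(5)
    for _ in range(50):
        a = rng.uniform(-0.7, 0.9, size=3)
        m = np.array([[1, a[0], a[1]], [a[0], 1, a[2]], [a[1], a[2], 1]])
        if np.linalg.eigvalsh(m)[0] <= 1e-6:
            continue
        ci = statcore.zou_diff_ci(a[0], a[1], a[2], 18)
        L, U = zou_ref(a[0], a[1], a[2], 18)
        assert ci.low == pytest.approx(L, abs=1e-12)
        assert ci.high == pytest.approx(U, abs=1e-12)


def test_theil_sen_robust_to_one_gross_outlier():
    x = np.arange(9.0)
    y = 0.5 * x + 1.0
    y[4] += 50.0  # gross outlier
    m, _ = statcore.theil_sen(x, y)
    assert m == pytest.approx(0.5, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    shift=st.floats(-5, 5),
    scale=st.floats(0.1, 10),
)
def test_theil_sen_equivariance(shift, scale):
    x = np.array([0.0, 1.0, 2.0, 3.5, 4.0, 6.0])
    y = np.array([1.0, 0.5, 2.5, 2.0, 4.0, 3.0])
    m0, b0 = statcore.theil_sen(x, y)
    m1, b1 = statcore.theil_sen(x, y + shift)
    assert m1 == pytest.approx(m0, abs=1e-9)
    assert b1 == pytest.approx(b0 + shift, abs=1e-9)
    m2, _ = statcore.theil_sen(x, y * scale)
    assert m2 == pytest.approx(m0 * scale, rel=1e-9)


def test_passing_bablok_exact_line_and_reciprocal_symmetry(rng):
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.5, 6.0])
    slope, intercept, _, _ = statcore.passing_bablok(x, 2 * x + 1)
    assert slope == pytest.approx(2.0, abs=1e-12)
    assert intercept == pytest.approx(1.0, abs=1e-12)
    # symmetry: swapping the variables inverts the slope (tie-free data)
    xr = rng.normal(size=11)
    yr = 1.7 * xr + rng.normal(scale=0.3, size=11)
    s_xy, _, _, _ = statcore.passing_bablok(xr, yr)
    s_yx, _, _, _ = statcore.passing_bablok(yr, xr)
    assert s_xy == pytest.approx(1.0 / s_yx, rel=1e-9)


def test_passing_bablok_scale_equivariance(rng):
    # the -1 offset (K shift) makes equivariance exact only while no
    # pairwise slope crosses -1, so use cleanly increasing data
    x = np.arange(15.0)
    y = x + rng.normal(scale=0.4, size=15)
    s, _, _, _ = statcore.passing_bablok(x, y)
    s_kx, _, _, _ = statcore.passing_bablok(3.0 * x, y)
    s_ky, _, _, _ = statcore.passing_bablok(x, 3.0 * y)
    assert s_kx == pytest.approx(s / 3.0, rel=1e-9)
    assert s_ky == pytest.approx(s * 3.0, rel=1e-9)


def test_ols_joint_test_accepts_truth_on_noiseless_data():
    x = np.linspace(0, 5, 10)
    res = statcore.ols_fit(x, 2.0 * x + 0.5, joint=(2.0, 0.5))
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.slope_ci.width == pytest.approx(0.0, abs=1e-9)
    assert res.joint_p > 0.05
    res2 = statcore.ols_fit(x, 2.0 * x + 0.5, joint=(1.0, 0.0))
    assert res2.joint_p < 1e-6


def test_binomial_published_pvalues_and_center():
    assert statcore.binom_test_exact(58, 61, 0.5) == pytest.approx(3.3e-14, rel=0.02)
    assert statcore.binom_test_exact(18, 18, 0.5) == pytest.approx(7.6e-6, rel=0.02)
    assert statcore.binom_test_exact(5, 10, 0.5) == pytest.approx(1.0, abs=1e-12)
    assert statcore.binom_test_exact(0, 10, 0.5) == pytest.approx(2 * 2.0**-10, rel=1e-9)


def test_interval_invariants():
    iv = statcore.Interval(-1.0, 2.0)
    assert iv.contains(0.0) and not iv.contains(3.0)
    with pytest.raises(ValueError):
        statcore.Interval(2.0, 1.0)
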