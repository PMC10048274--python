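import numpy as np
import pytest
from scipy import stats

from mirprofile.accuracy_profile import (
    LevelData,
    anova_components,
    bias_recovery,
    build_profile,
    coverage_simulation,
    level_stats,
    lod,
    noncentrality_lambda,
    precision,
    profile_from_limits,
    r_prime,
    satterthwaite_k,
    tolerance_factor,
    tolerance_interval,
)


# -------------------------------------------------------------------- LOD
def test_lod_identical_blanks_is_zero():
    assert lod(np.full(10, 2.5)).lod == 0.0


def test_lod_hand_sd_oracle():
    res = lod(np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
    sd_hand = np.sqrt(np.sum((np.arange(5) - 2.0) ** 2) / 4.0)  # ~1.581
    assert res.s0 == pytest.approx(sd_hand)
    assert res.lod == pytest.approx(3 * sd_hand)


def test_lod_scale_equivariance():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    assert lod(2 * x).lod == pytest.approx(2 * lod(x).lod)
    with pytest.raises(ValueError, match="at least 2"):
        lod(np.array([1.0]))


# --------------------------------------------------------- bias / recovery
@pytest.mark.parametrize(
    "mean,yr,bias,recovery",
    [
        (6.52, 5.0, 30.4, 130.4),
        (10.67, 10.0, 6.7, 106.7),
        (20.43, 20.0, 2.15, 102.15),
        (49.72, 50.0, -0.56, 99.44),
    ],
)
def test_bias_recovery_known_values(mean, yr, bias, recovery):
    d = LevelData(y_r=yr, measurements=np.full((3, 3), mean))
    b, r, m = bias_recovery(d)
    assert b == pytest.approx(bias, abs=0.005)
    assert r == pytest.approx(recovery, abs=0.005)
    assert m == pytest.approx(mean)


def test_bias_zero_when_unbiased():
    d = LevelData(y_r=20.0, measurements=np.full((2, 2), 20.0))
    b, r, _ = bias_recovery(d)
    assert b == 0.0 and r == 100.0


def test_recovery_minus_100_equals_bias_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        d = LevelData(y_r=rng.uniform(1, 100),
                      measurements=rng.uniform(1, 100, size=(3, 4)))
        b, r, _ = bias_recovery(d)
        assert r - 100.0 == pytest.approx(b, abs=1e-12)


# ------------------------------------------------------------------ ANOVA
def test_anova_hand_oracle():
    d = LevelData(y_r=4.0, measurements=np.array([[1.0, 3.0], [5.0, 7.0]]))
    msb, mse = anova_components(d)
    assert mse == pytest.approx(2.0)
    assert msb == pytest.approx(16.0)


def test_anova_all_equal_is_zero():
    msb, mse = anova_components(LevelData(y_r=5.0, measurements=np.full((3, 3), 5.0)))
    assert msb == 0.0 and mse == 0.0


def test_anova_sum_of_squares_identity():
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(3, 3))
    d = LevelData(y_r=1.0, measurements=Y)
    msb, mse = anova_components(d)
    ss_total = np.sum((Y - Y.mean()) ** 2)
    assert (3 - 1) * msb + 3 * (3 - 1) * mse == pytest.approx(ss_total)


def test_leveldata_validation():
    with pytest.raises(ValueError, match="positive"):
        LevelData(y_r=0.0, measurements=np.ones((2, 2)))
    with pytest.raises(ValueError, match="2 days"):
        LevelData(y_r=5.0, measurements=np.ones((1, 3)))
    with pytest.raises(ValueError, match="finite"):
        LevelData(y_r=5.0, measurements=np.array([[1.0, np.nan], [1.0, 2.0]]))


# -------------------------------------------------------------- precision
def test_precision_hand_arithmetic():
    # MSE=2, MSB=16, n=2 -> s_re = sqrt(2), sigma_B^2 = 7, s_ip = 3
    d = LevelData(y_r=4.0, measurements=np.array([[1.0, 3.0], [5.0, 7.0]]))
    s_re, s_ip = precision(d)
    assert s_re == pytest.approx(np.sqrt(2.0))
    assert s_ip == pytest.approx(3.0)


def test_precision_collapses_when_no_day_effect():
    # within-day spread dominates: MSB <= MSE -> pooled SD with divisor mn-1
    Y = np.array([[1.0, 9.0, 5.0], [4.0, 6.0, 5.0]])
    d = LevelData(y_r=5.0, measurements=Y)
    msb, mse = anova_components(d)
    assert msb <= mse
    s_re, s_ip = precision(d)
    pooled = np.sqrt(np.sum((Y - Y.mean()) ** 2) / (Y.size - 1))
    assert s_re == s_ip == pytest.approx(pooled)


def test_ip_at_least_repeatability_random():
    rng = np.random.default_rng(2)
    for _ in range(30):
        d = LevelData(y_r=10.0, measurements=rng.normal(10, 2, size=(3, 3)))
        s_re, s_ip = precision(d)
        assert s_ip >= s_re - 1e-12


def test_zero_day_effect_ratio_tends_to_one():
    rng = np.random.default_rng(3)
    Y = rng.normal(50, 1, size=(20, 20))
    s_re, s_ip = precision(LevelData(y_r=50.0, measurements=Y))
    assert s_ip / s_re < 1.05


# ------------------------------------------------- variance-ratio bound R'
def test_r_prime_truncation_below_threshold():
    # the bound is zero whenever MSB/MSE falls below the lower F quantile
    m, n = 3, 3
    f_low = stats.f.ppf(0.15, m - 1, m * (n - 1))
    assert r_prime(0.5 * f_low, 1.0, m, n) == 0.0
    assert r_prime(1e-6, 1.0, m, n) == 0.0
    assert r_prime(1.01 * f_low, 1.0, m, n) > 0.0


def test_r_prime_hand_formula():
    m, n, ratio = 3, 3, 20.0
    f_low = stats.f.ppf(0.15, m - 1, m * (n - 1))
    expected = (ratio / f_low - 1.0) / n
    assert r_prime(ratio, 1.0, m, n) == pytest.approx(expected)
    with pytest.raises(ValueError, match="MSE"):
        r_prime(1.0, 0.0, m, n)


# ------------------------------------------------------- Satterthwaite df
def test_satterthwaite_direct_value():
    # R'=0, m=3, n=3 -> 1 / [(1/9)/2 + (2/3)/9] = 7.714...
    assert satterthwaite_k(0.0, 3, 3) == pytest.approx(1.0 / ((1 / 9) / 2 + (2 / 3) / 9))
    assert satterthwaite_k(0.0, 3, 3) == pytest.approx(7.7142857, abs=1e-6)


def test_satterthwaite_limit_between_day_dominated():
    assert satterthwaite_k(1e9, 4, 3) == pytest.approx(3.0, rel=1e-6)  # -> m-1


def test_satterthwaite_matches_generic_two_mean_squares():
    rng = np.random.default_rng(4)
    for _ in range(20):
        rp = rng.uniform(0, 5)
        m = rng.integers(2, 8)
        n = rng.integers(2, 8)
        msb, mse = n * rp + 1.0, 1.0  # expected mean squares at ratio rp
        var_hat = msb / n + (1 - 1 / n) * mse
        generic = var_hat**2 / (
            (msb / n) ** 2 / (m - 1) + ((1 - 1 / n) * mse) ** 2 / (m * (n - 1))
        )
        assert satterthwaite_k(rp, int(m), int(n)) == pytest.approx(generic)


# ------------------------------------------------------------ lambda
def test_lambda_direct_values_and_limits():
    assert noncentrality_lambda(0.0, 3, 3) == pytest.approx(1.0 / 3.0)
    assert noncentrality_lambda(0.0, 4, 5) == pytest.approx(1.0 / np.sqrt(20))
    assert noncentrality_lambda(1e12, 3, 3) == pytest.approx(1.0 / np.sqrt(3), rel=1e-5)


def test_lambda_squared_equals_mc_variance_ratio():
    """lambda^2 = Var(grand mean)/sigma_IP^2 by Monte-Carlo at R'=1, m=n=3."""
    rp, m, n = 1.0, 3, 3
    sigma_b2, sigma_e2 = rp, 1.0
    rng = np.random.default_rng(5)
    draws = 100_000
    b = rng.normal(0, np.sqrt(sigma_b2), size=(draws, m))
    e = rng.normal(0, np.sqrt(sigma_e2), size=(draws, m, n))
    gm = (b[:, :, None] + e).mean(axis=(1, 2))
    var_mc = gm.var()
    sigma_ip2 = sigma_e2 + sigma_b2
    assert noncentrality_lambda(rp, m, n) ** 2 == pytest.approx(
        var_mc / sigma_ip2, rel=0.02
    )


# --------------------------------------------------------- tolerance factor
def test_tolerance_factor_normal_limit():
    # k -> inf, lambda -> 0: chi_k -> z_{(1+beta)/2} ~ 0.967 for beta = 0.667
    val = tolerance_factor(1e7, 1e-9, beta=0.667, gamma=0.9)
    assert val == pytest.approx(stats.norm.ppf((1 + 0.667) / 2), abs=1e-3)


def test_tolerance_factor_gamma_half_large_k():
    k = 5e6
    lam = 0.2
    val = tolerance_factor(k, lam, beta=0.667, gamma=0.5)
    assert val == pytest.approx(np.sqrt(stats.ncx2.ppf(0.667, 1, lam**2)), rel=1e-3)


def test_tolerance_factor_monotonicity_grid():
    ks = [2.0, 4.0, 8.0, 16.0, 50.0]
    lams = [0.05, 0.2, 0.4, 0.6, 0.9]
    gammas = [0.6, 0.7, 0.8, 0.9, 0.95]
    for lam in lams:
        for g in gammas:
            vals = [tolerance_factor(k, lam, 0.667, g) for k in ks]
            assert all(a > b for a, b in zip(vals, vals[1:]))  # decreasing in k
    for k in ks:
        for g in gammas:
            vals = [tolerance_factor(k, lam, 0.667, g) for lam in lams]
            assert all(a < b for a, b in zip(vals, vals[1:]))  # increasing in lambda
    for k in ks:
        for lam in lams:
            vals = [tolerance_factor(k, lam, 0.667, g) for g in gammas]
            assert all(a < b for a, b in zip(vals, vals[1:]))  # increasing in gamma


def test_tolerance_factor_validation():
    with pytest.raises(ValueError, match="beta"):
        tolerance_factor(5.0, 0.1, beta=1.2)
    with pytest.raises(ValueError, match="positive"):
        tolerance_factor(0.0, 0.1)


# ------------------------------------------------------- tolerance interval
def test_interval_degenerates_without_spread():
    d = LevelData(y_r=50.0, measurements=np.full((3, 3), 51.0))
    iv = tolerance_interval(level_stats(d))
    assert iv.l_pct == iv.u_pct == pytest.approx(2.0)


def test_interval_contains_bias():
    rng = np.random.default_rng(6)
    for _ in range(20):
        d = LevelData(y_r=50.0, measurements=rng.normal(50, 3, size=(3, 3)))
        iv = tolerance_interval(level_stats(d))
        assert iv.l_pct <= iv.bias_pct <= iv.u_pct


def test_interval_widens_with_gamma(toy_level):
    st_ = level_stats(toy_level)
    widths = [
        tolerance_interval(st_, gamma=g).u_pct - tolerance_interval(st_, gamma=g).l_pct
        for g in (0.6, 0.8, 0.9, 0.95)
    ]
    assert all(a < b for a, b in zip(widths, widths[1:]))


def test_interval_end_to_end_hand_chain(toy_level):
    """Every step of the tolerance-interval chain recomputed independently."""
    Y = toy_level.measurements
    m, n, yr = 3, 3, 50.0
    grand = Y.mean()
    bias = 100 * (grand - yr) / yr
    day_means = Y.mean(axis=1)
    msb = n * np.sum((day_means - grand) ** 2) / (m - 1)
    mse = np.sum((Y - day_means[:, None]) ** 2) / (m * (n - 1))
    assert msb == pytest.approx(7.0) and mse == pytest.approx(4.0)
    s_ip2 = mse + (msb - mse) / n
    rsd = 100 * np.sqrt(s_ip2) / yr
    f_low = stats.f.ppf(0.15, m - 1, m * (n - 1))
    rp = max(0.0, (msb / (mse * f_low) - 1.0) / n)
    k = (rp + 1) ** 2 / ((rp + 1 / n) ** 2 / (m - 1) + (1 - 1 / n) / (m * n))
    lam2 = (n * rp + 1) / (m * n * (rp + 1))
    chik = np.sqrt(k * stats.ncx2.ppf(0.667, 1, lam2) / stats.chi2.ppf(0.1, k))
    iv = tolerance_interval(level_stats(toy_level))
    assert iv.bias_pct == pytest.approx(bias)
    assert iv.r_prime == pytest.approx(rp)
    assert iv.k == pytest.approx(k)
    assert iv.lam**2 == pytest.approx(lam2)
    assert iv.chi_k == pytest.approx(chik)
    assert iv.l_pct == pytest.approx(bias - chik * rsd)
    assert iv.u_pct == pytest.approx(bias + chik * rsd)
    assert iv.l_abs == pytest.approx(yr * (1 + iv.l_pct / 100))


# ----------------------------------------------------------------- profile
def test_profile_all_levels_valid():
    rng = np.random.default_rng(7)
    levels = [
        LevelData(y_r=c, measurements=rng.normal(c, 0.005 * c, size=(3, 3)))
        for c in (10.0, 20.0, 50.0)
    ]
    prof = build_profile(levels)
    assert all(prof.within_acceptance)
    assert prof.lloq == 10.0 and prof.uloq == 50.0


def test_profile_constructed_crossing_exact():
    # upper limit falls 30 -> 10 between levels 10 and 20; crosses +20 at 15
    prof = profile_from_limits([10.0, 20.0], [-5.0, -5.0], [30.0, 10.0])
    assert prof.lloq == pytest.approx(15.0)
    assert prof.uloq == 20.0


def test_profile_no_valid_level_warns():
    with pytest.warns(UserWarning, match="LLOQ/ULOQ undefined"):
        prof = profile_from_limits([5.0, 10.0], [-50.0, -40.0], [50.0, 60.0])
    assert prof.lloq is None and prof.uloq is None


def test_profile_flags_high_cv():
    rng = np.random.default_rng(8)
    noisy = LevelData(y_r=5.0, measurements=rng.normal(5, 3, size=(3, 3)))
    clean = LevelData(y_r=50.0, measurements=rng.normal(50, 0.5, size=(3, 3)))
    prof = build_profile([noisy, clean])
    assert prof.cv_exceeds[0] and not prof.cv_exceeds[1]


def test_profile_input_validation():
    d = LevelData(y_r=5.0, measurements=np.ones((2, 2)))
    with pytest.raises(ValueError, match="2 levels"):
        build_profile([d])
    with pytest.raises(ValueError, match="distinct"):
        build_profile([d, LevelData(y_r=5.0, measurements=np.ones((2, 2)))])


# ---------------------------------------------------------------- coverage
def test_coverage_degenerate_is_certain():
    assert coverage_simulation(sigma_b=0.0, sigma_e=0.0, n_sims=200, seed=0) == 1.0


def test_coverage_near_nominal_small_run():
    conf = coverage_simulation(m=3, n=3, sigma_b=1.0, sigma_e=1.0, n_sims=400, seed=1)
    assert conf >= 0.85
    with pytest.raises(ValueError, match="n_sims"):
        coverage_simulation(n_sims=50)
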