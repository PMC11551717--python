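"""Wald ratio, IVW and MR-Egger against closed-form and WLS oracles."""
import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.estimators import egger, ivw, to_odds_ratio, wald_ratio, MrEstimate
from mrmediate.exceptions import (DegenerateInputError, InsufficientInstrumentsError,
                                  UndefinedRatioError)

from conftest import make_hset


def test_wald_ratio_arithmetic():
    est = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01, "beta_out": 0.2, "se_out": 0.05})
    assert est.beta == pytest.approx(2.0)
    assert est.se == pytest.approx(0.5)
    null = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01, "beta_out": 0.0, "se_out": 0.05})
    assert null.beta == 0.0 and null.odds_ratio == 1.0
    with pytest.raises(UndefinedRatioError):
        wald_ratio({"beta_exp": 0.0, "se_exp": 0.01, "beta_out": 0.2, "se_out": 0.05})


def test_single_snp_ivw_equals_wald_ratio_exactly():
    hset = make_hset([0.12], [0.01], [0.05], [0.02])
    assert ivw(hset) == wald_ratio(hset.table.iloc[0])


def test_identical_wald_ratios_are_homogeneous():
    bx = np.array([0.1, 0.2])
    hset = make_hset(bx, [0.01, 0.01], 1.7 * bx, [0.02, 0.03])
    fixed = ivw(hset, mode="fixed")
    mre = ivw(hset, mode="multiplicative_random")
    assert fixed.beta == pytest.approx(1.7, abs=1e-14)
    assert mre.beta == fixed.beta
    assert mre.se == fixed.se  # Q = 0 -> no inflation


@pytest.mark.parametrize("seed", range(5))
def test_ivw_equals_weighted_mean_of_wald_ratios(seed, ):
    """Ratio-form oracle: beta = sum(w_j r_j)/sum(w_j), w_j = bx^2/sy^2."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 9))
    bx = rng.normal(0.2, 0.08, m)
    sy = rng.uniform(0.01, 0.05, m)
    by = 0.5 * bx + rng.normal(0, 0.05, m)
    hset = make_hset(bx, np.full(m, 0.01), by, sy)
    w = bx ** 2 / sy ** 2
    oracle = np.sum(w * (by / bx)) / np.sum(w)
    est = ivw(hset, mode="fixed")
    assert est.beta == pytest.approx(oracle, abs=1e-12)
    assert est.se == pytest.approx(1.0 / np.sqrt(np.sum(w)), abs=1e-12)


def test_ivw_cross_checked_against_statsmodels_wls(random_hset):
    bx, _, by, sy = random_hset.arrays()
    fit = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit()
    est = ivw(random_hset, mode="fixed")
    assert est.beta == pytest.approx(fit.params[0], abs=1e-12)
    mre = ivw(random_hset, mode="multiplicative_random")
    q = np.sum((by - est.beta * bx) ** 2 / sy ** 2)
    scale = max(1.0, np.sqrt(q / (random_hset.n_snp - 1)))
    assert mre.se == pytest.approx(est.se * scale, abs=1e-14)
    if q / (random_hset.n_snp - 1) >= 1:
        # statsmodels estimates the same multiplicative dispersion
        assert mre.se == pytest.approx(fit.bse[0], rel=1e-10)


def test_egger_cross_checked_against_statsmodels_wls(random_hset):
    bx, _, by, sy = random_hset.arrays()
    sign = np.where(bx < 0, -1, 1)
    x, y = sign * bx, sign * by
    fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy ** 2).fit()
    slope, intercept = egger(random_hset)
    assert intercept.beta == pytest.approx(fit.params[0], abs=1e-12)
    assert slope.beta == pytest.approx(fit.params[1], abs=1e-12)
    q = np.sum((y - fit.params[0] - fit.params[1] * x) ** 2 / sy ** 2)
    if q / (random_hset.n_snp - 2) >= 1:
        assert slope.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert intercept.se == pytest.approx(fit.bse[0], rel=1e-10)


def test_egger_slope_with_zero_intercept_is_ivw(random_hset):
    """Constraining the Egger intercept to zero recovers the IVW fit."""
    bx, _, by, sy = random_hset.arrays()
    sign = np.where(bx < 0, -1, 1)
    fit = sm.WLS(sign * by, sign * bx, weights=1.0 / sy ** 2).fit()
    assert fit.params[0] == pytest.approx(ivw(random_hset, mode="fixed").beta,
                                          abs=1e-12)


def test_egger_requires_three_instruments_and_spread():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2))
    with pytest.raises(DegenerateInputError):
        egger(make_hset([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.02] * 4))


def test_egger_recovers_directional_pleiotropy(rng):
    m = 40
    bx = np.abs(rng.normal(0.3, 0.1, m))
    sy = np.full(m, 0.02)
    by = 0.05 + 0.4 * bx + rng.normal(0, sy)
    slope, intercept = egger(make_hset(bx, np.full(m, 0.005), by, sy))
    assert abs(intercept.beta - 0.05) < 2 * intercept.se
    assert abs(slope.beta - 0.4) < 2 * slope.se


def test_odds_ratio_fields_and_published_values():
    # printed-precision agreement with reported screening odds ratios
    est = to_odds_ratio(MrEstimate("ivw_mre", 10, 0.9517, 0.3258, 0.004))
    assert est.odds_ratio == pytest.approx(2.590, abs=1.5e-3)
    est2 = to_odds_ratio(MrEstimate("ivw_mre", 5, -1.313, 0.598, 0.028))
    assert est2.odds_ratio == pytest.approx(0.269, abs=1.5e-3)
    null = to_odds_ratio(MrEstimate("wald_ratio", 1, 0.0, 0.1, 1.0))
    assert null.odds_ratio == 1.0
    assert null.ci_low * null.ci_high == pytest.approx(1.0)  # symmetric on log scale
    assert est.ci_low < est.odds_ratio < est.ci_high


def test_ivw_invariances(random_hset):
    base = ivw(random_hset, mode="fixed")
    # SNP order
    perm = random_hset.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    from mrmediate.harmonize import HarmonizedInstrumentSet
    shuffled = HarmonizedInstrumentSet("exp", "out", perm)
    assert ivw(shuffled, mode="fixed").beta == pytest.approx(base.beta, abs=1e-12)
    # scaling both exposure and outcome leaves the ratio unchanged
    t = random_hset.table.copy()
    t[["beta_exp", "beta_out"]] *= 3.0
    both = HarmonizedInstrumentSet("exp", "out", t)
    assert ivw(both, mode="fixed").beta == pytest.approx(base.beta, abs=1e-12)
    # scaling the exposure alone divides the estimate
    t2 = random_hset.table.copy()
    t2["beta_exp"] *= 2.0
    assert ivw(HarmonizedInstrumentSet("exp", "out", t2), mode="fixed").beta \
        == pytest.approx(base.beta / 2.0, abs=1e-12)
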