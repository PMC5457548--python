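"""Cost standardization, estimators and bootstrap inference."""

import numpy as np
import pytest
import statsmodels.api as sm

from claimsce.codelists import CodeListError
from claimsce.iptw import EstimationError
from claimsce.outcomes import (
    apply_brand_discount,
    bootstrap_inference,
    estimate_mmcd,
    estimate_rr,
    monthly_costs,
    standardize_costs,
    stratified_resample,
    utilization,
)
from claimsce.pipeline import build_cohort


# ---------------------------------------------------------------------------
# CPI standardization and brand discount


def test_standardize_identity_year():
    assert standardize_costs([100.0], [2015])[0] == pytest.approx(100.0)


def test_standardize_index_ratio():
    cpi = {2014: 100.0, 2015: 105.0}
    assert standardize_costs([100.0], [2014], cpi)[0] == pytest.approx(105.0)


def test_standardize_linearity(rng):
    years = rng.choice([2009, 2012, 2014], 50)
    a, b = rng.random(50) * 100, rng.random(50) * 100
    lhs = standardize_costs(a + b, years)
    rhs = standardize_costs(a, years) + standardize_costs(b, years)
    assert np.allclose(lhs, rhs)


def test_standardize_missing_year_raises():
    with pytest.raises(CodeListError, match="2003"):
        standardize_costs([1.0], [2003])


def test_brand_discount():
    out = apply_brand_discount([100.0, 100.0], [True, False])
    assert out[0] == pytest.approx(76.9)
    assert out[1] == pytest.approx(100.0)


def test_brand_discount_scales_all_branded_total(rng):
    amounts = rng.random(100) * 50
    total = apply_brand_discount(amounts, np.ones(100, bool)).sum()
    assert total == pytest.approx(0.769 * amounts.sum())


def test_brand_discount_bad_rate():
    with pytest.raises(ValueError):
        apply_brand_discount([1.0], [True], rate=1.5)


# ---------------------------------------------------------------------------
# Per-patient cost and utilization records


def test_monthly_costs_fixture_hand_computed(fixture_bundle):
    table, _, _ = build_cohort(fixture_bundle, "2009-09-01")
    costs = monthly_costs(fixture_bundle, table)
    f2010 = 446.752 / 388.436
    # P01 follow-up year: six 800 USD fills, one 5000 USD inpatient stay
    assert costs.loc["P01", "pharmacy"] == pytest.approx(6 * 800 * f2010 / 12, rel=1e-9)
    assert costs.loc["P01", "inpatient"] == pytest.approx(5000 * f2010 / 12, rel=1e-9)
    assert costs.loc["P01", "outpatient"] == 0.0
    assert costs.loc["P01", "total_medical"] == costs.loc["P01", "inpatient"]
    assert costs.loc["P01", "total"] == pytest.approx(
        costs.loc["P01", "pharmacy"] + costs.loc["P01", "total_medical"]
    )


def test_monthly_costs_category_identities(fixture_bundle):
    table, _, _ = build_cohort(fixture_bundle, "2009-09-01")
    costs = monthly_costs(fixture_bundle, table)
    med_cols = [c for c in costs.columns if c not in ("pharmacy", "total_medical", "total")]
    assert np.allclose(costs["total_medical"], costs[med_cols].sum(axis=1))
    assert np.allclose(costs["total"], costs["total_medical"] + costs["pharmacy"])


def test_monthly_costs_discount_reduces_branded_only(fixture_bundle):
    table, _, _ = build_cohort(fixture_bundle, "2009-09-01")
    main = monthly_costs(fixture_bundle, table)
    disc = monthly_costs(fixture_bundle, table, discount=True)
    # P01's fills are branded, P09's generic
    assert disc.loc["P01", "pharmacy"] == pytest.approx(0.769 * main.loc["P01", "pharmacy"])
    assert disc.loc["P09", "pharmacy"] == pytest.approx(main.loc["P09", "pharmacy"])


def test_utilization_fixture(fixture_bundle):
    table, _, _ = build_cohort(fixture_bundle, "2009-09-01")
    util = utilization(fixture_bundle, table)
    assert util.loc["P01", "inpatient_events"] == 1
    assert util.loc["P01", "inpatient_days"] == 5  # 2010-05-10 .. 2010-05-14
    assert util.loc["P09", "inpatient_events"] == 0
    # P01's baseline MHI admission (2009) is outside the follow-up window
    assert util.loc["P01", "mhi_admission_events"] == 0


# ---------------------------------------------------------------------------
# Point estimators


def test_mmcd_examples():
    y = np.array([10.0, 20.0, 10.0, 10.0])
    t = np.array([1, 1, 0, 0])
    assert estimate_mmcd(y, t, np.ones(4)) == pytest.approx(5.0, abs=1e-12)
    assert estimate_mmcd(np.r_[y, y], np.r_[t, t], np.ones(8)) == pytest.approx(5.0)
    assert estimate_mmcd(np.ones(4), t, np.ones(4)) == pytest.approx(0.0, abs=1e-12)


def test_mmcd_equals_weighted_mean_difference(rng):
    for _ in range(200):
        n = int(rng.integers(4, 60))
        y = rng.random(n) * 10
        t = rng.random(n) < 0.5
        if t.all() or (~t).all():
            continue
        w = rng.uniform(0.1, 3.0, n)
        direct = (w[t] * y[t]).sum() / w[t].sum() - (w[~t] * y[~t]).sum() / w[~t].sum()
        assert estimate_mmcd(y, t, w) == pytest.approx(direct, abs=1e-10)


def test_mmcd_matches_statsmodels_wls(rng):
    n = 200
    y = rng.random(n) * 100
    t = rng.random(n) < 0.4
    w = rng.uniform(0.2, 2.0, n)
    ref = sm.WLS(y, sm.add_constant(t.astype(float)), weights=w).fit()
    assert estimate_mmcd(y, t, w) == pytest.approx(ref.params[1], abs=1e-8)


def test_rr_examples():
    # treated: 10 events over 5 person-years; comparator: 4 over 4
    y = np.array([10.0, 4.0])
    t = np.array([1, 0])
    py = np.array([5.0, 4.0])
    assert estimate_rr(y, t, np.ones(2), py) == pytest.approx(2.0, abs=1e-8)
    y2 = np.array([3.0, 3.0, 3.0, 3.0])
    t2 = np.array([1, 1, 0, 0])
    assert estimate_rr(y2, t2, np.ones(4)) == pytest.approx(1.0, abs=1e-10)


def test_rr_equals_weighted_rate_ratio(rng):
    for _ in range(200):
        n = int(rng.integers(6, 80))
        y = rng.poisson(2.0, n).astype(float)
        t = rng.random(n) < 0.5
        w = rng.uniform(0.1, 3.0, n)
        if (w[t] * y[t]).sum() == 0 or (w[~t] * y[~t]).sum() == 0:
            continue
        direct = ((w[t] * y[t]).sum() / w[t].sum()) / ((w[~t] * y[~t]).sum() / w[~t].sum())
        assert estimate_rr(y, t, w) == pytest.approx(direct, abs=1e-8)


def test_rr_matches_statsmodels_poisson(rng):
    n = 300
    y = rng.poisson(1.5, n).astype(float)
    t = rng.random(n) < 0.4
    if (y[t].sum() == 0) or (y[~t].sum() == 0):
        pytest.skip("degenerate draw")
    ref = sm.GLM(y, sm.add_constant(t.astype(float)), family=sm.families.Poisson()).fit()
    assert estimate_rr(y, t, np.ones(n)) == pytest.approx(np.exp(ref.params[1]), abs=1e-7)


def test_rr_zero_comparator_raises():
    with pytest.raises(EstimationError, match="comparator"):
        estimate_rr(np.array([3.0, 0.0]), np.array([1, 0]), np.ones(2))


# ---------------------------------------------------------------------------
# Bootstrap


def test_stratified_resample_preserves_cohort_sizes(rng):
    t = np.r_[np.ones(30, bool), np.zeros(70, bool)]
    idx = stratified_resample(rng, t)
    assert t[idx].sum() == 30
    assert len(idx) == 100


def test_bootstrap_degenerate_data_zero_width_ci():
    t = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    y = np.full(20, 7.0)

    def stat(idx):
        return estimate_mmcd(y[idx], t[idx], np.ones(len(idx)))

    est = bootstrap_inference(stat, t, B=99, seed=1)
    assert est.ci_low == est.ci_high == est.estimate == 0.0


def test_bootstrap_deterministic_under_seed(rng):
    t = np.r_[np.ones(25, bool), np.zeros(25, bool)]
    y = rng.random(50) * 10

    def stat(idx):
        return estimate_mmcd(y[idx], t[idx], np.ones(len(idx)))

    a = bootstrap_inference(stat, t, B=99, seed=7)
    b = bootstrap_inference(stat, t, B=99, seed=7)
    assert (a.ci_low, a.ci_high, a.p_value) == (b.ci_low, b.ci_high, b.p_value)
    c = bootstrap_inference(stat, t, B=99, seed=8)
    assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)


def test_bootstrap_point_inside_ci_for_smooth_stat(rng):
    t = np.r_[np.ones(40, bool), np.zeros(40, bool)]
    y = rng.normal(5, 1, 80) + t * 2

    def stat(idx):
        return estimate_mmcd(y[idx], t[idx], np.ones(len(idx)))

    est = bootstrap_inference(stat, t, B=199, seed=3)
    assert est.ci_low <= est.estimate <= est.ci_high


def test_bootstrap_failure_rate_guard():
    t = np.r_[np.ones(5, bool), np.zeros(5, bool)]

    def stat(idx):
        # succeeds on the full sample, fails on (almost) every resample
        if len(np.unique(idx)) < len(idx):
            raise EstimationError("resample fails")
        return 0.0

    with pytest.raises(EstimationError, match="replicates failed"):
        bootstrap_inference(stat, t, B=20, seed=0)
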