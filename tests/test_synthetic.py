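"""Synthetic generator: determinism, marginals, injected effects, degenerates."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from claimsce.claims_io import validate_bundle
from claimsce.patterns import compute_pdc, coverage_intervals
from claimsce.pipeline import build_cohort
from claimsce.synthetic import (
    DegenerateCases,
    EnrollmentModel,
    FillModel,
    GeneratorConfig,
    OutcomeModel,
    assign_treatment,
    expected_monthly_cost,
    generate_bundle,
    generate_covariates,
    generate_fills,
    generate_frame,
)
from oracles import oracle_pdc


def test_config_validation():
    with pytest.raises(ValueError, match="n_patients"):
        GeneratorConfig(n_patients=1)
    with pytest.raises(ValueError, match="probabilities"):
        GeneratorConfig.from_dict({"covariates": {"race_probs": {"white": 0.5}}})
    with pytest.raises(ValueError, match="gamma_shape"):
        GeneratorConfig.from_dict({"outcomes": {"gamma_shape": 0.0}})


def test_covariate_marginals_converge(rng):
    cfg = GeneratorConfig(n_patients=10_000, seed=7)
    cov = generate_covariates(cfg, np.random.default_rng(7))
    assert abs(cov["female"].mean() - 0.5) < 0.02
    assert abs((cov["race"] == "white").mean() - 0.55) < 0.02


def test_degenerate_categorical_probabilities():
    cfg = GeneratorConfig.from_dict(
        {"n_patients": 50, "covariates": {"race_probs": {"white": 1.0}}}
    )
    cov = generate_covariates(cfg, np.random.default_rng(0))
    assert (cov["race"] == "white").all()


def test_generator_determinism():
    cfg = GeneratorConfig(n_patients=60, seed=5)
    f1, _ = generate_frame(cfg)
    f2, _ = generate_frame(cfg)
    pd.testing.assert_frame_equal(f1, f2)
    b1, _ = generate_bundle(cfg)
    b2, _ = generate_bundle(cfg)
    for name in ("patients", "enrollment", "pharmacy", "medical"):
        pd.testing.assert_frame_equal(getattr(b1, name), getattr(b2, name))
    b3, _ = generate_bundle(cfg, seed=6)
    assert not b3.pharmacy.equals(b1.pharmacy)


def test_zero_beta_gives_half_probabilities():
    cfg = GeneratorConfig(n_patients=100, seed=0)
    cov = generate_covariates(cfg, np.random.default_rng(0))
    _, p = assign_treatment(cov, {"intercept": 0.0}, np.random.default_rng(1))
    assert np.allclose(p, 0.5)


def test_unknown_beta_name_raises():
    cfg = GeneratorConfig(n_patients=10, seed=0)
    cov = generate_covariates(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError, match="nope"):
        assign_treatment(cov, {"nope": 1.0}, np.random.default_rng(1))


def test_positive_age_coefficient_monotone_in_age():
    cfg = GeneratorConfig(n_patients=10_000, seed=3)
    cov = generate_covariates(cfg, np.random.default_rng(3))
    treated, _ = assign_treatment(cov, {"intercept": 0.0, "age_c": 1.0}, np.random.default_rng(4))
    q = pd.qcut(cov["age"], 5, labels=False, duplicates="drop")
    frac = pd.Series(treated).groupby(q).mean()
    assert frac.is_monotonic_increasing


# ---------------------------------------------------------------------------
# Fill model


def test_fills_continuous_coverage_gives_pdc_one():
    fm = FillModel(gap_fixed=0, days_supply=30, disc_prob_treated=0.0)
    days = generate_fills(0, 364, fm, True, np.random.default_rng(0))
    assert len(days) == 13
    fills = pd.DataFrame({"day": days, "days_supply": 30})
    assert compute_pdc(coverage_intervals(fills, (0, 364))) == 1.0


def test_fills_fixed_gap_halves_pdc():
    fm = FillModel(gap_fixed=30, days_supply=30, disc_prob_treated=0.0)
    days = generate_fills(0, 364, fm, True, np.random.default_rng(0))
    got = compute_pdc(coverage_intervals(pd.DataFrame({"day": days, "days_supply": 30}), (0, 364)))
    want = oracle_pdc([(d, 30) for d in days], (0, 364))
    assert got == pytest.approx(want)
    assert got == pytest.approx(0.5, abs=0.02)


def test_first_two_fills_within_90_days(rng):
    fm = FillModel(gap_mean_comparator=50.0)  # heavy gaps still capped for fill 2
    for s in range(50):
        days = generate_fills(0, 364, fm, False, np.random.default_rng(s))
        if len(days) >= 2:
            assert days[1] - days[0] <= 90


def test_fill_determinism():
    fm = FillModel()
    a = generate_fills(0, 364, fm, True, np.random.default_rng(9))
    b = generate_fills(0, 364, fm, True, np.random.default_rng(9))
    assert a == b


# ---------------------------------------------------------------------------
# Outcome model


def test_expected_cost_difference_equals_injected_delta():
    cfg = GeneratorConfig(n_patients=500, seed=0)
    cov = generate_covariates(cfg, np.random.default_rng(0))
    mu1 = expected_monthly_cost(cov, np.ones(len(cov)), cfg.outcomes)
    mu0 = expected_monthly_cost(cov, np.zeros(len(cov)), cfg.outcomes)
    total_diff = sum((mu1[c] - mu0[c]).mean() for c in mu1 if c != "pharmacy")
    assert total_diff == pytest.approx(sum(cfg.outcomes.delta_monthly.values()), abs=1e-9)
    assert (mu1["pharmacy"] - mu0["pharmacy"]).mean() == pytest.approx(322.0)


def test_null_model_arms_indistinguishable():
    cfg = GeneratorConfig(
        n_patients=10_000, seed=1,
        outcomes=OutcomeModel(delta_monthly={}, delta_pharmacy=0.0, rr_true=1.0),
        treatment=dataclasses.replace(GeneratorConfig().treatment, beta={"intercept": 0.0}),
    )
    frame, _ = generate_frame(cfg)
    t = frame["treated"].to_numpy(bool)
    y = frame["cost_total_medical"].to_numpy()
    diff = y[t].mean() - y[~t].mean()
    se = np.sqrt(y[t].var() / t.sum() + y[~t].var() / (~t).sum())
    assert abs(diff) < 3 * se


def test_rate_ratio_injection_recovered_marginally():
    cfg = GeneratorConfig(
        n_patients=10_000, seed=2,
        outcomes=dataclasses.replace(GeneratorConfig().outcomes, rr_true=0.5),
        treatment=dataclasses.replace(GeneratorConfig().treatment, beta={"intercept": 0.0}),
    )
    frame, truth = generate_frame(cfg)
    t = frame["treated"].to_numpy(bool)
    y = frame["ev_outpatient"].to_numpy()
    rr = y[t].mean() / y[~t].mean()
    assert 0.45 <= rr <= 0.55
    assert truth.rr_true == 0.5


def test_zero_mass_probability_one_gives_zero_costs():
    om = OutcomeModel(zero_prob={c: 1.0 for c in GeneratorConfig().outcomes.zero_prob})
    cfg = GeneratorConfig(n_patients=200, seed=0, outcomes=om)
    frame, _ = generate_frame(cfg)
    assert (frame["cost_total_medical"] == 0).all()


# ---------------------------------------------------------------------------
# Bundle materialization


def test_default_bundle_valid_and_mostly_included():
    cfg = GeneratorConfig(n_patients=500, seed=1)
    bundle, truth = generate_bundle(cfg)
    assert validate_bundle(bundle, strict=True) == []
    table, _, _ = build_cohort(bundle, cfg.accrual_start)
    assert len(table) >= 0.9 * 500
    # cohort labels agree with the generator's assignment
    merged = table.merge(truth.per_patient, on="patient_id")
    assert ((merged["cohort"] == "PP1M") == merged["treated"]).all()


def test_baseline_enrollment_gap_excludes_everyone():
    cfg = GeneratorConfig(
        n_patients=60, seed=2, enrollment=EnrollmentModel(baseline_gap_prob=1.0)
    )
    bundle, _ = generate_bundle(cfg)
    from claimsce.cohort import apply_inclusion, find_index_events

    events = find_index_events(bundle, cfg.accrual_start)
    assert events  # index events exist, but criterion (d) fails
    assert all(not apply_inclusion(bundle, ev).flags["d_pre_enrollment"] for ev in events)


def test_no_second_fill_prevents_index_events():
    cfg = GeneratorConfig(
        n_patients=40, seed=3,
        degenerate=DegenerateCases(p_no_second_fill=1.0),
        fills=FillModel(p_second_ap=0.0),
    )
    bundle, _ = generate_bundle(cfg)
    from claimsce.cohort import find_index_events

    assert find_index_events(bundle, cfg.accrual_start) == []


def test_washout_violation_prevents_index_events():
    cfg = GeneratorConfig(
        n_patients=40, seed=4,
        degenerate=DegenerateCases(p_washout_violation=1.0),
        fills=FillModel(p_second_ap=0.0),
    )
    bundle, _ = generate_bundle(cfg)
    from claimsce.cohort import find_index_events

    assert find_index_events(bundle, cfg.accrual_start) == []


def test_single_dx_fails_criterion_b():
    cfg = GeneratorConfig(n_patients=40, seed=5, degenerate=DegenerateCases(p_single_dx=1.0))
    bundle, _ = generate_bundle(cfg)
    table, decisions, _ = build_cohort(bundle, cfg.accrual_start)
    assert len(table) == 0
    assert all(d.exclusion_reason == "b_schizophrenia_dx" for d in decisions)


def test_underage_fails_criterion_c():
    cfg = GeneratorConfig(n_patients=40, seed=6, degenerate=DegenerateCases(p_underage=1.0))
    bundle, _ = generate_bundle(cfg)
    table, decisions, _ = build_cohort(bundle, cfg.accrual_start)
    assert len(table) == 0
    assert all(not d.flags["c_age_18"] for d in decisions)
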