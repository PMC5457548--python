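"""Interval algebra: coverage, PDC, persistence, exposure, polypharmacy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claimsce.claims_io import AP_CLASSES, PSYCH_CLASSES
from claimsce.patterns import (
    bridge_intervals,
    compute_pdc,
    continuous_exposure,
    coverage_intervals,
    detect_polypharmacy,
    fill_intervals,
    intersect_intervals,
    merge_intervals,
    persistence_flags,
    summarize_patterns,
)
from oracles import (
    day_array,
    oracle_continuous_exposure,
    oracle_pdc,
    oracle_persistence,
    oracle_polypharmacy,
)

WINDOW = (0, 364)


def _fills_df(fills):
    return pd.DataFrame(fills, columns=["day", "days_supply"])


def _cal(fills, window=WINDOW):
    return coverage_intervals(_fills_df(fills), window)


# ---------------------------------------------------------------------------
# Worked examples


@pytest.mark.parametrize(
    "fills,expected",
    [
        ([(0, 30), (30, 30)], [(0, 59)]),  # abutting fills merge
        ([(0, 30), (15, 30)], [(0, 44)]),  # overlapping supply collapses
        ([(0, 30), (100, 30)], [(0, 29), (100, 129)]),
        ([], []),
    ],
)
def test_coverage_union_examples(fills, expected):
    assert _cal(fills).intervals == expected


def test_stockpile_mode_carries_overlap_forward():
    ivs = fill_intervals(np.array([0, 15]), np.array([30, 30]), mode="stockpile")
    assert ivs == [(0, 59)]


def test_pdc_examples():
    assert compute_pdc(_cal([(0, 30), (30, 30)])) == pytest.approx(60 / 365)
    full = _cal([(d, 30) for d in range(0, 365, 30)])
    assert compute_pdc(full) == 1.0


@pytest.mark.parametrize(
    "fills,expected_duration,expected_n",
    [
        ([(0, 30)], 30, 1),
        ([(0, 30), (200, 30)], 30, 2),  # 170-day gap ends the chain
        ([(0, 30), (30, 30), (60, 30)], 90, 3),
        ([(0, 30), (119, 30)], 149, 2),  # gap of 90 from supply end: chain holds
        ([(0, 30), (120, 30)], 30, 2),  # gap of 90... measured from supply end day 29
    ],
)
def test_continuous_exposure_examples(fills, expected_duration, expected_n):
    dur, n = continuous_exposure(_fills_df(fills), 0, WINDOW)
    assert n == expected_n
    oracle = oracle_continuous_exposure(fills, 0, WINDOW)
    assert (dur, n) == oracle
    assert dur == expected_duration


def test_continuous_exposure_fill_date_anchor():
    # successor 100 days after the fill date but only 70 after supply end
    fills = [(0, 30), (100, 30)]
    dur_supply, _ = continuous_exposure(_fills_df(fills), 0, WINDOW, anchor="supply_end")
    dur_fill, _ = continuous_exposure(_fills_df(fills), 0, WINDOW, anchor="fill_date")
    assert dur_supply == 130
    assert dur_fill == 30  # 100 > 90 from the fill date


def test_persistence_single_gap_example():
    cal = _cal([(0, 30), (100, 30)])
    flags = persistence_flags(cal, count_terminal_gap=False)
    assert flags == {30: False, 60: False, 90: True}  # one 70-day gap
    # terminal mode adds the 235-day run after day 129
    flags_t = persistence_flags(cal, count_terminal_gap=True)
    assert flags_t == {30: False, 60: False, 90: False}


def test_persistence_full_coverage():
    cal = _cal([(d, 30) for d in range(0, 365, 30)])
    assert persistence_flags(cal) == {30: True, 60: True, 90: True}


def test_polypharmacy_examples():
    a = ("A", "olanzapine", [(0, 100)])
    b = ("B", "risperidone", [(20, 90)])
    assert detect_polypharmacy([("A", "olanzapine", [(0, 100)]), ("B", "risperidone", [(20, 90)])], "AP-AP")
    # an 8-day hole is not bridged: longest intersections 31 and 32 days
    b_split = ("B", "risperidone", [(20, 50), (59, 90)])
    assert not detect_polypharmacy([a, b_split], "AP-AP")
    # a 7-day hole is bridged, restoring the 71-day overlap
    b_bridge = ("B", "risperidone", [(20, 50), (58, 90)])
    assert detect_polypharmacy([a, b_bridge], "AP-AP")
    # one agent alone can never qualify
    assert not detect_polypharmacy([a], "AP-AP")
    # AP + anxiolytic qualifies only in AP-other mode
    anx = ("X", "anxiolytic", [(0, 100)])
    assert not detect_polypharmacy([a, anx], "AP-AP")
    assert detect_polypharmacy([a, anx], "AP-other")


# ---------------------------------------------------------------------------
# Oracle equivalence on random inputs


def _random_fills(rng, n_max=50):
    n = int(rng.integers(1, n_max))
    days = rng.integers(-30, 400, n)
    supplies = rng.integers(1, 90, n)
    return list(zip(days.tolist(), supplies.tolist()))


def test_interval_measures_match_day_array_oracle(rng):
    for _ in range(300):
        fills = _random_fills(rng)
        cal = _cal(fills)
        assert cal.days == int(day_array(fills, WINDOW).sum())
        assert compute_pdc(cal) == pytest.approx(oracle_pdc(fills, WINDOW), abs=0)
        for g in (30, 60, 90):
            for mode in (True, False):
                got = persistence_flags(cal, [g], count_terminal_gap=mode)[g]
                assert got == oracle_persistence(fills, WINDOW, g, mode), (fills, g, mode)


def test_continuous_exposure_matches_chain_walk_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(1, 15))
        days = np.sort(rng.integers(0, 365, n))
        days[0] = 0  # first fill at index
        supplies = rng.integers(1, 60, n)
        fills = list(zip(days.tolist(), supplies.tolist()))
        got = continuous_exposure(_fills_df(fills), 0, WINDOW)
        assert got == oracle_continuous_exposure(fills, 0, WINDOW)


def test_polypharmacy_matches_day_array_oracle(rng):
    classes = ["olanzapine", "risperidone", "anxiolytic", "antidepressant", "PP1M"]
    for _ in range(200):
        n_agents = int(rng.integers(1, 5))
        agents = []
        for k in range(n_agents):
            fills = _random_fills(rng, n_max=10)
            cls = classes[int(rng.integers(0, len(classes)))]
            ivs = _cal(fills).intervals
            agents.append((f"AG{k}", cls, ivs))
        for mode in ("AP-AP", "AP-other"):
            got = detect_polypharmacy(agents, mode)
            want = oracle_polypharmacy(
                [(c, cl, [(s, e - s + 1) for s, e in iv]) for c, cl, iv in agents],
                WINDOW, AP_CLASSES, PSYCH_CLASSES, mode,
            )
            assert got == want, (agents, mode)


# ---------------------------------------------------------------------------
# Structural properties


def test_pdc_monotone_under_adding_fills(rng):
    for _ in range(50):
        fills = _random_fills(rng, n_max=10)
        base = compute_pdc(_cal(fills))
        extra = fills + _random_fills(rng, n_max=4)
        assert compute_pdc(_cal(extra)) >= base


def test_persistence_thresholds_nested(rng):
    for _ in range(200):
        cal = _cal(_random_fills(rng))
        for mode in (True, False):
            f = persistence_flags(cal, count_terminal_gap=mode)
            assert (not f[30] or f[60]) and (not f[60] or f[90])


fills_strategy = st.lists(
    st.tuples(st.integers(-30, 400), st.integers(1, 90)), min_size=0, max_size=25
)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(fills=fills_strategy)
def test_union_calendar_matches_day_array(fills):
    cal = _cal(fills)
    arr = day_array(fills, WINDOW)
    assert cal.days == int(arr.sum())
    # intervals are sorted, disjoint with at least a one-day hole between them
    for (s1, e1), (s2, e2) in zip(cal.intervals, cal.intervals[1:]):
        assert e1 + 1 < s2
    for s, e in cal.intervals:
        assert WINDOW[0] <= s <= e <= WINDOW[1]
        assert arr[s - WINDOW[0] : e - WINDOW[0] + 1].all()


@settings(max_examples=200, derandomize=True, deadline=None)
@given(fills=fills_strategy, extra=fills_strategy)
def test_pdc_monotone_property(fills, extra):
    assert compute_pdc(_cal(fills + extra)) >= compute_pdc(_cal(fills))


def test_intersect_and_bridge_primitives():
    assert intersect_intervals([(0, 10), (20, 30)], [(5, 25)]) == [(5, 10), (20, 25)]
    assert bridge_intervals([(0, 10), (14, 20)], 3) == [(0, 20)]
    assert bridge_intervals([(0, 10), (15, 20)], 3) == [(0, 10), (15, 20)]
    assert merge_intervals([(5, 1)]) == []  # inverted interval dropped


# ---------------------------------------------------------------------------
# Weighted cohort summary


def _toy_summaries(n, rng):
    cols = {
        "duration_continuous_exposure": rng.integers(0, 365, n),
        "n_dispensings": rng.integers(0, 14, n),
        "pdc_index": rng.random(n),
        "pdc_any_ap": rng.random(n),
    }
    from claimsce.patterns import _BINARY_ROWS

    for col, _ in _BINARY_ROWS:
        cols[col] = rng.random(n) < 0.4
    return pd.DataFrame(cols)


def test_summarize_patterns_unit_weights_match_unweighted(rng):
    df = _toy_summaries(200, rng)
    treated = np.arange(200) < 80
    tbl = summarize_patterns(df, treated, np.ones(200))
    row = tbl[tbl["outcome"].str.startswith("PDC on index")].iloc[0]
    assert row["treated_mean"] == pytest.approx(df["pdc_index"][treated].mean(), abs=1e-12)


def test_summarize_patterns_identical_cohorts_p_one(rng):
    half = _toy_summaries(100, rng)
    df = pd.concat([half, half], ignore_index=True)
    treated = np.arange(200) < 100
    tbl = summarize_patterns(df, treated, np.ones(200))
    assert np.allclose(tbl["p_value"].to_numpy(), 1.0)


def test_summarize_patterns_weighted_proportion_matches_direct_sum(rng):
    df = _toy_summaries(300, rng)
    treated = np.arange(300) < 120
    w = rng.uniform(0.2, 3.0, 300)
    tbl = summarize_patterns(df, treated, w)
    row = tbl[tbl["outcome"] == "AP polypharmacy present"].iloc[0]
    x = df["ap_polypharmacy"].to_numpy(float)
    want = (w[treated] * x[treated]).sum() / w[treated].sum()
    assert row["treated_mean"] == pytest.approx(want, abs=1e-12)


def test_summarize_patterns_rejects_zero_weight_arm(rng):
    df = _toy_summaries(10, rng)
    treated = np.arange(10) < 5
    w = np.where(treated, 0.0, 1.0)
    with pytest.raises(ValueError, match="zero weight"):
        summarize_patterns(df, treated, w)
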