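"""Interval algebra for pharmacy-claims treatment patterns.

Every measure here is defined on closed integer day-intervals inside a
fixed 365-day observation window anchored at the index date.  A fill
dispensed on day ``d`` with ``s`` days of supply covers ``[d, d+s-1]``;
overlapping supply is de-duplicated by set union (calendar-day coverage),
not shifted forward — a configurable stockpiling variant is provided for
sensitivity analyses.

Measures:

* proportion of days covered (PDC): unique covered days / 365, with
  adherence defined as PDC >= 0.8;
* persistence: absence of any uncovered run of at least 30/60/90 days
  after therapy start (optionally counting the run from last supply end
  to the window end);
* continuous exposure: days from index to the supply end of the first
  fill whose successor, if any, starts more than a permissible gap (90
  days) later;
* antipsychotic and psychiatric polypharmacy: two qualifying agents whose
  coverage calendars — after bridging per-agent holes of at most 7 days —
  overlap for at least 60 consecutive days.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims_io import AP_CLASSES, PSYCH_CLASSES

Interval = tuple[int, int]

OBSERVATION_DAYS = 365
ADHERENCE_THRESHOLD = 0.8
PERSISTENCE_GAPS = (30, 60, 90)

# ---------------------------------------------------------------------------
# Interval primitives


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of closed integer intervals: sorted, pairwise-disjoint output.

    Abutting intervals ([0,29], [30,59]) merge; a one-day hole keeps them
    separate.
    """
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if e < s:
            continue
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def clip_intervals(intervals: Iterable[Interval], lo: int, hi: int) -> list[Interval]:
    """Restrict intervals to the closed window ``[lo, hi]``."""
    return [(max(s, lo), min(e, hi)) for s, e in intervals if e >= lo and s <= hi]


def bridge_intervals(intervals: Sequence[Interval], max_gap: int) -> list[Interval]:
    """Merge consecutive intervals separated by at most ``max_gap`` uncovered days."""
    ivs = merge_intervals(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s - out[-1][1] - 1 <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two disjoint sorted interval lists."""
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def covered_days(intervals: Iterable[Interval]) -> int:
    """Total number of days covered by a disjoint interval list."""
    return sum(e - s + 1 for s, e in intervals)


# ---------------------------------------------------------------------------
# Coverage calendars


@dataclasses.dataclass
class CoverageCalendar:
    """Union of medication-covered day intervals inside a window."""

    patient_id: str
    key: str  # agent_code or an agent-set label such as "any-AP"
    intervals: list[Interval]
    window: Interval

    @property
    def days(self) -> int:
        return covered_days(self.intervals)


def fill_intervals(
    days: np.ndarray, supplies: np.ndarray, mode: str = "union"
) -> list[Interval]:
    """Raw fill intervals under union or stockpile carry-forward semantics.

    Under ``"stockpile"`` a fill dispensed while supply from earlier fills
    is still on hand starts when that supply runs out, so no supply is lost
    to overlap.
    """
    order = np.argsort(days, kind="stable")
    days, supplies = np.asarray(days)[order], np.asarray(supplies)[order]
    if mode == "union":
        return merge_intervals(
            (int(d), int(d + s - 1)) for d, s in zip(days, supplies)
        )
    if mode == "stockpile":
        out: list[Interval] = []
        next_free = -(10**9)
        for d, s in zip(days, supplies):
            start = max(int(d), next_free)
            out.append((start, start + int(s) - 1))
            next_free = start + int(s)
        return merge_intervals(out)
    raise ValueError(f"unknown coverage mode {mode!r}")


def coverage_intervals(
    fills: pd.DataFrame,
    window: Interval,
    mode: str = "union",
    patient_id: str = "",
    key: str = "",
) -> CoverageCalendar:
    """Build a coverage calendar from fills (columns ``day``, ``days_supply``).

    Fill intervals are unioned (or stockpiled) first, then clipped to the
    closed window.
    """
    if len(fills):
        ivs = fill_intervals(
            fills["day"].to_numpy(), fills["days_supply"].to_numpy(), mode=mode
        )
        ivs = clip_intervals(ivs, window[0], window[1])
    else:
        ivs = []
    return CoverageCalendar(patient_id=patient_id, key=key, intervals=ivs, window=window)


# ---------------------------------------------------------------------------
# Measures


def compute_pdc(calendar: CoverageCalendar, window_days: int = OBSERVATION_DAYS) -> float:
    """Proportion of days covered: unique covered days / window length."""
    return calendar.days / window_days


def continuous_exposure(
    fills: pd.DataFrame,
    index_day: int,
    window: Interval,
    permissible_gap: int = 90,
    anchor: str = "supply_end",
) -> tuple[int, int]:
    """Duration of continuous exposure to the index agent, plus fill count.

    Walks index-agent fills in date order from the index date.  The chain
    ends at the supply end of the first fill whose successor (if any)
    starts more than ``permissible_gap`` days after the anchor — the supply
    end of that fill (default) or its dispense date (``anchor="fill_date"``).
    Duration is chain-end − index + 1, clipped to the observation window.
    The fill count is all index-agent dispensings inside the window.
    """
    if anchor not in ("supply_end", "fill_date"):
        raise ValueError(f"unknown anchor {anchor!r}")
    f = fills.sort_values(["day", "days_supply"], kind="stable")  # deterministic ties
    days = f["day"].to_numpy()
    supplies = f["days_supply"].to_numpy()
    in_window = (days >= window[0]) & (days <= window[1])
    n_dispensings = int(in_window.sum())
    if n_dispensings == 0:
        return 0, 0
    days, supplies = days[in_window], supplies[in_window]
    chain_end = None
    for i in range(len(days)):
        supply_end = int(days[i] + supplies[i] - 1)
        ref = supply_end if anchor == "supply_end" else int(days[i])
        if i + 1 == len(days) or days[i + 1] - ref > permissible_gap:
            chain_end = supply_end
            break
    chain_end = min(chain_end, window[1])
    return chain_end - index_day + 1, n_dispensings


def coverage_gaps(
    calendar: CoverageCalendar, count_terminal_gap: bool = True
) -> list[int]:
    """Uncovered-run lengths after therapy start.

    Interior gaps run from one covered interval's end + 1 to the next
    interval's start − 1; when ``count_terminal_gap`` the run from the last
    covered day + 1 to the window end is also a gap.  Days before the first
    covered day are not counted (therapy has not started).  A calendar with
    no coverage yields the whole window as a single gap when terminal gaps
    count.
    """
    ivs = calendar.intervals
    if not ivs:
        w0, w1 = calendar.window
        return [w1 - w0 + 1] if count_terminal_gap else []
    gaps = [ivs[i + 1][0] - ivs[i][1] - 1 for i in range(len(ivs) - 1)]
    if count_terminal_gap:
        terminal = calendar.window[1] - ivs[-1][1]
        if terminal > 0:
            gaps.append(terminal)
    return gaps


def persistence_flags(
    calendar: CoverageCalendar,
    thresholds: Sequence[int] = PERSISTENCE_GAPS,
    count_terminal_gap: bool = True,
) -> dict[int, bool]:
    """Persistence at each gap threshold: no uncovered run of >= g days."""
    gaps = coverage_gaps(calendar, count_terminal_gap=count_terminal_gap)
    longest = max(gaps, default=0)
    return {int(g): longest < g for g in thresholds}


def detect_polypharmacy(
    calendars: Sequence[tuple[str, str, Sequence[Interval]]],
    mode: str,
    min_overlap: int = 60,
    bridge_gap: int = 7,
) -> bool:
    """Concurrent-therapy flag over bridged per-agent calendars.

    ``calendars`` holds ``(agent_code, agent_class, intervals)`` triples for
    one patient.  Each agent's calendar is first bridged (holes of at most
    ``bridge_gap`` days closed); a qualifying pair's bridged calendars must
    then share an *unbroken* overlap of at least ``min_overlap`` days.

    mode ``"AP-AP"``: two distinct antipsychotic agent codes.
    mode ``"AP-other"``: one antipsychotic and one anxiolytic /
    antidepressant / mood stabilizer.
    """
    if mode not in ("AP-AP", "AP-other"):
        raise ValueError(f"unknown polypharmacy mode {mode!r}")
    bridged = [
        (code, cls, bridge_intervals(list(ivs), bridge_gap))
        for code, cls, ivs in calendars
    ]
    n = len(bridged)
    for i in range(n):
        code_i, cls_i, ivs_i = bridged[i]
        for j in range(i + 1, n):
            code_j, cls_j, ivs_j = bridged[j]
            if code_i == code_j:
                continue
            if mode == "AP-AP":
                ok = cls_i in AP_CLASSES and cls_j in AP_CLASSES
            else:
                ok = (cls_i in AP_CLASSES and cls_j in PSYCH_CLASSES) or (
                    cls_j in AP_CLASSES and cls_i in PSYCH_CLASSES
                )
            if not ok:
                continue
            inter = intersect_intervals(ivs_i, ivs_j)
            if any(e - s + 1 >= min_overlap for s, e in inter):
                return True
    return False


# ---------------------------------------------------------------------------
# Per-patient exposure summary


@dataclasses.dataclass
class ExposureSummary:
    """Treatment-pattern outcomes for one patient over the follow-up year."""

    patient_id: str
    duration_continuous_exposure: int
    n_dispensings: int
    pdc_index: float
    pdc_any_ap: float
    adherent_index: bool
    adherent_any_ap: bool
    persist_index_30: bool
    persist_index_60: bool
    persist_index_90: bool
    persist_any_ap_30: bool
    persist_any_ap_60: bool
    persist_any_ap_90: bool
    ap_polypharmacy: bool
    psychiatric_polypharmacy: bool
    any_other_ap: bool
    any_other_psych: bool
    uses_anxiolytic: bool
    uses_antidepressant: bool
    uses_mood_stabilizer: bool


def summarize_exposure(
    patient_id: str,
    fills: pd.DataFrame,
    index_day: int,
    index_agent: str,
    count_terminal_gap: bool = True,
    coverage_mode: str = "union",
    gap_anchor: str = "supply_end",
) -> ExposureSummary:
    """Compute the full treatment-pattern record for one patient.

    ``fills`` holds all pharmacy-like fills for the patient with columns
    ``day``, ``days_supply``, ``agent_code``, ``agent_class``; fills before
    the index day are ignored.
    """
    window = (index_day, index_day + OBSERVATION_DAYS - 1)
    f = fills[(fills["day"] >= window[0]) & (fills["day"] <= window[1])]

    idx_fills = f[f["agent_code"] == index_agent]
    ap_fills = f[f["agent_class"].isin(AP_CLASSES)]

    cal_index = coverage_intervals(idx_fills, window, coverage_mode, patient_id, index_agent)
    cal_any_ap = coverage_intervals(ap_fills, window, coverage_mode, patient_id, "any-AP")

    pdc_index = compute_pdc(cal_index)
    pdc_any = compute_pdc(cal_any_ap)
    dur, n_disp = continuous_exposure(idx_fills, index_day, window, anchor=gap_anchor)
    p_idx = persistence_flags(cal_index, count_terminal_gap=count_terminal_gap)
    p_any = persistence_flags(cal_any_ap, count_terminal_gap=count_terminal_gap)

    per_agent = [
        (code, grp["agent_class"].iloc[0], coverage_intervals(grp, window, coverage_mode).intervals)
        for code, grp in f.groupby("agent_code")
        if len(grp)
    ]
    ap_poly = detect_polypharmacy(per_agent, "AP-AP")
    psych_poly = detect_polypharmacy(per_agent, "AP-other")

    other = f[f["agent_code"] != index_agent]
    classes = set(other["agent_class"])
    return ExposureSummary(
        patient_id=patient_id,
        duration_continuous_exposure=dur,
        n_dispensings=n_disp,
        pdc_index=pdc_index,
        pdc_any_ap=pdc_any,
        adherent_index=pdc_index >= ADHERENCE_THRESHOLD,
        adherent_any_ap=pdc_any >= ADHERENCE_THRESHOLD,
        persist_index_30=p_idx[30],
        persist_index_60=p_idx[60],
        persist_index_90=p_idx[90],
        persist_any_ap_30=p_any[30],
        persist_any_ap_60=p_any[60],
        persist_any_ap_90=p_any[90],
        ap_polypharmacy=ap_poly,
        psychiatric_polypharmacy=psych_poly,
        any_other_ap=bool(classes & set(AP_CLASSES)),
        any_other_psych=bool(classes & set(PSYCH_CLASSES)),
        uses_anxiolytic="anxiolytic" in classes,
        uses_antidepressant="antidepressant" in classes,
        uses_mood_stabilizer="mood-stabilizer" in classes,
    )


# ---------------------------------------------------------------------------
# Weighted cohort summary


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    m = float((w * x).sum() / sw)
    v = float((w * (x - m) ** 2).sum() / sw)  # frequency-weight denominator
    return m, v


def weighted_ttest(x1, w1, x2, w2) -> float:
    """Two-sample t-test p-value treating normalized weights as frequencies."""
    m1, v1 = _weighted_mean_var(np.asarray(x1, float), np.asarray(w1, float))
    m2, v2 = _weighted_mean_var(np.asarray(x2, float), np.asarray(w2, float))
    n1, n2 = float(np.sum(w1)), float(np.sum(w2))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return 1.0
    t = (m1 - m2) / np.sqrt(se2)
    df = n1 + n2 - 2
    return float(2 * stats.t.sf(abs(t), df))


def weighted_chi2(p1_num, n1, p2_num, n2) -> float:
    """Pearson chi-square p-value on a weighted 2x2 table."""
    table = np.array([[p1_num, n1 - p1_num], [p2_num, n2 - p2_num]], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.allclose(table, exp):
        return 1.0
    chi2 = float(((table - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


_BINARY_ROWS = [
    ("adherent_index", "Adherence (PDC >= 80%) on index agent"),
    ("adherent_any_ap", "Adherence (PDC >= 80%) on any AP agent"),
    ("persist_index_30", "Persistence on index agent, no gap >= 30 days"),
    ("persist_index_60", "Persistence on index agent, no gap >= 60 days"),
    ("persist_index_90", "Persistence on index agent, no gap >= 90 days"),
    ("persist_any_ap_30", "Persistence on any AP, no gap >= 30 days"),
    ("persist_any_ap_60", "Persistence on any AP, no gap >= 60 days"),
    ("persist_any_ap_90", "Persistence on any AP, no gap >= 90 days"),
    ("any_other_ap", "Other AP use during follow-up"),
    ("any_other_psych", "Other psychiatric medication use"),
    ("uses_anxiolytic", "Anxiolytic use"),
    ("uses_antidepressant", "Antidepressant use"),
    ("uses_mood_stabilizer", "Mood stabilizer use"),
    ("ap_polypharmacy", "AP polypharmacy present"),
    ("psychiatric_polypharmacy", "Psychiatric polypharmacy present"),
]

_CONTINUOUS_ROWS = [
    ("duration_continuous_exposure", "Duration of continuous exposure to index agent (days)"),
    ("n_dispensings", "Number of dispensings of index agent"),
    ("pdc_index", "PDC on index agent"),
    ("pdc_any_ap", "PDC on any AP agent"),
]


def summarize_patterns(
    summaries: pd.DataFrame, treated: np.ndarray, weights: np.ndarray
) -> pd.DataFrame:
    """Weighted treatment-pattern comparison table.

    One row per pattern outcome with weighted means/proportions per cohort
    and a weighted t-test (continuous) or Pearson chi-square (binary)
    p-value.
    """
    treated = np.asarray(treated, bool)
    w = np.asarray(weights, float)
    if w[treated].sum() <= 0 or w[~treated].sum() <= 0:
        raise ValueError("zero weight sum in a cohort")
    rows = []
    for col, label in _CONTINUOUS_ROWS:
        x = summaries[col].to_numpy(float)
        m1, v1 = _weighted_mean_var(x[treated], w[treated])
        m2, v2 = _weighted_mean_var(x[~treated], w[~treated])
        p = weighted_ttest(x[treated], w[treated], x[~treated], w[~treated])
        rows.append((label, "continuous", m1, np.sqrt(v1), m2, np.sqrt(v2), p))
    for col, label in _BINARY_ROWS:
        x = summaries[col].to_numpy(float)
        n1, n2 = w[treated].sum(), w[~treated].sum()
        s1, s2 = (w[treated] * x[treated]).sum(), (w[~treated] * x[~treated]).sum()
        p = weighted_chi2(s1, n1, s2, n2)
        rows.append((label, "binary", s1 / n1, np.nan, s2 / n2, np.nan, p))
    return pd.DataFrame(
        rows,
        columns=["outcome", "kind", "treated_mean", "treated_sd", "comparator_mean", "comparator_sd", "p_value"],
    )
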