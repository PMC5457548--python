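"""New-user cohort construction for the active-comparator claims design.

A patient enters the study at the *index date*: the first day, on or after
the accrual start, with a qualifying claim for an index agent — the
once-monthly long-acting injectable (identified from pharmacy or medical
claims) or one of the nine oral atypical antipsychotics (pharmacy claims
only) — such that a second qualifying claim for the *same* agent occurs
within 90 days and no claim for that agent occurred in the preceding 12
months (agent-specific washout).

Inclusion then requires (a) the index event itself, (b) at least two
distinct claim dates carrying a schizophrenia diagnosis (ICD-9-CM 295
prefix) anywhere in the data period, (c) age >= 18 in completed years at
index, and (d/e) continuous enrollment over the 365 days before and the
365 days from the index date.  Patients aged 18-25 at index form the
recently-diagnosed subcohort (age as a proxy for recent diagnosis).

Baseline covariates for the propensity model are computed strictly from
the 365-day pre-index window.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import codelists
from .claims_io import (
    AP_CLASSES,
    OAA_CLASSES,
    PP1M,
    PSYCH_CLASSES,
    ClaimsBundle,
    from_day,
    match_dx,
    split_dx,
    to_day,
)
from .patterns import compute_pdc, coverage_intervals, detect_polypharmacy
from .outcomes import standardize_costs

BASELINE_DAYS = 365
OBSERVATION_DAYS = 365
QUALIFYING_WINDOW = 90
WASHOUT_DAYS = 365
DEFAULT_ACCRUAL_START = "2009-09-01"
PP1M_IMPUTED_SUPPLY = 30  # once-monthly product; medical claims carry no days supply

CRITERIA = ("a_two_claims_90d", "b_schizophrenia_dx", "c_age_18", "d_pre_enrollment", "e_post_enrollment")

#: Typical oral / short-acting vs LAI groupings used for baseline use flags.
TYPICAL_ORAL = ("typical-oral-AP",)
ATYPICAL_ORAL = OAA_CLASSES
TYPICAL_LAI = ("typical-LAI",)
ATYPICAL_LAI = (PP1M, "other-atypical-LAI")


@dataclasses.dataclass
class IndexEvent:
    patient_id: str
    index_day: int
    index_agent: str
    cohort: str  # "PP1M" or "OAA"

    @property
    def index_date(self):
        return from_day([self.index_day])[0]


# ---------------------------------------------------------------------------
# Qualifying claims and fills


def qualifying_claims(bundle: ClaimsBundle, agent_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """All index-agent candidate claims as (patient_id, day, agent_code, cohort).

    Pharmacy claims qualify for the LAI class and the nine oral atypical
    classes; medical claims qualify only for the LAI (provider-administered
    injection), identified via their ``agent_code`` and the agent map (or,
    absent a map, by a code whose pharmacy claims carry the LAI class).
    """
    frames = []
    rx = bundle.pharmacy
    if len(rx):
        is_pp1m = rx["agent_class"] == PP1M
        is_oaa = rx["agent_class"].isin(OAA_CLASSES)
        sub = rx[is_pp1m | is_oaa]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": sub["patient_id"].to_numpy(),
                    "day": to_day(sub["dispense_date"]),
                    "agent_code": sub["agent_code"].to_numpy(),
                    "cohort": np.where(sub["agent_class"] == PP1M, "PP1M", "OAA"),
                }
            )
        )
    # class lookup for medical-claim agent codes
    class_of: dict[str, str] = {}
    if agent_map is not None:
        class_of.update(zip(agent_map["agent_code"], agent_map["agent_class"]))
    if len(rx):
        class_of.update(zip(rx["agent_code"], rx["agent_class"]))
    med = bundle.medical
    if len(med):
        codes = med["agent_code"].fillna("").astype(str)
        is_pp1m_med = codes.map(lambda c: bool(c) and class_of.get(c, c) == PP1M)
        sub = med[is_pp1m_med.to_numpy(bool)]
        if len(sub):
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": sub["patient_id"].to_numpy(),
                        "day": to_day(sub["start_date"]),
                        "agent_code": sub["agent_code"].to_numpy(),
                        "cohort": "PP1M",
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day", "agent_code", "cohort"])
    return pd.concat(frames, ignore_index=True)


def fills_table(bundle: ClaimsBundle, agent_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pharmacy-like fills: all pharmacy claims plus provider-administered
    LAI medical claims converted to fills with an imputed 30-day supply."""
    rx = bundle.pharmacy
    frames = []
    if len(rx):
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": rx["patient_id"].to_numpy(),
                    "day": to_day(rx["dispense_date"]),
                    "agent_code": rx["agent_code"].to_numpy(),
                    "agent_class": rx["agent_class"].to_numpy(),
                    "days_supply": rx["days_supply"].to_numpy(int),
                }
            )
        )
    qc = qualifying_claims(bundle, agent_map)
    med_pp1m = qc[qc["cohort"] == "PP1M"]
    if len(bundle.medical):
        class_of = dict(zip(rx["agent_code"], rx["agent_class"])) if len(rx) else {}
        if agent_map is not None:
            class_of.update(zip(agent_map["agent_code"], agent_map["agent_class"]))
        med = bundle.medical
        codes = med["agent_code"].fillna("").astype(str)
        keep = codes.map(lambda c: bool(c) and class_of.get(c, c) == PP1M).to_numpy(bool)
        sub = med[keep]
        if len(sub):
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": sub["patient_id"].to_numpy(),
                        "day": to_day(sub["start_date"]),
                        "agent_code": sub["agent_code"].to_numpy(),
                        "agent_class": PP1M,
                        "days_supply": PP1M_IMPUTED_SUPPLY,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day", "agent_code", "agent_class", "days_supply"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Index events


def _agent_index_day(days: np.ndarray, accrual_day: int) -> int | None:
    """Earliest qualifying index day for one (patient, agent) claim series.

    ``days`` is the (unsorted, possibly duplicated) vector of claim days.
    A day D qualifies when D >= accrual start, at least two claims fall in
    [D, D+90], and no claim falls in [D-365, D-1].
    """
    days = np.sort(np.asarray(days))
    for i, d in enumerate(days):
        if d < accrual_day:
            continue
        if np.sum((days >= d - WASHOUT_DAYS) & (days <= d - 1)) > 0:
            continue
        if np.sum((days >= d) & (days <= d + QUALIFYING_WINDOW)) >= 2:
            return int(d)
    return None


def find_index_events(
    bundle: ClaimsBundle,
    accrual_start: str = DEFAULT_ACCRUAL_START,
    agent_map: pd.DataFrame | None = None,
) -> list[IndexEvent]:
    """One retained index event per qualifying patient.

    The earliest qualifying day across agents wins; a same-day tie between
    the LAI and an oral agent is broken in favor of the LAI, then by agent
    code for determinism.
    """
    accrual_day = int(to_day([accrual_start])[0])
    qc = qualifying_claims(bundle, agent_map)
    events: list[IndexEvent] = []
    for pid, grp in qc.groupby("patient_id", sort=True):
        candidates = []
        for (agent, cohort), ag in grp.groupby(["agent_code", "cohort"]):
            d = _agent_index_day(ag["day"].to_numpy(), accrual_day)
            if d is not None:
                candidates.append((d, 0 if cohort == "PP1M" else 1, agent, cohort))
        if candidates:
            d, _, agent, cohort = min(candidates)
            events.append(IndexEvent(patient_id=pid, index_day=d, index_agent=agent, cohort=cohort))
    return events


# ---------------------------------------------------------------------------
# Inclusion criteria


@dataclasses.dataclass
class InclusionDecision:
    patient_id: str
    flags: dict[str, bool]
    included: bool
    exclusion_reason: str | None


def _completed_years(birth_day: int, at_day: int) -> int:
    b = from_day([birth_day])[0]
    d = from_day([at_day])[0]
    years = d.year - b.year
    if (d.month, d.day) < (b.month, b.day):
        years -= 1
    return years


def _window_covered(spans: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True iff [lo, hi] is fully covered by the union of spans."""
    need = lo
    for s, e in sorted(spans):
        if s > need:
            break
        if e >= need:
            need = e + 1
        if need > hi:
            return True
    return need > hi


def apply_inclusion(bundle: ClaimsBundle, event: IndexEvent) -> InclusionDecision:
    """Evaluate criteria (a)-(e) for one index event."""
    pid = event.patient_id
    d0 = event.index_day
    flags = {}
    flags["a_two_claims_90d"] = True  # established by find_index_events

    med = bundle.medical[bundle.medical["patient_id"] == pid]
    dx_days = set()
    if len(med):
        days = to_day(med["start_date"])
        for day, dx in zip(days, med["dx_codes"]):
            if any(match_dx(c, "295.xx") for c in split_dx(dx)):
                dx_days.add(int(day))
    flags["b_schizophrenia_dx"] = len(dx_days) >= 2

    pat = bundle.patients[bundle.patients["patient_id"] == pid].iloc[0]
    age = _completed_years(int(to_day([pat["birth_date"]])[0]), d0)
    flags["c_age_18"] = age >= 18

    enr = bundle.enrollment[bundle.enrollment["patient_id"] == pid]
    spans = list(zip(to_day(enr["start_date"]), to_day(enr["end_date"]))) if len(enr) else []
    flags["d_pre_enrollment"] = _window_covered(spans, d0 - BASELINE_DAYS, d0 - 1)
    flags["e_post_enrollment"] = _window_covered(spans, d0, d0 + OBSERVATION_DAYS - 1)

    included = all(flags.values())
    reason = next((c for c in CRITERIA if not flags[c]), None)
    return InclusionDecision(patient_id=pid, flags=flags, included=included, exclusion_reason=reason)


def assign_subcohorts(events: list[IndexEvent], patients: pd.DataFrame) -> pd.DataFrame:
    """Cohort table with age at index and the recently-diagnosed flag (18-25)."""
    birth = dict(zip(patients["patient_id"], to_day(patients["birth_date"])))
    rows = []
    for ev in events:
        age = _completed_years(int(birth[ev.patient_id]), ev.index_day)
        rows.append(
            (ev.patient_id, ev.index_day, ev.index_agent, ev.cohort, age, 18 <= age <= 25)
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "index_day", "index_agent", "cohort", "age_at_index", "recently_diagnosed"],
    )


# ---------------------------------------------------------------------------
# Quan-Charlson comorbidity index


def compute_quan_cci(dx_codes, code_table: pd.DataFrame | None = None) -> int:
    """Charlson score (Quan ICD-9 coding) from a collection of diagnosis codes.

    Sums each distinct category's weight; the hierarchy keeps only the
    severe member of each (mild, severe) pair.
    """
    table = code_table if code_table is not None else codelists.load_quan_cci()
    present: set[str] = set()
    weights: dict[str, int] = {}
    for cat, prefix, wt in zip(table["category"], table["icd9_prefix"], table["weight"]):
        weights[cat] = int(wt)
        if cat in present:
            continue
        if any(match_dx(c, prefix) for c in dx_codes):
            present.add(cat)
    for severe, mild in codelists.CCI_HIERARCHY.items():
        if severe in present:
            present.discard(mild)
    return sum(weights[c] for c in present)


# ---------------------------------------------------------------------------
# Baseline covariates

MH_DX_PREFIXES = tuple(str(p) for p in range(290, 320))  # mental-disorder ICD-9 chapter


def build_baseline_covariates(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    agent_map: pd.DataFrame | None = None,
    cpi: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Propensity-model covariate record per included patient.

    Every field is computed from the 365-day pre-index window only (claims
    dated ``index_day-365 .. index_day-1``); demographics come from the
    patient table and enrollment spans.
    """
    pat = bundle.patients.set_index("patient_id")
    comorb = codelists.load_comorbidities()
    comorb_groups = {n: g["icd9_prefix"].tolist() for n, g in comorb.groupby("name")}
    fills_all = fills_table(bundle, agent_map)
    fills_by_pid = {pid: g for pid, g in fills_all.groupby("patient_id")}
    med_by_pid = {pid: g for pid, g in bundle.medical.groupby("patient_id")}
    rx_by_pid = {pid: g for pid, g in bundle.pharmacy.groupby("patient_id")}
    enr_by_pid = {pid: g for pid, g in bundle.enrollment.groupby("patient_id")}

    rows = []
    for rec in cohort.itertuples(index=False):
        pid, d0 = rec.patient_id, int(rec.index_day)
        lo, hi = d0 - BASELINE_DAYS, d0 - 1
        p = pat.loc[pid]

        enr = enr_by_pid.get(pid)
        capitated = dual = False
        if enr is not None:
            s, e = to_day(enr["start_date"]), to_day(enr["end_date"])
            active = (s <= hi) & (e >= lo)
            capitated = bool(enr["capitated"].to_numpy()[active].any())
            dual = bool(enr["dual_coverage"].to_numpy()[active].any())

        index_date = from_day([d0])[0]

        baseline_dx: list[str] = []
        n_mhi = n_mhi_1day = 0
        med_cost = 0.0
        med = med_by_pid.get(pid)
        if med is not None:
            days = to_day(med["start_date"])
            inwin = (days >= lo) & (days <= hi)
            sub = med[inwin]
            for dx in sub["dx_codes"]:
                baseline_dx.extend(split_dx(dx))
            n_mhi = int((sub["service_category"] == "mhi_admission").sum())
            n_mhi_1day = int((sub["service_category"] == "mhi_1day").sum())
            if len(sub):
                med_cost = float(
                    standardize_costs(sub["paid_amount"], sub["service_year"], cpi).sum()
                )

        rx_cost = 0.0
        rx = rx_by_pid.get(pid)
        if rx is not None:
            days = to_day(rx["dispense_date"])
            sub = rx[(days >= lo) & (days <= hi)]
            if len(sub):
                rx_cost = float(
                    standardize_costs(sub["paid_amount"], sub["service_year"], cpi).sum()
                )

        f = fills_by_pid.get(pid)
        if f is not None:
            f = f[(f["day"] >= lo) & (f["day"] <= hi)]
        else:
            f = fills_all.iloc[0:0]
        ap = f[f["agent_class"].isin(AP_CLASSES)]
        psych = f[f["agent_class"].isin(AP_CLASSES + PSYCH_CLASSES)]
        cal = coverage_intervals(ap, (lo, hi))
        pdc_ap = compute_pdc(cal, BASELINE_DAYS)
        if pdc_ap == 0:
            pdc_cat = "zero"
        elif pdc_ap < 0.8:
            pdc_cat = "lt80"
        else:
            pdc_cat = "ge80"
        per_agent = [
            (code, grp["agent_class"].iloc[0], coverage_intervals(grp, (lo, hi)).intervals)
            for code, grp in f.groupby("agent_code")
        ]
        ap_poly = detect_polypharmacy(per_agent, "AP-AP")

        classes = set(ap["agent_class"])
        mh_dx = {
            c for c in baseline_dx if any(match_dx(c, pref) for pref in MH_DX_PREFIXES)
        }
        rows.append(
            {
                "patient_id": pid,
                "age": float(rec.age_at_index),
                "female": p["sex"] == "female",
                "race": p["race"],
                "state": p["state"],
                "region": p["region"],
                "capitated": capitated,
                "dual_coverage": dual,
                "index_year": int(index_date.year),
                "index_quarter": int((index_date.month - 1) // 3 + 1),
                "quan_cci": compute_quan_cci(baseline_dx),
                "n_unique_mh_dx": len(mh_dx),
                "n_unique_psych_agents": int(psych["agent_code"].nunique()),
                "use_typical_oral": bool(classes & set(TYPICAL_ORAL)),
                "use_atypical_oral": bool(classes & set(ATYPICAL_ORAL)),
                "use_typical_lai": bool(classes & set(TYPICAL_LAI)),
                "use_atypical_lai": bool(classes & set(ATYPICAL_LAI)),
                "baseline_pdc_ap": pdc_ap,
                "baseline_pdc_category": pdc_cat,
                "ap_polypharmacy": ap_poly,
                "use_anxiolytic": "anxiolytic" in set(f["agent_class"]),
                "use_antidepressant": "antidepressant" in set(f["agent_class"]),
                "use_mood_stabilizer": "mood-stabilizer" in set(f["agent_class"]),
                **{
                    f"comorb_{name}": match_any_prefix(baseline_dx, prefixes)
                    for name, prefixes in comorb_groups.items()
                },
                "n_mhi_admissions": n_mhi,
                "n_mhi_1day": n_mhi_1day,
                "baseline_monthly_total_cost": (med_cost + rx_cost) / 12.0,
                "baseline_monthly_pharmacy_cost": rx_cost / 12.0,
                "baseline_monthly_medical_cost": med_cost / 12.0,
            }
        )
    return pd.DataFrame(rows)


def match_any_prefix(codes, prefixes) -> bool:
    return any(match_dx(c, p) for c in codes for p in prefixes)


# ---------------------------------------------------------------------------
# Propensity design matrix

_CATEGORICAL = ("race", "state", "region", "baseline_pdc_category")
_DROP = ("patient_id", "baseline_pdc_ap")


def ps_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for the propensity model (no intercept column).

    Multi-level categoricals are expanded to indicators dropping the first
    level; boolean flags become 0/1.  Constant and collinear columns are
    pruned (pivoted QR against an implicit intercept) so the design stays
    full rank even when a category level is absent in a small sample.
    """
    df = covariates.drop(columns=[c for c in _DROP if c in covariates.columns])
    cats = [c for c in _CATEGORICAL if c in df.columns]
    df = pd.get_dummies(df, columns=cats, drop_first=True)
    df = df.astype(float)
    keep = [c for c in df.columns if df[c].nunique() > 1]
    from .iptw import prune_collinear

    return prune_collinear(df[keep])
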