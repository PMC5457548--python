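"""Claims data model: read, write and validate delimited-text claim bundles.

A bundle is four CSV tables — patients, enrollment spans, pharmacy claims
and medical claims — the unit of input for every downstream stage.  Dates
are ISO-8601 strings on disk and ``datetime64[ns]`` in memory; all window
arithmetic downstream treats a day as the atomic unit and every window as a
closed interval of whole days.

Agent identity is two-level: ``agent_code`` names a specific product (used
for "same agent" rules) while ``agent_class`` is the analysis grouping
(long-acting injectable under study, the nine oral atypical antipsychotics,
other antipsychotic classes, and the non-antipsychotic psychotropic
classes).  The code→class map ships as an editable CSV standing in for the
proprietary GPI/NDC/HCPCS dictionaries real claims would use.
"""

from __future__ import annotations

import dataclasses
import os
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Enumerations

SEXES = ("female", "male")
REGIONS = ("urban", "suburban", "rural")

#: Index-agent class for the once-monthly long-acting injectable cohort.
PP1M = "PP1M"

#: The nine oral atypical antipsychotic agent classes (comparator cohort).
OAA_CLASSES = (
    "aripiprazole",
    "asenapine",
    "iloperidone",
    "lurasidone",
    "olanzapine",
    "paliperidone",
    "quetiapine",
    "risperidone",
    "ziprasidone",
)

#: Antipsychotic classes that are not index-agent candidates.
OTHER_AP_CLASSES = ("typical-oral-AP", "typical-LAI", "other-atypical-LAI")

#: Non-antipsychotic psychotropic classes.
PSYCH_CLASSES = ("anxiolytic", "antidepressant", "mood-stabilizer")

AGENT_CLASSES = (PP1M,) + OAA_CLASSES + OTHER_AP_CLASSES + PSYCH_CLASSES + ("other",)

#: Every antipsychotic class (index candidates plus the rest).
AP_CLASSES = (PP1M,) + OAA_CLASSES + OTHER_AP_CLASSES

SERVICE_CATEGORIES = (
    "inpatient",
    "outpatient",
    "emergency_room",
    "long_term_care",
    "mhi_admission",
    "mhi_1day",
    "home_care",
    "other",
)

PATIENT_COLUMNS = ("patient_id", "birth_date", "sex", "race", "region", "state")
ENROLLMENT_COLUMNS = ("patient_id", "start_date", "end_date", "capitated", "dual_coverage")
PHARMACY_COLUMNS = (
    "patient_id",
    "dispense_date",
    "agent_code",
    "agent_class",
    "days_supply",
    "paid_amount",
    "branded",
    "service_year",
)
MEDICAL_COLUMNS = (
    "patient_id",
    "start_date",
    "end_date",
    "service_category",
    "dx_codes",
    "paid_amount",
    "agent_code",
    "branded",
    "service_year",
)

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "enrollment": ["start_date", "end_date"],
    "pharmacy": ["dispense_date"],
    "medical": ["start_date", "end_date"],
}

_FLAG_COLUMNS = {
    "patients": [],
    "enrollment": ["capitated", "dual_coverage"],
    "pharmacy": ["branded"],
    "medical": ["branded"],
}


class SchemaError(ValueError):
    """A required column is missing or a value lies outside its enumeration."""


class IntegrityError(ValueError):
    """A referential or invariant violation in strict validation."""


@dataclasses.dataclass
class ClaimsBundle:
    """In-memory claims bundle: four tables sharing ``patient_id`` keys.

    ``strict`` records whether the bundle passed referential validation
    (every claim inside an enrollment span of its patient).  Non-strict
    bundles are permitted so generators can deliberately produce claims
    outside enrollment when exercising the enrollment-continuity filters.
    """

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    pharmacy: pd.DataFrame
    medical: pd.DataFrame
    strict: bool = True

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            self.patients.copy(),
            self.enrollment.copy(),
            self.pharmacy.copy(),
            self.medical.copy(),
            self.strict,
        )


# ---------------------------------------------------------------------------
# Day arithmetic

EPOCH = pd.Timestamp("2000-01-01")


def to_day(dates) -> np.ndarray:
    """Convert datetime-like values to integer day offsets from the epoch."""
    ser = pd.to_datetime(pd.Series(np.asarray(dates)))
    return ((ser - EPOCH).dt.days).to_numpy()


def from_day(days) -> pd.Series:
    """Inverse of :func:`to_day`: integer day offsets back to timestamps."""
    return EPOCH + pd.to_timedelta(np.asarray(days), unit="D")


# ---------------------------------------------------------------------------
# Diagnosis-code matching


def match_dx(code: str, pattern: str) -> bool:
    """True iff ICD-9 ``code`` starts with the prefix of ``pattern``.

    Both arguments are compared dot-insensitively; trailing ``x``/``×``
    wildcard characters in the pattern are ignored, so ``"295.xx"`` matches
    ``"295.30"`` and ``"29530"`` alike.
    """
    if not code:
        raise ValueError("empty diagnosis code")
    c = code.replace(".", "").upper()
    p = pattern.replace(".", "").upper().rstrip("X×")
    return c.startswith(p)


def match_dx_any(codes, patterns) -> bool:
    """True iff any code matches any prefix pattern."""
    return any(match_dx(c, p) for c in codes for p in patterns)


def split_dx(dx_field) -> list[str]:
    """Split a serialized ``dx_codes`` field (``;``-separated) into codes."""
    if dx_field is None or (isinstance(dx_field, float) and np.isnan(dx_field)):
        return []
    s = str(dx_field).strip()
    return [c for c in s.split(";") if c] if s else []


# ---------------------------------------------------------------------------
# Reading / validation


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")


def _check_enum(df: pd.DataFrame, col: str, allowed, table: str) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{table}: unknown {col} value {df[col].iloc[idx]!r} at row {idx}"
        )


def validate_bundle(bundle: ClaimsBundle, strict: bool = True) -> list[str]:
    """Validate invariants; raise on hard violations, return warnings.

    Hard violations: schema/enumeration errors, non-positive days supply,
    negative paid amounts, overlapping enrollment spans, duplicate patient
    ids, medical end before start.  In strict mode a claim dated outside all
    of its patient's enrollment spans (or for an unknown patient) raises
    :class:`IntegrityError`; otherwise it is returned as a warning.
    """
    warnings: list[str] = []
    pat, enr, rx, med = bundle.patients, bundle.enrollment, bundle.pharmacy, bundle.medical

    _require_columns(pat, PATIENT_COLUMNS, "patients")
    _require_columns(enr, ENROLLMENT_COLUMNS, "enrollment")
    _require_columns(rx, PHARMACY_COLUMNS, "pharmacy")
    _require_columns(med, MEDICAL_COLUMNS, "medical")

    if pat["patient_id"].duplicated().any():
        raise IntegrityError("patients: duplicate patient_id")
    _check_enum(pat, "sex", SEXES, "patients")
    _check_enum(pat, "region", REGIONS, "patients")
    if len(rx):
        _check_enum(rx, "agent_class", AGENT_CLASSES, "pharmacy")
        bad = rx["days_supply"].to_numpy() < 1
        if bad.any():
            raise SchemaError(
                f"pharmacy: days_supply < 1 at row {int(np.flatnonzero(bad)[0])}"
            )
        if (rx["paid_amount"].to_numpy() < 0).any():
            raise SchemaError("pharmacy: negative paid_amount")
    if len(med):
        _check_enum(med, "service_category", SERVICE_CATEGORIES, "medical")
        if (to_day(med["end_date"]) < to_day(med["start_date"])).any():
            raise SchemaError("medical: end_date precedes start_date")
        if (med["paid_amount"].to_numpy() < 0).any():
            raise SchemaError("medical: negative paid_amount")
        one_day = med["service_category"] == "mhi_1day"
        if one_day.any():
            sub = med.loc[one_day]
            if (to_day(sub["start_date"]) != to_day(sub["end_date"])).any():
                raise SchemaError("medical: mhi_1day claim spanning more than one day")

    # enrollment spans: ordered, non-overlapping per patient
    if len(enr):
        s, e = to_day(enr["start_date"]), to_day(enr["end_date"])
        if (e < s).any():
            raise SchemaError("enrollment: end_date precedes start_date")
        srt = enr.assign(_s=s, _e=e).sort_values(["patient_id", "_s"])
        same = srt["patient_id"].to_numpy()[1:] == srt["patient_id"].to_numpy()[:-1]
        overlap = srt["_s"].to_numpy()[1:] <= srt["_e"].to_numpy()[:-1]
        if (same & overlap).any():
            raise IntegrityError("enrollment: overlapping spans for one patient")

    # referential integrity + claims-in-enrollment
    known = set(pat["patient_id"])
    spans: dict = {}
    if len(enr):
        for pid, grp in enr.groupby("patient_id"):
            spans[pid] = list(zip(to_day(grp["start_date"]), to_day(grp["end_date"])))

    def _covered(pid, day) -> bool:
        return any(s <= day <= e for s, e in spans.get(pid, ()))

    for table, name, datecol in ((rx, "pharmacy", "dispense_date"), (med, "medical", "start_date")):
        if not len(table):
            continue
        unknown = ~table["patient_id"].isin(known)
        if unknown.any():
            msg = f"{name}: claim for unknown patient {table['patient_id'][unknown].iloc[0]!r}"
            if strict:
                raise IntegrityError(msg)
            warnings.append(msg)
        days = to_day(table[datecol])
        for pid, day in zip(table["patient_id"], days):
            if pid in spans and not _covered(pid, day):
                msg = f"{name}: claim on day {day} outside enrollment for {pid!r}"
                if strict:
                    raise IntegrityError(msg)
                warnings.append(msg)
                break  # one warning per table is enough

    # birth precedes claims
    if len(pat):
        born = dict(zip(pat["patient_id"], to_day(pat["birth_date"])))
        for table, name, datecol in ((rx, "pharmacy", "dispense_date"), (med, "medical", "start_date")):
            if not len(table):
                continue
            days = to_day(table[datecol])
            for pid, day in zip(table["patient_id"], days):
                if pid in born and day < born[pid]:
                    raise IntegrityError(f"{name}: claim predates birth for {pid!r}")
    return warnings


def _read_table(path: str, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in _DATE_COLUMNS[table]:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    for col in _FLAG_COLUMNS[table]:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if table == "medical" and "dx_codes" in df.columns:
        df["dx_codes"] = df["dx_codes"].fillna("").astype(str)
    if table == "medical" and "agent_code" in df.columns:
        df["agent_code"] = df["agent_code"].fillna("").astype(str)
    return df


def read_bundle(directory: str, strict: bool = True) -> ClaimsBundle:
    """Read and validate a bundle from ``patients/enrollment/pharmacy/medical.csv``."""
    paths = {t: os.path.join(directory, f"{t}.csv") for t in _DATE_COLUMNS}
    for t, p in paths.items():
        if not os.path.exists(p):
            raise FileNotFoundError(f"bundle table {t} not found at {p}")
    bundle = ClaimsBundle(
        patients=_read_table(paths["patients"], "patients"),
        enrollment=_read_table(paths["enrollment"], "enrollment"),
        pharmacy=_read_table(paths["pharmacy"], "pharmacy"),
        medical=_read_table(paths["medical"], "medical"),
        strict=strict,
    )
    validate_bundle(bundle, strict=strict)
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: str) -> dict[str, str]:
    """Write a bundle to CSVs; ``read_bundle`` on the result is the identity."""
    os.makedirs(directory, exist_ok=True)
    out = {}
    for name, df in (
        ("patients", bundle.patients),
        ("enrollment", bundle.enrollment),
        ("pharmacy", bundle.pharmacy),
        ("medical", bundle.medical),
    ):
        path = os.path.join(directory, f"{name}.csv")
        df = df.copy()
        for col in _DATE_COLUMNS[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(path, index=False)
        out[name] = path
    return out


def read_agent_map(path: str) -> pd.DataFrame:
    """Read an agent_code → (agent_class, branded) map CSV."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("agent_code", "agent_class", "branded"), "agent_map")
    df["branded"] = df["branded"].astype(str).str.lower().isin(("true", "1", "yes"))
    _check_enum(df, "agent_class", AGENT_CLASSES, "agent_map")
    return df
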