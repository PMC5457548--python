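"""Loaders for the packaged code-list and reference tables.

Three editable CSVs ship with the package:

* ``quan_cci.csv`` — Quan's ICD-9-CM coding of the 17 Charlson comorbidity
  categories with their Charlson weights.
* ``comorbidities.csv`` — prefix lists for the specific comorbidity flags
  used as propensity-model covariates (cardiovascular disease, diabetes,
  obesity, drug abuse, hepatitis C, HIV/AIDS).
* ``cpi_medical.csv`` — annual medical-care consumer-price-index values
  used to express paid amounts in reference-year dollars.

Each loader accepts an optional path so a study can substitute its own
dictionaries without touching the package.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import pandas as pd


class CodeListError(ValueError):
    """A packaged or user-supplied code-list file is malformed."""


def _data_path(name: str):
    return importlib.resources.files("claimsce.data").joinpath(name)


def _load_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - I/O failure path
        raise CodeListError(f"cannot read code list {path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise CodeListError(f"code list {path}: missing column {col!r}")
    return df


@lru_cache(maxsize=None)
def load_quan_cci(path: str | None = None) -> pd.DataFrame:
    """Quan ICD-9 Charlson map: columns category, icd9_prefix, weight."""
    df = _load_csv(path or _data_path("quan_cci.csv"), ("category", "icd9_prefix", "weight"))
    df = df.copy()
    df["weight"] = df["weight"].astype(int)
    return df


@lru_cache(maxsize=None)
def load_comorbidities(path: str | None = None) -> pd.DataFrame:
    """Comorbidity-flag map: columns name, icd9_prefix."""
    return _load_csv(path or _data_path("comorbidities.csv"), ("name", "icd9_prefix"))


@lru_cache(maxsize=None)
def load_cpi(path: str | None = None) -> dict[int, float]:
    """Medical-care CPI by calendar year."""
    df = _load_csv(path or _data_path("cpi_medical.csv"), ("year", "index"))
    return {int(y): float(v) for y, v in zip(df["year"], df["index"])}


#: Charlson category hierarchy: when the severe form is present the mild
#: form does not also score (complicated diabetes over uncomplicated,
#: metastatic disease over localized malignancy, severe over mild liver
#: disease).
CCI_HIERARCHY = {
    "diabetes_complicated": "diabetes_uncomplicated",
    "metastatic": "malignancy",
    "severe_liver": "mild_liver",
}
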