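"""Reading and validation of the three delimited-text input archives.

Schemas (header row required, dates strictly ISO-8601 ``YYYY-MM-DD``):

* refills — ``patient_id, dispense_date, atc_code, n_packages,
  ddd_per_package``
* registry — ``patient_id, sex, birth_date, death_date`` (death empty
  when alive)
* discharges — ``patient_id, admission_date, discharge_date``

Schema violations are reported with 1-based data row numbers.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from ._calendar import to_day

__all__ = ["SchemaError", "read_refills", "read_registry", "read_discharges"]

REFILL_COLUMNS = ["patient_id", "dispense_date", "atc_code", "n_packages",
                  "ddd_per_package"]
REGISTRY_COLUMNS = ["patient_id", "sex", "birth_date", "death_date"]
DISCHARGE_COLUMNS = ["patient_id", "admission_date", "discharge_date"]


class SchemaError(ValueError):
    pass


def _read(path: str | Path, columns: list[str], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _parse_dates(df: pd.DataFrame, col: str, path, required: bool = True) -> pd.Series:
    raw = df[col].str.strip()
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & (raw != "")
    if required:
        bad |= raw == ""
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(f"{path}: invalid {col} at data row(s) {rows}")
    return parsed


def read_refills(
    path: str | Path, observation_year: int, delimiter: str = ","
) -> pd.DataFrame:
    """Load a refill table; adds integer ``dispense_day`` offsets.

    Fills must be dispensed between 1 January of the look-back year and
    31 December of the observation year.
    """
    df = _read(path, REFILL_COLUMNS, delimiter)
    dates = _parse_dates(df, "dispense_date", path)
    try:
        n_pkg = df["n_packages"].astype(int)
        ddd = df["ddd_per_package"].astype(float)
    except ValueError as e:
        raise SchemaError(f"{path}: non-numeric package fields ({e})") from None
    bad = (n_pkg <= 0) | (ddd <= 0)
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(f"{path}: nonpositive supply at data row(s) {rows}")
    lo = pd.Timestamp(dt.date(observation_year - 1, 1, 1))
    hi = pd.Timestamp(dt.date(observation_year, 12, 31))
    bad = (dates < lo) | (dates > hi)
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(
            f"{path}: dispense_date outside look-back/observation years at "
            f"data row(s) {rows}"
        )
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "dispense_date": dates,
            "dispense_day": (
                dates - pd.Timestamp(dt.date(observation_year, 1, 1))
            ).dt.days.astype(int),
            "atc_code": df["atc_code"].str.strip(),
            "n_packages": n_pkg,
            "ddd_per_package": ddd,
        }
    )
    out["record_id"] = out.index
    return out


def read_registry(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = _read(path, REGISTRY_COLUMNS, delimiter)
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(f"{path}: sex must be F or M at data row(s) {rows}")
    birth = _parse_dates(df, "birth_date", path)
    death = _parse_dates(df, "death_date", path, required=False)
    bad = death.notna() & (death <= birth)
    if bad.any():
        rows = (df.index[bad] + 1).tolist()[:10]
        raise SchemaError(f"{path}: death before birth at data row(s) {rows}")
    if df["patient_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicated patient_id")
    return pd.DataFrame(
        {"patient_id": df["patient_id"], "sex": df["sex"],
         "birth_date": birth, "death_date": death}
    )


def read_discharges(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = _read(path, DISCHARGE_COLUMNS, delimiter)
    adm = _parse_dates(df, "admission_date", path)
    dis = _parse_dates(df, "discharge_date", path)
    return pd.DataFrame(
        {"patient_id": df["patient_id"], "admission_date": adm,
         "discharge_date": dis}
    )


def day_of(date: dt.date, observation_year: int) -> int:
    return to_day(date, observation_year)
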