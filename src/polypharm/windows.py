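"""Drug counts per time window, aggregation across windows, and prevalence.

A patient's drug count in a window is the number of distinct ATC 4th-level
classes with at least one covered day in that window.  Windows are the
calendar year, the four calendar quarters, or the twelve calendar months of
the observation year.  For sub-annual granularities the per-window counts
are collapsed to a single patient summary by one of three rules:

* ``MAX`` — the maximum count across windows (the primary rule: a patient
  is on polypharmacy if any month/quarter reaches five classes);
* ``MEAN`` — the unrounded arithmetic mean of the counts;
* ``COVERED_FRACTION`` — on polypharmacy only if at least a given fraction
  of the windows individually reach five classes (50/80/100% of twelve
  months correspond to 6, 10 and 12 qualifying months).

Patients are binned by drug count into 1-4 (no polypharmacy), 5, 6, 7, 8,
9, and >=10 (hyper-polypharmacy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._calendar import window_bounds
from .supply_diary import SupplyDiary, covered_days_in

__all__ = [
    "CLASS_BINS",
    "WindowScheme",
    "PolypharmacyStatus",
    "class_bin",
    "count_per_window",
    "count_table",
    "count_no_coverage",
    "summarize",
    "summarize_table",
    "prevalence",
    "percent",
]

CLASS_BINS = ("1-4", "5", "6", "7", "8", "9", ">=10")

N_WINDOWS = {"ANNUAL": 1, "QUARTER": 4, "MONTH": 12}


@dataclass(frozen=True)
class WindowScheme:
    granularity: str  # ANNUAL | QUARTER | MONTH
    aggregation: str = "MAX"  # MAX | MEAN | COVERED_FRACTION
    covered_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.granularity.upper() not in N_WINDOWS:
            raise ValueError(f"unknown granularity: {self.granularity!r}")
        if self.aggregation.upper() not in ("MAX", "MEAN", "COVERED_FRACTION"):
            raise ValueError(f"unknown aggregation: {self.aggregation!r}")
        if not 0 < self.covered_fraction <= 1:
            raise ValueError("covered_fraction must be in (0, 1]")
        object.__setattr__(self, "granularity", self.granularity.upper())
        object.__setattr__(self, "aggregation", self.aggregation.upper())

    @property
    def n_windows(self) -> int:
        return N_WINDOWS[self.granularity]

    @property
    def label(self) -> str:
        lab = f"{self.granularity}/{self.aggregation}"
        if self.aggregation == "COVERED_FRACTION":
            lab += f"@{self.covered_fraction:g}"
        return lab


@dataclass(frozen=True)
class PolypharmacyStatus:
    patient_id: str
    definition_name: str
    scheme: WindowScheme
    per_window_counts: tuple[int, ...]
    summary_count: float
    class_bin: str
    poly5: bool
    poly10: bool


def class_bin(summary_count: float) -> str:
    """Bin a (possibly fractional) drug count by the standard cutpoints."""
    if summary_count < 5:
        return "1-4"
    if summary_count >= 10:
        return ">=10"
    return str(math.floor(summary_count))


def count_per_window(
    diary: SupplyDiary, granularity: str, observation_year: int
) -> list[int]:
    """Distinct classes with >=1 covered day, per calendar window."""
    bounds = window_bounds(granularity, observation_year)
    return [
        sum(1 for atc4 in diary.segments if covered_days_in(diary, atc4, w) > 0)
        for w in bounds
    ]


def count_table(
    segments: pd.DataFrame,
    granularity: str,
    observation_year: int,
    patients: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Cohort-wide per-window distinct-class counts.

    Returns a DataFrame indexed by patient_id with one integer column per
    window (``w0``, ``w1``, ...).  *patients* fixes the row index so that
    patients whose diary is empty under a restrictive definition appear
    with zero counts.
    """
    bounds = window_bounds(granularity, observation_year)
    cols = {}
    for i, (lo, hi) in enumerate(bounds):
        hit = segments[(segments["end_day"] > lo) & (segments["start_day"] < hi)]
        cols[f"w{i}"] = hit.groupby("patient_id")["atc4"].nunique()
    out = pd.DataFrame(cols)
    if patients is not None:
        out = out.reindex(pd.Index(patients, name="patient_id"))
    out.index.name = "patient_id"
    return out.fillna(0).astype(int)


def count_no_coverage(
    prescriptions: pd.DataFrame,
    granularity: str,
    observation_year: int,
    patients: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Per-window counts from dispensing dates only.

    Sensitivity variant: a class counts in the window in which it was
    dispensed, ignoring both estimated coverage and same-class overlap
    shifting.  Same return shape as :func:`count_table`.
    """
    df = prescriptions.copy()
    df["atc4"] = df["atc_code"].astype(str).str[:5]
    bounds = window_bounds(granularity, observation_year)
    cols = {}
    for i, (lo, hi) in enumerate(bounds):
        hit = df[(df["dispense_day"] >= lo) & (df["dispense_day"] < hi)]
        cols[f"w{i}"] = hit.groupby("patient_id")["atc4"].nunique()
    out = pd.DataFrame(cols)
    if patients is not None:
        out = out.reindex(pd.Index(patients, name="patient_id"))
    out.index.name = "patient_id"
    return out.fillna(0).astype(int)


def summarize(counts: list[int], scheme: WindowScheme) -> dict:
    """Collapse per-window counts to the patient-level summary fields.

    For ``COVERED_FRACTION`` the polypharmacy flags follow the
    qualifying-window rule (a window qualifies when its own count reaches
    the threshold) while ``summary_count`` and the class bin report the
    maximum count, so the bin remains comparable across aggregations.
    """
    if len(counts) != scheme.n_windows:
        raise ValueError(
            f"expected {scheme.n_windows} window counts, got {len(counts)}"
        )
    counts = [int(c) for c in counts]
    if scheme.aggregation == "MAX":
        summary = float(max(counts))
        poly5, poly10 = summary >= 5, summary >= 10
    elif scheme.aggregation == "MEAN":
        summary = float(np.mean(counts))
        poly5, poly10 = summary >= 5, summary >= 10
    else:  # COVERED_FRACTION
        needed = math.ceil(scheme.covered_fraction * scheme.n_windows)
        poly5 = sum(c >= 5 for c in counts) >= needed
        poly10 = sum(c >= 10 for c in counts) >= needed
        summary = float(max(counts))
    return {
        "per_window_counts": tuple(counts),
        "summary_count": summary,
        "class_bin": class_bin(summary),
        "poly5": bool(poly5),
        "poly10": bool(poly10),
    }


def summarize_table(counts: pd.DataFrame, scheme: WindowScheme) -> pd.DataFrame:
    """Vectorised :func:`summarize` over a cohort count table."""
    if counts.shape[1] != scheme.n_windows:
        raise ValueError(
            f"expected {scheme.n_windows} window columns, got {counts.shape[1]}"
        )
    arr = counts.to_numpy()
    mx = arr.max(axis=1).astype(float)
    if scheme.aggregation == "MAX":
        summary = mx
        poly5, poly10 = summary >= 5, summary >= 10
    elif scheme.aggregation == "MEAN":
        summary = arr.mean(axis=1)
        poly5, poly10 = summary >= 5, summary >= 10
    else:
        needed = math.ceil(scheme.covered_fraction * scheme.n_windows)
        poly5 = (arr >= 5).sum(axis=1) >= needed
        poly10 = (arr >= 10).sum(axis=1) >= needed
        summary = mx
    bins = np.where(
        summary < 5, "1-4", np.where(summary >= 10, ">=10",
                                     np.floor(summary).astype(int).astype(str))
    )
    return pd.DataFrame(
        {
            "summary_count": summary,
            "class_bin": pd.Categorical(bins, categories=list(CLASS_BINS)),
            "poly5": poly5,
            "poly10": poly10,
        },
        index=counts.index,
    )


def percent(count: int, total: int) -> float:
    """Proportion as a percentage rounded half-up to two decimals."""
    if total <= 0:
        raise ValueError("empty cohort")
    pct = Decimal(count) / Decimal(total) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def prevalence(statuses: pd.DataFrame | list, flag: str) -> tuple[int, float]:
    """Count and percentage of patients carrying a flag or class bin.

    *flag* is ``poly5``, ``poly10`` or one of the class-bin labels.
    Accepts a summary DataFrame (from :func:`summarize_table`) or a list
    of :class:`PolypharmacyStatus`.
    """
    if isinstance(statuses, pd.DataFrame):
        n = len(statuses)
        if flag in ("poly5", "poly10"):
            k = int(statuses[flag].sum())
        else:
            k = int((statuses["class_bin"] == flag).sum())
    else:
        n = len(statuses)
        if flag in ("poly5", "poly10"):
            k = sum(getattr(s, flag) for s in statuses)
        else:
            k = sum(s.class_bin == flag for s in statuses)
    return k, percent(k, n)
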