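"""Reconstruction of drug-coverage timelines from pharmacy refill records.

Each dispensing is converted to an estimated days-of-supply through the WHO
defined daily dose (DDD): one DDD dispensed is assumed to cover one day of
therapy.  Drugs within the same therapeutic class (ATC 4th level, the first
five characters of the ATC code) are treated as interchangeable, and when a
fill of a class arrives before the coverage of the previous fill of that
class has ended, its whole coverage period is shifted forward to begin the
day after the previous coverage ends.  The result is a *supply diary*: per
patient and per ATC4 class, an ordered list of non-overlapping half-open
day intervals.

Two equivalent entry points are provided: an object API operating on one
patient's :class:`PrescriptionRecord` list (:func:`build_diary`), and a
vectorised table API (:func:`build_segments`) used by the pipeline on whole
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrescriptionRecord",
    "CoverageSegment",
    "SupplyDiary",
    "days_supply",
    "build_diary",
    "build_segments",
    "truncate",
    "covered_days_in",
]

ROUNDING_MODES = ("round", "floor", "ceil")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event — the atom of drug exposure.

    ``dispense_day`` is the integer day offset from 1 January of the
    observation year (negative values address the look-back year).
    ``ddd_per_package`` is the number of DDDs contained in one package.
    """

    patient_id: str
    dispense_day: int
    atc_code: str
    n_packages: int
    ddd_per_package: float
    record_id: int = 0

    @property
    def atc4(self) -> str:
        return self.atc_code[:5]


@dataclass(frozen=True)
class CoverageSegment:
    """A half-open ``[start_day, end_day)`` interval of covered days."""

    atc4: str
    start_day: int
    end_day: int
    source_record_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError("segment must have positive length")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


@dataclass
class SupplyDiary:
    """Per-patient coverage intervals, keyed by ATC 4th-level class.

    Within each class the segments are sorted and pairwise disjoint
    (guaranteed by the shift rule).
    """

    patient_id: str
    segments: dict[str, list[CoverageSegment]] = field(default_factory=dict)

    def total_covered(self, atc4: str) -> int:
        return sum(s.n_days for s in self.segments.get(atc4, ()))

    def classes(self) -> list[str]:
        return sorted(self.segments)


def days_supply(n_packages: int, ddd_per_package: float, rounding: str = "round") -> int:
    """Days of therapy covered by one dispensing: n_packages x DDDs/package.

    Fractional totals are rounded per *rounding* (``round`` = half-up,
    ``floor``, ``ceil``), with a floor of one day — any dispensed amount
    covers at least one day.
    """
    if n_packages <= 0 or ddd_per_package <= 0:
        raise ValueError("n_packages and ddd_per_package must be positive")
    total = n_packages * ddd_per_package
    if rounding == "round":
        days = math.floor(total + 0.5)
    elif rounding == "floor":
        days = math.floor(total)
    elif rounding == "ceil":
        days = math.ceil(total)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return max(1, days)


def build_diary(
    prescriptions: list[PrescriptionRecord], rounding: str = "round"
) -> SupplyDiary:
    """Chain one patient's fills into non-overlapping per-class segments.

    Fills are processed per ATC4 class in ``(dispense_day, record_id)``
    order.  A fill starts at its dispensing day, or at the end of the
    class's current coverage if that is later (the shift-on-overlap rule),
    and runs for its days of supply.  Total coverage is conserved: no
    supply is lost or double-counted by shifting.
    """
    if not prescriptions:
        raise ValueError("no prescriptions given")
    patient_ids = {p.patient_id for p in prescriptions}
    if len(patient_ids) != 1:
        raise ValueError(f"records from multiple patients: {sorted(patient_ids)}")
    (patient_id,) = patient_ids

    diary = SupplyDiary(patient_id=patient_id)
    by_class: dict[str, list[PrescriptionRecord]] = {}
    for p in prescriptions:
        by_class.setdefault(p.atc4, []).append(p)

    for atc4, fills in by_class.items():
        fills.sort(key=lambda p: (p.dispense_day, p.record_id))
        segments: list[CoverageSegment] = []
        cursor = -(10**9)  # end of current coverage for this class
        for p in fills:
            start = max(p.dispense_day, cursor)
            end = start + days_supply(p.n_packages, p.ddd_per_package, rounding)
            segments.append(
                CoverageSegment(atc4, start, end, source_record_ids=(p.record_id,))
            )
            cursor = end
        diary.segments[atc4] = segments
    return diary


def build_segments(
    refills: pd.DataFrame, rounding: str = "round"
) -> pd.DataFrame:
    """Vectorised diary construction for a whole cohort.

    Parameters
    ----------
    refills
        One row per dispensing with columns ``patient_id``,
        ``dispense_day`` (int), ``atc_code``, ``n_packages``,
        ``ddd_per_package``.  Row order is irrelevant; ties on the same
        day break on input row position.

    Returns
    -------
    DataFrame with one segment per input record: ``patient_id``, ``atc4``,
    ``record_id`` (input row position), ``start_day``, ``end_day``.

    Notes
    -----
    Within each (patient, class) group sorted by dispensing day, the shift
    rule is the recurrence ``end_i = max(dispense_i, end_{i-1}) + supply_i``,
    which unrolls to ``end_i = cum_i + max_{j<=i}(dispense_j - cum_{j-1})``
    with ``cum`` the running supply total — a grouped cumsum/cummax, no
    Python loop.
    """
    df = refills.reset_index(drop=True).copy()
    if "record_id" not in df.columns:
        df["record_id"] = np.arange(len(df))
    df["atc4"] = df["atc_code"].astype(str).str[:5]
    n_pkg = df["n_packages"].to_numpy()
    ddd = df["ddd_per_package"].to_numpy(dtype=float)
    if (n_pkg <= 0).any() or (ddd <= 0).any():
        raise ValueError("n_packages and ddd_per_package must be positive")
    total = n_pkg * ddd
    if rounding == "round":
        dur = np.floor(total + 0.5)
    elif rounding == "floor":
        dur = np.floor(total)
    elif rounding == "ceil":
        dur = np.ceil(total)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    df["_dur"] = np.maximum(1, dur).astype(np.int64)

    df = df.sort_values(
        ["patient_id", "atc4", "dispense_day", "record_id"], kind="stable"
    )
    grp = df.groupby(["patient_id", "atc4"], sort=False)
    cum = grp["_dur"].cumsum()
    base = df["dispense_day"] - (cum - df["_dur"])
    offset = base.groupby([df["patient_id"], df["atc4"]], sort=False).cummax()
    end = cum + offset
    start = end - df["_dur"]

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "atc4": df["atc4"].to_numpy(),
            "record_id": df["record_id"].to_numpy(),
            "start_day": start.to_numpy(dtype=np.int64),
            "end_day": end.to_numpy(dtype=np.int64),
        }
    )
    return out.reset_index(drop=True)


def truncate(diary: SupplyDiary, period_start: int, period_end: int) -> SupplyDiary:
    """Clip a diary to ``[period_start, period_end)`` day indices.

    Segments are clipped at both edges and dropped when nothing remains.
    A fill dispensed in the look-back year whose (possibly shifted)
    coverage reaches the observation period survives with the in-period
    portion.
    """
    if period_end < period_start:
        raise ValueError("period_end before period_start")
    clipped = SupplyDiary(patient_id=diary.patient_id)
    for atc4, segments in diary.segments.items():
        kept = []
        for s in segments:
            lo = max(s.start_day, period_start)
            hi = min(s.end_day, period_end)
            if hi > lo:
                kept.append(CoverageSegment(atc4, lo, hi, s.source_record_ids))
        if kept:
            clipped.segments[atc4] = kept
    return clipped


def covered_days_in(diary: SupplyDiary, atc4: str, window: tuple[int, int]) -> int:
    """Days of *window* (half-open day-index pair) covered by *atc4*.

    Unknown classes simply contribute zero days.
    """
    lo, hi = window
    total = 0
    for s in diary.segments.get(atc4, ()):
        total += max(0, min(s.end_day, hi) - max(s.start_day, lo))
    return total
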