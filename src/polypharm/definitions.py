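"""Operational polypharmacy definitions: which drug classes are counted.

Three inclusion rules are supported, all operating on ATC 4th-level
classes:

* ``ALL_ATC`` — every dispensed class counts (the WHO >=5-medications
  criterion applied to all reimbursed prescriptions).
* ``CHRONIC_ATC`` — classes belonging to drug families usually dispensed
  for short-term treatment are excluded: stomatologicals (A01), drugs for
  constipation (A06), systemic antibacterials (J01), antimycotics (J02),
  antivirals (J05), sera/immunoglobulins (J06), vaccines (J07),
  ectoparasiticides (P03), dermatologicals (D) and various (V).
* ``DDD_GE_60`` — only classes with a cumulative annual DDD total of at
  least 60 count, a proxy for regular chronic use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .supply_diary import SupplyDiary

__all__ = [
    "CHRONIC_EXCLUDED_PREFIXES",
    "DefinitionSpec",
    "ALL_ATC",
    "CHRONIC_ATC",
    "DDD_GE_60",
    "DEFAULT_DEFINITIONS",
    "apply_definition",
    "annual_ddd_totals",
    "filter_segments",
]

# ATC 2nd-level and 1st-level families excluded under CHRONIC_ATC.
CHRONIC_EXCLUDED_PREFIXES: tuple[str, ...] = (
    "A01", "A06", "J01", "J02", "J05", "J06", "J07", "P03", "D", "V",
)


@dataclass(frozen=True)
class DefinitionSpec:
    """A drug-inclusion rule for the polypharmacy count.

    ``excluded_atc_prefixes`` drops whole ATC4 classes by level-1/2 prefix
    match; ``annual_ddd_threshold`` drops classes whose cumulative annual
    DDDs fall below it.  The three standard rules are module constants.
    """

    name: str
    excluded_atc_prefixes: tuple[str, ...] = ()
    annual_ddd_threshold: float = 0.0

    def keeps(self, atc4: str, annual_ddds: float = 0.0) -> bool:
        if any(atc4.startswith(p) for p in self.excluded_atc_prefixes):
            return False
        if self.annual_ddd_threshold > 0 and annual_ddds < self.annual_ddd_threshold:
            return False
        return True


ALL_ATC = DefinitionSpec(name="ALL_ATC")
CHRONIC_ATC = DefinitionSpec(
    name="CHRONIC_ATC", excluded_atc_prefixes=CHRONIC_EXCLUDED_PREFIXES
)
DDD_GE_60 = DefinitionSpec(name="DDD_GE_60", annual_ddd_threshold=60.0)

DEFAULT_DEFINITIONS: dict[str, DefinitionSpec] = {
    d.name: d for d in (ALL_ATC, CHRONIC_ATC, DDD_GE_60)
}


def annual_ddd_totals(
    prescriptions: pd.DataFrame,
    segments: pd.DataFrame,
    year_window: tuple[int, int],
    attribution: str = "covered",
) -> pd.DataFrame:
    """Cumulative annual DDDs per (patient, ATC4 class).

    Parameters
    ----------
    prescriptions
        Refill table with ``patient_id``, ``dispense_day``, ``atc_code``,
        ``n_packages``, ``ddd_per_package`` (and optionally ``record_id``
        matching *segments*).
    segments
        Output of :func:`polypharm.supply_diary.build_segments` for the
        same records (pre-truncation), used to decide which fills
        contribute coverage to the year.
    year_window
        Half-open day-index bounds of the observation year.
    attribution
        ``covered`` sums DDDs of fills with at least one covered day in
        the year (consistent with the cohort-entry rule that admits
        look-back fills whose shifted coverage reaches the year);
        ``dispensed`` sums fills dispensed within the year instead.

    Returns
    -------
    DataFrame with ``patient_id``, ``atc4``, ``total_ddds``.
    """
    df = prescriptions.reset_index(drop=True).copy()
    if "record_id" not in df.columns:
        df["record_id"] = df.index
    df["atc4"] = df["atc_code"].astype(str).str[:5]
    df["_ddds"] = df["n_packages"] * df["ddd_per_package"]
    lo, hi = year_window
    if attribution == "covered":
        seg = segments[(segments["end_day"] > lo) & (segments["start_day"] < hi)]
        df = df[df["record_id"].isin(seg["record_id"])]
    elif attribution == "dispensed":
        df = df[(df["dispense_day"] >= lo) & (df["dispense_day"] < hi)]
    else:
        raise ValueError(f"unknown attribution mode: {attribution!r}")
    out = (
        df.groupby(["patient_id", "atc4"], sort=False, as_index=False)["_ddds"]
        .sum()
        .rename(columns={"_ddds": "total_ddds"})
    )
    return out


def apply_definition(
    diary: SupplyDiary,
    spec: DefinitionSpec,
    ddd_totals: dict[str, float] | None = None,
) -> SupplyDiary:
    """Restrict one patient's diary to the classes a definition counts.

    ``ddd_totals`` maps ATC4 class to the patient's cumulative annual
    DDDs; it is required whenever the definition carries a DDD threshold.
    """
    if spec.annual_ddd_threshold > 0 and ddd_totals is None:
        raise ValueError(f"definition {spec.name} requires annual DDD totals")
    totals = ddd_totals or {}
    kept = SupplyDiary(patient_id=diary.patient_id)
    for atc4, segs in diary.segments.items():
        if spec.keeps(atc4, totals.get(atc4, 0.0)):
            kept.segments[atc4] = list(segs)
    return kept


def filter_segments(
    segments: pd.DataFrame,
    spec: DefinitionSpec,
    ddd_totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Table-level counterpart of :func:`apply_definition`."""
    out = segments
    if spec.excluded_atc_prefixes:
        mask = pd.Series(False, index=out.index)
        for p in spec.excluded_atc_prefixes:
            mask |= out["atc4"].str.startswith(p)
        out = out[~mask]
    if spec.annual_ddd_threshold > 0:
        if ddd_totals is None:
            raise ValueError(f"definition {spec.name} requires annual DDD totals")
        eligible = ddd_totals.loc[
            ddd_totals["total_ddds"] >= spec.annual_ddd_threshold,
            ["patient_id", "atc4"],
        ]
        out = out.merge(eligible, on=["patient_id", "atc4"], how="inner")
    return out.reset_index(drop=True)
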