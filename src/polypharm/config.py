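"""Run configuration: one structured file drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic_claims import SimulationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved configuration for an end-to-end analysis run.

    Either the three input paths or a ``simulate`` block must be given.
    ``counting_mode`` selects coverage-based drug counting (the primary
    approach) or the dispensing-date-only sensitivity variant.
    """

    refills_path: str | None = None
    registry_path: str | None = None
    discharges_path: str | None = None
    simulate: SimulationConfig | None = None
    observation_year: int = 2017
    definitions: tuple[str, ...] = ("ALL_ATC", "CHRONIC_ATC", "DDD_GE_60")
    granularities: tuple[str, ...] = ("ANNUAL", "QUARTER", "MONTH")
    aggregation: str = "MAX"
    covered_fraction: float = 1.0
    counting_mode: str = "coverage"  # coverage | dispensing
    rounding: str = "round"
    ddd_attribution: str = "covered"  # covered | dispensed
    outcome_start: dt.date | None = None
    outcome_end: dt.date | None = None
    min_stay_days: int | None = None  # set to restrict to long stays (> n days)
    output_dir: str = "results"
    delimiter: str = ","
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = all(
            p is not None
            for p in (self.refills_path, self.registry_path, self.discharges_path)
        )
        if not has_paths and self.simulate is None:
            raise ValueError(
                "either all three input paths or a simulate block is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            known = {f.name for f in dataclasses.fields(SimulationConfig)}
            unknown = set(sim) - known
            if unknown:
                raise ValueError(f"unknown simulate fields: {sorted(unknown)}")
            sim = SimulationConfig(**sim)
        for key in ("outcome_start", "outcome_end"):
            if isinstance(raw.get(key), str):
                raw[key] = dt.date.fromisoformat(raw[key])
        for key in ("definitions", "granularities"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(simulate=sim, **raw)

    def resolved(self) -> dict:
        """Plain-dict view (for the report bundle's provenance record)."""
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        for key in ("outcome_start", "outcome_end"):
            if d[key] is not None:
                d[key] = d[key].isoformat()
        return d
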