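"""Synthetic pharmacy-claims generator with known ground truth.

Emulates the three administrative archives the pipeline consumes — an
assisted-residents registry, a pharmacy refill stream, and hospital
discharge records — for a cohort of adults aged >=40 with at least one
reimbursed prescription in the observation year.  Each patient receives a
random number of chronic ATC4 classes refilled near-periodically with
timing jitter (creating both coverage gaps and the early-refill overlaps
the shift rule resolves) plus occasional short acute courses drawn from
drug families usually dispensed for short-term treatment.

The generator retains a hidden truth table (chronic class burden, the
>=5-class exposure flag, the outcome flag) and links exposure to the
hospitalization outcome through a logistic model with a configurable true
odds ratio, so both prevalence machinery and association models can be
validated against known parameters.

Randomness is organised as one master seed from which a per-patient
substream is derived by patient index, so enlarging the cohort never
perturbs already-generated patients.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._calendar import to_date, year_length
from .supply_diary import PrescriptionRecord

__all__ = [
    "DrugClass",
    "SimulationConfig",
    "SyntheticClaims",
    "ConfigError",
    "DEFAULT_CHRONIC_POOL",
    "DEFAULT_ACUTE_POOL",
    "generate_population",
    "generate_refill_stream",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class DrugClass:
    """One dispensable drug (full ATC code) with its package content.

    ``ddd_per_package`` is the number of DDDs per package, hence the
    nominal days of supply of a one-package fill.  Chronic classes refill
    every ``refill_interval_days`` (defaults to the days of supply, i.e.
    back-to-back refills before jitter); acute classes are dispensed as
    single isolated courses.
    """

    atc: str
    ddd_per_package: float
    refill_interval_days: int | None = None
    chronic: bool = True

    @property
    def atc4(self) -> str:
        return self.atc[:5]

    @property
    def interval(self) -> int:
        if self.refill_interval_days is not None:
            return self.refill_interval_days
        return max(1, round(self.ddd_per_package))


# Common chronic-treatment classes (PPIs, statins, antihypertensives,
# antidiabetics, antiplatelets, antidepressants, thyroid hormones, ...).
DEFAULT_CHRONIC_POOL: tuple[DrugClass, ...] = (
    DrugClass("A02BC01", 28.0),
    DrugClass("C10AA05", 28.0),
    DrugClass("C09AA02", 28.0),
    DrugClass("C07AB07", 28.0),
    DrugClass("C08CA01", 28.0),
    DrugClass("A10BA02", 30.0),
    DrugClass("B01AC06", 30.0),
    DrugClass("N06AB06", 28.0),
    DrugClass("H03AA01", 50.0),
    DrugClass("C09CA01", 28.0),
    DrugClass("C03CA01", 30.0),
    DrugClass("A11CC05", 90.0),
    DrugClass("M04AA01", 30.0),
    DrugClass("R03AK06", 30.0),
)

# Short-term treatment families (the CHRONIC_ATC exclusion list):
# stomatologicals, laxatives, systemic anti-infectives, vaccines,
# dermatologicals, various, ectoparasiticides.
DEFAULT_ACUTE_POOL: tuple[DrugClass, ...] = (
    DrugClass("J01CR02", 7.0, chronic=False),
    DrugClass("J01MA02", 7.0, chronic=False),
    DrugClass("A01AB03", 10.0, chronic=False),
    DrugClass("A06AD11", 14.0, chronic=False),
    DrugClass("J02AC01", 7.0, chronic=False),
    DrugClass("J05AB01", 7.0, chronic=False),
    DrugClass("D01AC08", 14.0, chronic=False),
    DrugClass("V03AB16", 5.0, chronic=False),
    DrugClass("P03AC04", 1.0, chronic=False),
    DrugClass("J07BB02", 1.0, chronic=False),
)

FILLER_CLASS = DrugClass("N02BE01", 7.0, chronic=False)


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    observation_year: int = 2017
    age_range: tuple[int, int] = (40, 95)
    chronic_class_pool: tuple[DrugClass, ...] = DEFAULT_CHRONIC_POOL
    acute_class_pool: tuple[DrugClass, ...] = DEFAULT_ACUTE_POOL
    mean_chronic_classes_per_patient: float = 3.0
    mean_acute_courses_per_patient: float = 1.5
    refill_jitter_days: int = 5
    true_outcome_or: float = 2.5
    baseline_outcome_prob: float = 0.08
    # small covariate effects so adjusted models have something to adjust for
    outcome_sex_log_or: float = float(np.log(1.10))
    outcome_age_log_or_per_decade: float = float(np.log(1.15))
    # confounding dials (off by default, so the crude OR targets the true OR)
    prior_hosp_rate: float = 0.4
    prior_hosp_exposed_multiplier: float = 1.0
    outcome_prior_log_or: float = 0.0
    # hospital-stay lengths; >1 multiplier enriches long stays among exposed
    los_mean_days: float = 6.0
    los_exposed_multiplier: float = 1.0
    # follow-up-year nuisance events exercising the cohort exclusions
    death_prob: float = 0.01
    second_half_admission_prob: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.age_range[0] < 40 or self.age_range[1] < self.age_range[0]:
            raise ConfigError("age_range must be an ordered pair with minimum >= 40")
        for name in ("baseline_outcome_prob", "death_prob",
                     "second_half_admission_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        if self.true_outcome_or <= 0:
            raise ConfigError("true_outcome_or must be positive")
        for name in ("mean_chronic_classes_per_patient",
                     "mean_acute_courses_per_patient", "prior_hosp_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.refill_jitter_days < 0:
            raise ConfigError("refill_jitter_days must be nonnegative")
        chronic4 = {c.atc4 for c in self.chronic_class_pool}
        acute4 = {c.atc4 for c in self.acute_class_pool}
        if chronic4 & acute4:
            raise ConfigError(
                "chronic_class_pool and acute_class_pool overlap at ATC4: "
                f"{sorted(chronic4 & acute4)}"
            )


@dataclass
class SyntheticClaims:
    """The three generated archives plus the hidden truth table."""

    registry: pd.DataFrame
    refills: pd.DataFrame
    discharges: pd.DataFrame
    truth: pd.DataFrame


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_refill_stream(
    patient_id: str,
    assigned_classes: list[DrugClass],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[PrescriptionRecord]:
    """Dispensing events for one patient (day offsets, look-back included).

    Chronic classes are anchored at a uniform start day and refilled every
    class interval plus integer jitter in ``[-j, j]``; a negative draw
    dispenses before the previous coverage ends (an overlap for the shift
    rule), a positive one opens a gap.  Acute classes appear once, at a
    uniform day of the observation year.  Streams may begin in the
    look-back year so that carried-over supply reaches the year.
    """
    records: list[PrescriptionRecord] = []
    n_days = year_length(config.observation_year)
    j = config.refill_jitter_days
    rid = 0
    for cls in assigned_classes:
        if cls.chronic:
            interval = cls.interval
            t = int(rng.integers(-interval, n_days))
            while t < n_days:
                records.append(
                    PrescriptionRecord(
                        patient_id=patient_id, dispense_day=t, atc_code=cls.atc,
                        n_packages=1, ddd_per_package=cls.ddd_per_package,
                        record_id=rid,
                    )
                )
                rid += 1
                step = interval + (int(rng.integers(-j, j + 1)) if j else 0)
                t += max(1, step)
        else:
            t = int(rng.integers(0, n_days))
            records.append(
                PrescriptionRecord(
                    patient_id=patient_id, dispense_day=t, atc_code=cls.atc,
                    n_packages=1, ddd_per_package=cls.ddd_per_package,
                    record_id=rid,
                )
            )
            rid += 1
    return records


def generate_population(config: SimulationConfig) -> SyntheticClaims:
    """Generate registry, refill and discharge tables with known truth.

    Every patient is guaranteed at least one dispensing in the
    observation year (a single filler analgesic course if their assigned
    streams produced none), matching the cohort-entry rule.  Exposure in
    the truth table is carrying >=5 distinct chronic ATC4 classes; the
    outcome (any first-half admission in the follow-up year) follows a
    logistic model with the configured true odds ratio plus small age and
    sex effects.
    """
    config.validate()
    year = config.observation_year
    n_days = year_length(year)
    lo_age, hi_age = config.age_range

    reg_rows, refill_rows, hosp_rows, truth_rows = [], [], [], []
    log_or = float(np.log(config.true_outcome_or))
    base_logit = float(logit(config.baseline_outcome_prob))

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        rng = _patient_rng(config.seed, i)

        sex = "F" if rng.random() < 0.53 else "M"
        age = int(rng.integers(lo_age, hi_age + 1))
        birth = dt.date(year - age, 12, 31) - dt.timedelta(
            days=int(rng.integers(0, 365))
        )

        n_chronic = min(
            int(rng.poisson(config.mean_chronic_classes_per_patient)),
            len(config.chronic_class_pool),
        )
        chronic = [
            config.chronic_class_pool[k]
            for k in rng.choice(len(config.chronic_class_pool), size=n_chronic,
                                replace=False)
        ] if n_chronic else []
        n_acute = (
            min(int(rng.poisson(config.mean_acute_courses_per_patient)),
                len(config.acute_class_pool) * 3)
            if config.acute_class_pool else 0
        )
        acute = [
            config.acute_class_pool[int(k)]
            for k in rng.integers(0, len(config.acute_class_pool), size=n_acute)
        ] if n_acute else []

        records = generate_refill_stream(pid, chronic + acute, config, rng)
        if not any(0 <= r.dispense_day < n_days for r in records):
            records.append(
                PrescriptionRecord(
                    patient_id=pid, dispense_day=int(rng.integers(0, n_days)),
                    atc_code=FILLER_CLASS.atc, n_packages=1,
                    ddd_per_package=FILLER_CLASS.ddd_per_package,
                    record_id=len(records),
                )
            )
        for r in records:
            refill_rows.append(
                (pid, to_date(r.dispense_day, year).isoformat(), r.atc_code,
                 r.n_packages, r.ddd_per_package)
            )

        exposed = n_chronic >= 5

        prior_rate = config.prior_hosp_rate * (
            config.prior_hosp_exposed_multiplier if exposed else 1.0
        )
        n_prior = int(rng.poisson(prior_rate))
        prior_span = (dt.date(year, 12, 31) - dt.date(year - 3, 1, 1)).days + 1
        for _ in range(n_prior):
            adm = dt.date(year - 3, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, prior_span))
            )
            los = 1 + int(rng.poisson(max(config.los_mean_days - 1, 0)))
            hosp_rows.append(
                (pid, adm.isoformat(), (adm + dt.timedelta(days=los)).isoformat())
            )

        lp = (
            base_logit
            + log_or * exposed
            + config.outcome_sex_log_or * (sex == "M")
            + config.outcome_age_log_or_per_decade * (age - 70) / 10.0
            + config.outcome_prior_log_or * n_prior
        )
        outcome = rng.random() < expit(lp)
        follow = year + 1
        if outcome:
            adm = dt.date(follow, 1, 1) + dt.timedelta(days=int(rng.integers(0, 181)))
            los_mean = config.los_mean_days * (
                config.los_exposed_multiplier if exposed else 1.0
            )
            los = 1 + int(rng.poisson(max(los_mean - 1, 0)))
            hosp_rows.append(
                (pid, adm.isoformat(), (adm + dt.timedelta(days=los)).isoformat())
            )
        if rng.random() < config.second_half_admission_prob:
            adm = dt.date(follow, 7, 1) + dt.timedelta(days=int(rng.integers(0, 184)))
            los = 1 + int(rng.poisson(max(config.los_mean_days - 1, 0)))
            hosp_rows.append(
                (pid, adm.isoformat(), (adm + dt.timedelta(days=los)).isoformat())
            )
        death = ""
        if rng.random() < config.death_prob:
            death = (
                dt.date(follow, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
            ).isoformat()

        reg_rows.append((pid, sex, birth.isoformat(), death))
        truth_rows.append((pid, n_chronic, bool(exposed), bool(outcome),
                           sex, age, n_prior))

    registry = pd.DataFrame(
        reg_rows, columns=["patient_id", "sex", "birth_date", "death_date"]
    )
    refills = pd.DataFrame(
        refill_rows,
        columns=["patient_id", "dispense_date", "atc_code", "n_packages",
                 "ddd_per_package"],
    )
    discharges = pd.DataFrame(
        hosp_rows, columns=["patient_id", "admission_date", "discharge_date"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "n_chronic_classes", "exposed_flag",
                 "outcome_flag", "sex", "age_years", "prior_hospitalizations"],
    )
    return SyntheticClaims(registry, refills, discharges, truth)
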