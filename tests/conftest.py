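import numpy as np
import pytest

from polypharm.supply_diary import PrescriptionRecord
from polypharm.synthetic_claims import SimulationConfig, generate_population

DDD_CHOICES = [0.4, 7.0, 14.0, 16.5, 28.0, 30.0, 50.0, 90.0]
ATC_CHOICES = ["C10AA05", "C10AA07", "A02BC01", "J01CR02", "N06AB06"]


def random_patient_fills(
    rng: np.random.Generator, max_fills: int = 20, patient_id: str = "p"
) -> list[PrescriptionRecord]:
    """A randomized small fill stream with frequent same-class overlaps."""
    n = int(rng.integers(1, max_fills + 1))
    records = []
    for i in range(n):
        records.append(
            PrescriptionRecord(
                patient_id=patient_id,
                dispense_day=int(rng.integers(-60, 365)),
                atc_code=str(rng.choice(ATC_CHOICES)),
                n_packages=int(rng.integers(1, 4)),
                ddd_per_package=float(rng.choice(DDD_CHOICES)),
                record_id=i,
            )
        )
    return records


@pytest.fixture(scope="session")
def default_sim():
    """One mid-sized population under the default study conditions."""
    return generate_population(SimulationConfig(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def chronic_only_config():
    """Chronic streams only, low jitter: truth classes are recoverable."""
    return SimulationConfig(
        n_patients=500,
        seed=23,
        mean_acute_courses_per_patient=0.0,
        refill_jitter_days=2,
    )


@pytest.fixture(scope="session")
def chronic_only_sim(chronic_only_config):
    return generate_population(chronic_only_config)
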