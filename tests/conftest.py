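import numpy as np
import pytest

import optoaudit as oa
from optoaudit.vocab import Domain, OutcomeLevel


@pytest.fixture
def vocab():
    """Default vocabulary plus the region classes the worked fixture uses."""
    v = oa.default_vocabulary()
    v.region_classes.update({"V1": "PRIMARY_SENSORIMOTOR", "AMY": "OTHER"})
    return v


@pytest.fixture
def worked_cohort():
    return oa.make_worked_fixture()


def make_record(lab, animal, region, hist, phys, beh, row, vector=None):
    """Shorthand record builder for tests (levels given as OutcomeLevel)."""
    return oa.InjectionRecord(
        lab_id=lab,
        animal_id=animal,
        region_raw=region,
        region_canonical=region,
        vector_label=vector,
        outcomes={Domain.HISTOLOGY: hist, Domain.PHYSIOLOGY: phys, Domain.BEHAVIOR: beh},
        source_row=row,
    )


def random_records(rng: np.random.Generator, max_records: int = 60) -> list:
    """Small random record sets with clustered keys, for oracle comparisons."""
    n = int(rng.integers(1, max_records + 1))
    labs = [f"lab{i}" for i in range(1, int(rng.integers(1, 4)) + 1)]
    animals = [f"m{i}" for i in range(1, int(rng.integers(1, 5)) + 1)]
    regions = ["V1", "M1", "AMY", "HPC"][: int(rng.integers(1, 5))]
    levels = list(OutcomeLevel)
    records = []
    for row in range(1, n + 1):
        records.append(
            make_record(
                str(rng.choice(labs)),
                str(rng.choice(animals)),
                str(rng.choice(regions)),
                levels[int(rng.integers(0, 4))],
                levels[int(rng.integers(0, 4))],
                levels[int(rng.integers(0, 4))],
                row,
            )
        )
    return records
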