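import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pmhia import (
    GEMMParameterSet,
    MortalitySchedule,
    SyntheticConfig,
    generate_inputs,
    load_province_summary,
)
from pmhia.exposure import aggregate_to_district

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

ALL_AGE_GROUPS = tuple(
    [f"{s}-{s+4}" for s in range(0, 85, 5)] + ["85+"]
)


def make_schedule(rates, population=None, unit_id="unit") -> MortalitySchedule:
    """All-age schedule from per-band death rates (18 bands, 0-4 ... 85+)."""
    rates = np.asarray(rates, dtype=float)
    assert rates.shape == (18,)
    if population is None:
        population = np.full(18, 10_000.0)
    population = np.asarray(population, dtype=float)
    return MortalitySchedule(
        age_groups=ALL_AGE_GROUPS,
        population=population,
        deaths=population * rates,
        unit_id=unit_id,
    )


@pytest.fixture(scope="session")
def gemm():
    return GEMMParameterSet.default()


@pytest.fixture(scope="session")
def province_table():
    return load_province_summary()


@pytest.fixture(scope="session")
def calibrated_run(province_table):
    """Synthetic region pinned to the published province marginals."""
    config = SyntheticConfig(seed=1)
    schedules, mapping, cells = generate_inputs(config, province_table)
    district = aggregate_to_district(cells)
    exposures = dict(zip(district["district_id"], district["annual_mean"]))
    return schedules, mapping, exposures


@pytest.fixture()
def simple_schedule():
    """A gently Gompertz-like all-age schedule for hand checks."""
    mids = np.array([s + 2.5 for s in range(0, 85, 5)] + [90.0])
    rates = 4e-5 * np.exp(0.09 * mids) + 5e-4
    return make_schedule(rates, unit_id="simple")
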