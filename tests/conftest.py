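import numpy as np
import pytest
from hypothesis import settings

from tobaccosim.demography import (
    GENDERS,
    N_AGES,
    N_STATUS,
    MortalitySchedule,
    PopulationState,
)
from tobaccosim.synthetic_data import WorldConfig, gen_world

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def world():
    """Default synthetic world shared across read-only tests."""
    return gen_world(WorldConfig(seed=7, start_year=2006, end_year=2020))


@pytest.fixture
def small_world():
    """Cheap world for tests that mutate or re-run scenarios."""
    return gen_world(
        WorldConfig(seed=11, persons_per_gender=10_000, start_year=2008, end_year=2020)
    )


def random_state(rng, year=2000, ages=None, scale=1000.0) -> PopulationState:
    """A sparse random population: counts only at the requested ages."""
    counts = np.zeros((len(GENDERS), N_AGES, N_STATUS))
    ages = range(N_AGES) if ages is None else ages
    for a in ages:
        counts[:, a, :] = rng.uniform(0, scale, size=(len(GENDERS), N_STATUS))
    return PopulationState(year=year, counts=counts)


def flat_mortality(d_never, d_current, years=(2000, 2001, 2002)) -> MortalitySchedule:
    dn = np.full((len(GENDERS), N_AGES), d_never)
    dc = np.full((len(GENDERS), N_AGES), d_current)
    return MortalitySchedule.constant(dn, dc, years)
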