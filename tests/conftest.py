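import numpy as np
import pytest

from pulsefate.synthetic import (
    CellCycleParams,
    LentiMixModel,
    make_fucci_cohort,
    make_lenti_population,
    reference_allocations,
)


@pytest.fixture(scope="session")
def default_params():
    return CellCycleParams()


@pytest.fixture(scope="session")
def allocations():
    return reference_allocations()


@pytest.fixture(scope="session")
def default_population():
    """10,000-cell untreated control from the default mixing model."""
    model = LentiMixModel(seed=7)
    return make_lenti_population(model, 10_000)


@pytest.fixture(scope="session")
def g1_cohort(allocations):
    return make_fucci_cohort(allocations["palbo_G1"], n=50, seed=11)


@pytest.fixture(scope="session")
def mixed_cohorts(allocations):
    """One cohort per synchronise-and-pulse condition, default noise."""
    return {
        name: make_fucci_cohort(alloc, n=50, seed=11)
        for name, alloc in allocations.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
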