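import numpy as np
import pytest

from slicetrt.model import (
    ItemParameters,
    PersonParameters,
    TestletDesign,
    VarianceState,
    simulate_responses,
)
from slicetrt.sampler import ParameterState


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_testlet_design():
    """J=4 items in two testlets of two."""
    return TestletDesign(np.array([0, 0, 1, 1]))


@pytest.fixture
def toy_state(two_testlet_design):
    """A small consistent state: 3 persons, 4 items, 2 testlets."""
    items = ItemParameters(np.array([1.0, 0.8, 1.3, 0.6]),
                           np.array([0.0, -0.4, 0.7, 0.2]))
    persons = PersonParameters(
        np.array([0.3, -1.1, 0.9]),
        np.array([[0.2, -0.1], [0.0, 0.4], [-0.3, 0.1]]),
    )
    return ParameterState(items, persons, VarianceState(1.0, 1.0, np.ones(2)))


@pytest.fixture
def toy_data(toy_state, two_testlet_design):
    return simulate_responses(toy_state.items, toy_state.persons,
                              two_testlet_design, "n2pltm", seed=7)
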