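import numpy as np
import pytest

from dynstates import synthgen as sg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def state_model():
    """Default 3-state, 27-network model."""
    return sg.generate_state_model()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six fast subjects (two per group) from the study-shaped generator."""
    spec = sg.default_cohort_spec(seed=7)
    spec.groups = [sg.GroupSpec(g.name, 2, g.markov) for g in spec.groups]
    return sg.simulate_cohort(spec)
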