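import numpy as np
import pytest

from timepheno import simulate


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 12-sample, 30-gene worked cohort."""
    return simulate.worked_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized default-condition cohort shared across tests."""
    return simulate.simulate_cohort(simulate.SimulationConfig(n_samples=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
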