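import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", message=".*BiopythonExperimental.*")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation shared across tests."""
    import lecdup

    return lecdup.simulate(seed=1)


@pytest.fixture(scope="session")
def default_classification(default_sim):
    import lecdup

    return lecdup.classify_genome(default_sim.annotation, default_sim.hits)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
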