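import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb single-contig random genome shared across tests."""
    from mutspectra.simulate import simulate_genome

    return simulate_genome(60_000, seed=11)


@pytest.fixture(scope="session")
def default_truth():
    from mutspectra.simulate import SimulationTruth

    return SimulationTruth(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
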