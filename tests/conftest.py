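import numpy as np
import pytest

from movemode import synthgen


@pytest.fixture(scope="session")
def tiny_trips():
    """Five short well-separated trips, one per mode (~15 min total)."""
    trips, _ = synthgen.simulate_dataset(synthgen.SimConfig(total_hours=0.25, seed=7))
    return trips


@pytest.fixture(scope="session")
def small_dataset():
    """A moderate simulated dataset reused by the slower model tests."""
    trips, manifest = synthgen.simulate_dataset(synthgen.SimConfig(total_hours=0.6, seed=11))
    return trips, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
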