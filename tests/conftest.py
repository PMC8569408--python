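import numpy as np
import pytest

from ssvepshift import ElectrodeGrid, SimulationConfig, preprocess, simulate_recording


@pytest.fixture(scope="session")
def grid():
    return ElectrodeGrid()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """One preprocessed high-SNR subject, 20 trials, for fast checks."""
    config = SimulationConfig(trials_per_frequency=5, snr_db=10.0, seed=42)
    return preprocess(simulate_recording(config))
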