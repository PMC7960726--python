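import numpy as np
import pytest

from shockjet import synthio


@pytest.fixture(scope="session")
def default_series():
    """A 2000-shot series at default (study) conditions, shared across tests."""
    cfg = synthio.SimulationConfig(n_shots=2000, seed=11)
    shots, gt = synthio.generate_shot_series(cfg)
    return cfg, shots, gt


@pytest.fixture(scope="session")
def reference_model():
    return synthio.make_reference_model(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
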