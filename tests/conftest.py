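import numpy as np
import pytest

from chanpopen import FlipMechanism, SimConfig, generate_crc_dataset, simulate_recording


@pytest.fixture(scope="session")
def taurine_recording():
    """60 s simulated cell-attached record at a taurine-like efficacy.

    E=0.956, F=8 gives an expected within-cluster open probability of
    0.459; default rendering (5 pA, 0.5 pA noise, 3 kHz filter, 33.3 kHz
    sampling).
    """
    mech = FlipMechanism(E=0.956, F=8.0)
    config = SimConfig(duration=60.0, seed=7)
    dwells, trace = simulate_recording(mech, config)
    return mech, config, dwells, trace


@pytest.fixture(scope="session")
def noiseless_crc():
    """Two-cell noiseless, drift-free concentration–response dataset."""
    return generate_crc_dataset(noise_cv=0.0, rundown_rate=0.0, n_cells=2, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
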