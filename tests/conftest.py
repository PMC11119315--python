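import numpy as np
import pytest

from nirsfuse.montage import Montage, Optode, default_montage
from nirsfuse.synth import SynthConfig, simulate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_session():
    """One full-size synthetic session under the default study conditions."""
    return simulate_session(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_session():
    """A shorter session (6 trials/class) for IO and plumbing tests."""
    cfg = SynthConfig(seed=5, n_trials_per_class=6)
    return cfg, simulate_session(cfg)


@pytest.fixture()
def toy_montage():
    """2 sources x 3 detectors on a simple grid (distances easy to hand-check)."""
    return Montage(
        [
            Optode("S1", "source", (0.0, 0.0, 0.0)),
            Optode("S2", "source", (30.0, 0.0, 0.0)),
            Optode("D1", "detector", (0.0, 30.0, 0.0)),
            Optode("D2", "detector", (30.0, 30.0, 0.0)),
            Optode("D3", "detector", (60.0, 30.0, 0.0)),
        ]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
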