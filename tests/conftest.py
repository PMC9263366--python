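import numpy as np
import pytest

import nlts


@pytest.fixture(scope="session")
def lorenz():
    """Canonical chaotic Lorenz benchmark: 250 s of X at 40 Hz (10,000 samples)."""
    ts, traj = nlts.generate_lorenz(nlts.LorenzParams(seed=1))
    return ts, traj


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
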