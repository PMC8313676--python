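import numpy as np
import pytest

from dichotic.config import SimulationConfig
from dichotic.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One subject, 16 trials, default study conditions."""
    cfg = SimulationConfig(n_subjects=1, n_trials_per_cell=4, seed=101)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """One subject, 24 trials, no measurement noise or state jitter."""
    cfg = SimulationConfig(n_subjects=1, n_trials_per_cell=6, seed=202,
                           snr_envelope=np.inf, tracking_state_sd=0.0)
    return generate_dataset(cfg)
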