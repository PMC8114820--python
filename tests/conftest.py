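import numpy as np
import pytest

import hybci as h


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced geometry: 2 sessions x 6 trials, 6 fNIRS pairs, 4 EEG channels."""
    return h.SimConfig(n_subjects=2, n_sessions=1, trials_per_session=6,
                       n_nirs_channels=6, n_eeg_channels=4, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_cfg):
    """The six feature tables of the reduced synthetic dataset (12 trials)."""
    return h.run_synthetic_pipeline(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
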