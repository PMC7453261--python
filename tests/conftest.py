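import numpy as np
import pytest

from corrbci.preprocessing import preprocess_eeg, preprocess_fnirs
from corrbci.synthetic import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A short (3 min) session: enough trials for epoching/selection tests."""
    return SyntheticConfig(n_trials_per_class=3, snr=5.0, seed=42)


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture(scope="session")
def preprocessed_session():
    """A 12-trials-per-class session, long enough for stable channel ranking."""
    cfg = SyntheticConfig(n_trials_per_class=12, snr=5.0, seed=42)
    eeg, fnirs_od, events, truth = generate_session(cfg)
    return preprocess_eeg(eeg), preprocess_fnirs(fnirs_od), events, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
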