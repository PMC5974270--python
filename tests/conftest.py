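import numpy as np
import pytest

import paintrace as pt

# Desk-scale study conditions shared across tests: the minimum session size
# (15 trials/class), 4 channels, 8 units. Heavier tests build their own.


@pytest.fixture(scope="session")
def small_config():
    return pt.SynthConfig(n_trials_per_class=15, channels=4, n_units=8)


@pytest.fixture(scope="session")
def null_config():
    """All ERS gains at 1 and no spike modulation: labels carry no signal."""
    return pt.SynthConfig(
        n_trials_per_class=15,
        channels=4,
        n_units=8,
        ers_gain={"theta": {"NS": 1.0, "LS": 1.0, "HS": 1.0}},
        modulated_rate_gain=1.0,
    )


@pytest.fixture(scope="session")
def strong_session(small_config):
    """NS-vs-HS session with the default (intensity-scaled) ERS, denoised."""
    s = pt.make_session(small_config, "NS-HS", "naive", seed=11)
    pt.denoise_session(s)
    return s


@pytest.fixture(scope="session")
def null_session(null_config):
    s = pt.make_session(null_config, "NS-HS", "naive", seed=23)
    pt.denoise_session(s)
    return s


@pytest.fixture(scope="session")
def strong_lfp_features(strong_session):
    return pt.lfp_band_features(strong_session)


@pytest.fixture(scope="session")
def strong_spike_features(strong_session):
    return pt.cumulative_spike_features(strong_session)
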