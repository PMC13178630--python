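import numpy as np
import pytest
from hypothesis import settings

from coneorg import AcquisitionConfig, PopulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def acq():
    return AcquisitionConfig()


@pytest.fixture
def noiseless_pop():
    """Degenerate population: every stochastic channel switched off."""
    return PopulationConfig(
        n_cones=3, sd_A1=0.0, sd_tau_a=0.0, sd_tau_b=0.0,
        s_cone_fraction=0.0, trial_noise_sd=0.0, snr_db=None,
        dropout_rate=0.0, baseline_drift_rms=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
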