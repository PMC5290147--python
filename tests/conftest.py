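import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import scfskit as sk
from scfskit.synthetic import AcquisitionParams, single_molecule_acquisition

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def quiet_acq():
    """Noise-free, drift-free cell-scale acquisition."""
    return AcquisitionParams(noise_sd=0.0)


@pytest.fixture
def sm_acq():
    """Single-molecule acquisition with the default 10 pN noise."""
    return single_molecule_acquisition()


@pytest.fixture
def study_dataset():
    """Small four-condition adhesion dataset from the default study config."""
    table = sk.simulate_adhesion_table(sk.default_study_config(seed=17))
    return sk.AdhesionDataset(table)
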