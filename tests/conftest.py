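import numpy as np
import pytest

from calfcontrib import TrialParams, default_model, generate_trial


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def noiseless_trial(model):
    return generate_trial(model, TrialParams(seed=11))


@pytest.fixture(scope="session")
def noisy_trial(model):
    return generate_trial(
        model, TrialParams(seed=12, noise_sd_marker=0.001, noise_sd_force=2.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
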