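import numpy as np
import pytest

from wavemi.cwt import MotherWavelet
from wavemi.synthetic import ERDParams, EpochSet, generate_epoch


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free condition with a -75% contralateral ERD and no Cz spread."""
    return ERDParams(erd_attenuation=0.5, noise_sigma=0.0, cz_mix=0.0)


@pytest.fixture(scope="session")
def clean_left_epoch(clean_params):
    return generate_epoch("left", clean_params, seed=11)


@pytest.fixture(scope="session")
def left_epoch_set(clean_params):
    """100 noise-free left-hand trials for parameter-recovery checks."""
    epochs = [generate_epoch("left", clean_params, seed=s) for s in range(100)]
    return EpochSet(epochs=epochs, seed=0, params=clean_params)


@pytest.fixture(params=["morlet", "mexican_hat", "bump"])
def wavelet(request):
    return MotherWavelet(request.param)


@pytest.fixture(scope="session")
def tone_500():
    """2 s, 500-sample 10 Hz unit tone at 250 Hz."""
    fs = 250.0
    t = np.arange(500) / fs
    return np.sin(2 * np.pi * 10.0 * t), fs
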