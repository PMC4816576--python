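import numpy as np
import pandas as pd
import pytest

from erpdecode import (
    Epochs,
    analysis_montage,
    make_default_config,
    simulate_subject,
    standard_montage,
)


@pytest.fixture(scope="session")
def full_montage():
    return standard_montage()


@pytest.fixture(scope="session")
def small_montage():
    return analysis_montage()


@pytest.fixture(scope="session")
def default_config(small_montage):
    """Default study conditions on the reduced montage (keeps tests cheap)."""
    return make_default_config(n_subjects=4, montage=small_montage, seed=11)


@pytest.fixture(scope="session")
def noiseless_config(small_montage):
    cfg = make_default_config(n_subjects=2, montage=small_montage, seed=5)
    cfg.noise.white_sd = cfg.noise.pink_sd = cfg.noise.alpha_sd = 0.0
    cfg.between_subject_amplitude_sd = 0.0
    return cfg


@pytest.fixture(scope="session")
def subject_epochs(default_config):
    """One simulated subject's flanker-task epochs."""
    return simulate_subject(default_config, 0, "flanker", 123)


def make_epochs(data, montage, *, rts=None, responses=None, task="flanker", sfreq=500.0):
    """Wrap a raw (trials, channels, samples) array into an Epochs object."""
    data = np.asarray(data, float)
    n = data.shape[0]
    step = 1000.0 / sfreq
    times = -200.0 + step * np.arange(data.shape[2])
    meta = pd.DataFrame(
        {
            "subject_id": 0,
            "task": task,
            "response": responses if responses is not None else ["correct"] * n,
            "rt": rts if rts is not None else np.full(n, 300.0),
        }
    )
    return Epochs(
        data=data, montage=montage, sampling_rate=sfreq, times=times,
        trial_meta=meta, lock="response",
    )
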