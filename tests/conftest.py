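import numpy as np
import pandas as pd
import pytest

from lcstress.config import BehaviorConfig, CohortConfig, NoiseConfig, PupilConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Compact study configuration for fast end-to-end tests."""
    return CohortConfig(
        n_subjects=3,
        n_trials=40,
        n_scans=110,
        grid_shape=(16, 20, 13),
        seed=7,
    )


@pytest.fixture
def noiseless_cfg():
    """Zero-noise configuration: analyses must invert the generator exactly."""
    return CohortConfig(
        n_trials=60,
        n_scans=160,
        grid_shape=(16, 20, 13),
        noise=NoiseConfig(sigma=0.0, physio_amps=(0.0, 0.0, 0.0),
                          motion_coupling=0.0),
        seed=3,
    )


def toy_trials(sequence, valence=None, rts=None, accuracy=None,
               soa=4.0, duration=1.0):
    """Build a trial table from an explicit congruency sequence like 'CICI'."""
    congr = np.array(list(sequence))
    n = len(congr)
    prev = np.concatenate([["none"], congr[:-1]])
    tt = np.where(prev == "none", "first",
                  np.char.add(prev.astype(str), congr.astype(str)))
    return pd.DataFrame({
        "trial_index": np.arange(n),
        "onset_seconds": 12.0 + soa * np.arange(n),
        "duration_seconds": duration,
        "congruency": congr,
        "prev_congruency": prev,
        "trial_type": tt,
        "valence": valence if valence is not None else ["happy"] * n,
        "rt_ms": rts if rts is not None else np.full(n, 500.0),
        "accuracy": accuracy if accuracy is not None else np.ones(n),
    })
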