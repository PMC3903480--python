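import numpy as np
import pytest

import tgdecode as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sustained_epochs():
    """One simulated subject: strong sustained signal on a small grid."""
    cfg = tg.SimulationConfig(
        scenario=tg.sustained_scenario(duration=8, start=2, n_samples=12),
        n_trials=40,
        n_channels=8,
        n_samples=12,
        snr=1.0,
        seed=7,
    )
    return tg.simulate_subject(cfg, subject_seed=0)


@pytest.fixture(scope="session")
def session_epochs():
    """A full local-global session with noise data and exact trial counts."""
    labels = tg.reference_session_labels(seed=11)
    data = np.random.default_rng(11).standard_normal((len(labels), 4, 6))
    times = np.arange(6) / 256.0
    return tg.EpochsSet(
        data=data, times=times, sample_rate=256.0, labels=labels,
        subject_id="session",
    )
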