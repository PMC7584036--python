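import numpy as np
import pytest

from pulsebp.synthetic import SimConfig, simulate_record


@pytest.fixture(scope="session")
def clean_record():
    """A 20 s clean record at 75 bpm, PTT 0.25 s (no drift, no noise)."""
    return simulate_record(SimConfig(duration_s=20.0, heart_rate_bpm=75.0, ptt_s=0.25))


@pytest.fixture(scope="session")
def noisy_record():
    """Same conditions plus drift and mild broadband noise."""
    return simulate_record(
        SimConfig(
            duration_s=20.0,
            heart_rate_bpm=75.0,
            ptt_s=0.25,
            drift_amplitude=0.3,
            drift_freq_hz=0.05,
            noise_sd=0.01,
            seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
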