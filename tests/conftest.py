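import numpy as np
import pytest

import affectcare as ac


@pytest.fixture(scope="session")
def default_config() -> ac.SimConfig:
    return ac.SimConfig(seed=1)


@pytest.fixture(scope="session")
def short_config() -> ac.SimConfig:
    """A cheap configuration for unit tests: 4 s recordings, clean."""
    return ac.SimConfig(seed=7, duration_s=4.0, mains_amplitude=0.0)


@pytest.fixture(scope="session")
def bandstop_spec() -> ac.FilterSpec:
    return ac.design_bandstop(3, 48.0, 52.0, 250.0)


@pytest.fixture(scope="session")
def small_labeled_vectors(bandstop_spec):
    """Feature vectors from a small simulated dataset (7 classes x 15, 6 s)."""
    cfg = ac.SimConfig(seed=11, duration_s=6.0)
    dataset = ac.simulate_labeled_dataset(ac.DEFAULT_CLASS_PARAMS, 15, cfg)
    return [ac.extract_vector(rec, bandstop_spec) for rec in dataset]


def make_signal(samples, channel="ECG", fs=250.0, label=None) -> ac.Biosignal:
    return ac.Biosignal(channel, np.asarray(samples, dtype=float), fs, label)


@pytest.fixture
def sine_signal():
    def _make(freq_hz: float, fs: float = 250.0, duration_s: float = 4.0, amp: float = 1.0):
        t = np.arange(int(duration_s * fs)) / fs
        return make_signal(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)

    return _make
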