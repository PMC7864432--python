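import numpy as np
import pytest

import rseeg


@pytest.fixture(scope="session")
def montage():
    return rseeg.standard_1020()


@pytest.fixture(scope="session")
def hc_session(montage):
    """One 60-s healthy-profile session, moderately mixed."""
    return rseeg.generate_subject(
        rseeg.healthy_profile(), montage=montage, duration_s=60.0, seed=11
    )


@pytest.fixture(scope="session")
def hc_filtered(hc_session):
    return rseeg.bandpass_filter(hc_session)


@pytest.fixture(scope="session")
def hc_epm(hc_filtered):
    return rseeg.epoch_psd(hc_filtered)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sine_session(freq_hz, amplitude=10.0, duration_s=8.0, fs=256.0,
                 labels=("O1", "O2", "Cz", "Fz", "Pz")):
    """Deterministic pure-sinusoid session on a few channels."""
    mont = rseeg.standard_1020(labels)
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return rseeg.RecordingSession(
        samples=np.tile(x, (len(labels), 1)), fs=fs, montage=mont
    )
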