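import numpy as np
import pytest

from dyadsync.montage_io import CodingEvent, CodingLog, RawRecording, \
    build_default_montage
from dyadsync.preprocess import HbSeries

FS = 7.81


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(intensity, role="mother", dyad_id="d000", fs=FS,
                   montage=None):
    montage = montage or build_default_montage()
    return RawRecording(subject_role=role, dyad_id=dyad_id, fs=fs,
                        intensity=intensity, montage=montage)


def random_recording(rng, n_samples=400, role="mother", dyad_id="d000",
                     fs=FS, montage=None):
    """Positive random intensities around 1.0 for all 16 channels."""
    montage = montage or build_default_montage()
    base = rng.uniform(0.5, 2.0, size=(2, montage.n_channels, 1))
    wiggle = 1.0 + 0.05 * rng.standard_normal((2, montage.n_channels,
                                               n_samples))
    return make_recording(base * np.abs(wiggle) + 0.1, role=role,
                          dyad_id=dyad_id, fs=fs, montage=montage)


def make_hb(signal_by_channel, role="mother", dyad_id="d000", fs=FS,
            montage=None, mask=None):
    """HbSeries whose HbO rows are the given (n_channels, n) array."""
    montage = montage or build_default_montage()
    hbo = np.asarray(signal_by_channel, dtype=float)
    hbr = -0.5 * hbo
    return HbSeries(hbo=hbo, hbr=hbr, fs=fs, montage=montage,
                    subject_role=role, dyad_id=dyad_id, channel_mask=mask)


def event(speaker, onset_ms, offset_ms, code="vocalization"):
    return CodingEvent(speaker, onset_ms, offset_ms, code)


def log_of(events, dyad_id="d000"):
    return CodingLog(dyad_id=dyad_id, events=list(events))
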