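import numpy as np
import pytest

from radarbeat.radar_sim import (RadarParams, VitalModel, chest_displacement,
                                 generate_beat_train, synthesize_ecg,
                                 synthesize_iq)
from radarbeat.signal_core import SubjectRecording, TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_params():
    """Radar front end with imbalance, offsets and noise disabled."""
    return RadarParams(A_I=1.0, A_Q=1.0, DC_I=0.0, DC_Q=0.0, dphi=0.0,
                       noise_sd=0.0, phase_noise_sd=0.0)


@pytest.fixture
def default_model():
    return VitalModel()


def make_recording(duration=20.0, seed=5, model=None, params=None,
                   subject_id="T01", ecg_noise=0.01):
    """One fully synthetic subject with ground-truth beats."""
    model = model or VitalModel()
    params = params or RadarParams()
    beats = generate_beat_train(model, duration, seed)
    x = chest_displacement(beats, model, params.fs, duration, seed + 1)
    i_ch, q_ch = synthesize_iq(x, params, seed + 2)
    ecg = synthesize_ecg(beats, 250.0, duration, seed + 3,
                         noise_sd=ecg_noise)
    return SubjectRecording(subject_id=subject_id, ecg=ecg, i_ch=i_ch,
                            q_ch=q_ch, truth_beats=beats)


@pytest.fixture
def small_recording():
    return make_recording(duration=20.0, seed=5)
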