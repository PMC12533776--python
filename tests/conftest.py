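import numpy as np
import pytest

from pupilvr import GenerativeParams, PipelineConfig
from pupilvr.datatypes import PupilTrace
from pupilvr.synth import PlannedTrial


@pytest.fixture
def pipeline():
    return PipelineConfig()


@pytest.fixture
def gen_params():
    return GenerativeParams()


@pytest.fixture
def quiet_params():
    """Noise-free, blink-free generator: every downstream value is exact."""
    return GenerativeParams(tau_bps_mm=0.0, sigma_bps_mm=0.0, tau_amp_mm=0.0,
                            sigma_amp_mm=0.0, sample_noise_mm=0.0,
                            blink_rate_hz=0.0, jitter_sd_s=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(t, d, marked=None, trial_index=5, load="single",
               copresence="distractors", feedback="none", pid="P01"):
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if marked is None:
        marked = np.zeros(t.size, dtype=bool)
    return PupilTrace(participant_id=pid, trial_index=trial_index, load=load,
                      copresence=copresence, sent_dur_left_s=1.5,
                      sent_dur_right_s=1.5, feedback=feedback,
                      t_s=t, diameter_mm=d, marked=np.asarray(marked, bool))


def uniform_trace(fs=90.0, t0=-3.0, t1=4.5, level=4.0, **kw):
    """Constant-diameter trace on a uniform grid covering the window."""
    n = int(round((t1 - t0) * fs)) + 1
    t = t0 + np.arange(n) / fs
    return make_trace(t, np.full(n, level), **kw)


@pytest.fixture
def planned_trial():
    return PlannedTrial(trial_index=5, load="dual", copresence="agents",
                        sent_dur_left_s=1.6, sent_dur_right_s=1.4,
                        words_left=6, words_right=6)
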