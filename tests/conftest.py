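import numpy as np
import pytest

from imikin.io_trials import TrackerSeries, Trial
from imikin.synthetic import make_speed_profile


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def bell_positions(pv=70.0, mt_ms=800.0, tpv=0.45, fs=240.0,
                   pre_ms=500.0, post_ms=500.0, direction=(1.0, 0.0, 0.0),
                   start=(0.0, 0.0, 0.0), threshold_fraction=None):
    """Integrate a bell speed profile into a 3D straight-line trajectory with
    stationary padding on both sides."""
    profile = make_speed_profile(pv, mt_ms, tpv, fs,
                                 threshold_fraction=threshold_fraction)
    n_pre = int(round(pre_ms / 1000 * fs))
    n_post = int(round(post_ms / 1000 * fs))
    speed = np.concatenate([np.zeros(n_pre), profile, np.zeros(n_post)])
    arc = np.zeros_like(speed)
    arc[1:] = np.cumsum((speed[1:] + speed[:-1]) / 2) / fs
    return np.asarray(start) + arc[:, None] * np.asarray(direction, float)


def make_series(positions, label="wrist", role="imitator", fs=240.0):
    return TrackerSeries(label=label, role=role,
                         positions=np.asarray(positions, float),
                         sample_rate=fs)


def make_bell_trial(fs=240.0, go_ms=200.0, **kwargs):
    """Trial whose actor and imitator wrists carry identical bell movements."""
    pos = bell_positions(fs=fs, pre_ms=500.0, **kwargs)
    trial = Trial(
        participant_id="P01", session_index=0, site="pMTG",
        meaning="meaningful", effector="hand", gesture_id="g00",
        actor={"wrist": make_series(pos, role="actor", fs=fs)},
        imitator={"wrist": make_series(pos, role="imitator", fs=fs)},
        event_times={r: {"go_ms": go_ms, "stop_ms": 3000.0}
                     for r in ("actor", "imitator")},
    )
    return trial
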