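import numpy as np
import pytest

from imikin.kinematics import SegmentationConfig, segment_movement
from imikin.preprocess import (PreprocessConfig, PreprocessError,
                               apply_exclusions, despike,
                               drop_artifact_trackers, lowpass)
from imikin.synthetic import GeneratorConfig, make_trial

from conftest import bell_positions, make_bell_trial, make_series

FS = 240.0


def sinusoid_positions(n=400, amp=5.0, freq=1.5, fs=FS):
    """Gentle oscillatory trajectory: double-differenced trace is itself a
    sinusoid, whose max/SD ratio (sqrt 2) stays below the spike criterion."""
    t = np.arange(n) / fs
    return np.column_stack([amp * np.sin(2 * np.pi * freq * t),
                            amp * np.cos(2 * np.pi * freq * t),
                            0.5 * amp * np.sin(2 * np.pi * freq * t + 1.0)])


class TestDespike:
    def test_constant_series_unchanged(self):
        series = make_series(np.full((50, 3), 7.0))
        out, count = despike(series)
        assert count == 0
        np.testing.assert_array_equal(out.positions, series.positions)

    def test_single_spike_removed(self):
        clean = sinusoid_positions()
        spiked = clean.copy()
        spiked[200] += np.array([10.0, 0.0, 0.0])
        out, count = despike(make_series(spiked))
        assert count >= 1
        residual = np.abs(out.positions - clean)
        assert residual[200].max() < 0.1

    def test_two_spikes_counted(self):
        clean = sinusoid_positions()
        spiked = clean.copy()
        spiked[100] += np.array([0.0, 10.0, 0.0])
        spiked[300] += np.array([-8.0, 0.0, 4.0])
        _, count = despike(make_series(spiked))
        assert count >= 2

    def test_idempotent_on_isolated_spikes(self):
        # constant-velocity motion: the repair lies exactly on the line, so a
        # second pass sees a flat double-differenced trace
        t = np.arange(400) / FS
        spiked = np.column_stack([12.0 * t, -3.0 * t, 5.0 * t])
        spiked[150] += np.array([9.0, -3.0, 2.0])
        once, count1 = despike(make_series(spiked))
        twice, count2 = despike(once)
        assert count1 >= 1
        assert count2 == 0
        np.testing.assert_array_equal(twice.positions, once.positions)

    def test_too_short_series_rejected(self):
        series = make_series(np.zeros((7, 3)))
        with pytest.raises(PreprocessError):
            despike(series, PreprocessConfig(interp_halfwidth=3))

    def test_length_preserved(self):
        spiked = sinusoid_positions(n=123)
        spiked[60, 2] += 10.0
        out, _ = despike(make_series(spiked))
        assert out.n_samples == 123


class TestLowpass:
    def test_dc_gain_is_one(self):
        series = make_series(np.full((100, 3), 3.25))
        out = lowpass(series)
        np.testing.assert_allclose(out.positions, 3.25, atol=1e-9)

    def test_stopband_attenuation_matches_analytic_magnitude(self):
        # 50 Hz tone at 240 Hz sampling; two filter passes square the
        # 4th-order Butterworth magnitude |H|^2 = 1/(1 + (f/fc)^8).
        t = np.arange(2000) / FS
        tone = np.column_stack([np.sin(2 * np.pi * 50.0 * t)] * 3)
        out = lowpass(make_series(tone))
        measured = np.abs(out.positions[500:1500, 0]).max()
        # digital Butterworth: evaluate at the warped analog frequency
        warp = lambda f: np.tan(np.pi * f / FS)
        single_pass = 1.0 / np.sqrt(1.0 + (warp(50.0) / warp(12.0)) ** 8)
        expected = single_pass ** 2
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_phase_time_reversal_symmetry(self, rng):
        pos = np.cumsum(rng.normal(0, 0.3, (400, 3)), axis=0)
        fwd = lowpass(make_series(pos)).positions
        rev = lowpass(make_series(pos[::-1])).positions
        # away from the padded edges (transients decay within ~100 samples
        # at this cutoff) the forward-backward filter is exactly symmetric
        # under time reversal
        np.testing.assert_allclose(rev[120:-120], fwd[::-1][120:-120],
                                   atol=1e-6)

    def test_linearity(self, rng):
        x = np.cumsum(rng.normal(0, 0.2, (200, 3)), axis=0)
        y = np.cumsum(rng.normal(0, 0.2, (200, 3)), axis=0)
        lhs = lowpass(make_series(2.0 * x + 3.0 * y)).positions
        rhs = (2.0 * lowpass(make_series(x)).positions
               + 3.0 * lowpass(make_series(y)).positions)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(PreprocessError):
            lowpass(make_series(np.zeros((10, 3))))

    def test_cutoff_above_nyquist_rejected(self):
        series = make_series(np.zeros((100, 3)), fs=20.0)
        with pytest.raises(PreprocessError):
            lowpass(series, PreprocessConfig(filter_cutoff=12.0))


def hook(speed, sample_rate):
    return segment_movement(speed, SegmentationConfig(), sample_rate)


class TestApplyExclusions:
    CFG = PreprocessConfig()

    def test_short_movement_excluded(self):
        trial = make_bell_trial(mt_ms=300.0, go_ms=200.0)
        out = apply_exclusions(trial, self.CFG, hook)
        assert out.validity == "excluded"
        assert out.exclusion_reason == "too_short"

    def test_false_start_excluded(self):
        # movement begins ~500 ms into the epoch, go tone at 700 ms
        trial = make_bell_trial(mt_ms=800.0, go_ms=700.0)
        out = apply_exclusions(trial, self.CFG, hook)
        assert out.validity == "excluded"
        assert out.exclusion_reason == "false_start"

    def test_unfinished_movement_excluded(self):
        pos = bell_positions(mt_ms=800.0, post_ms=0.0)
        pos = pos[:len(pos) - 60]  # stop recording mid-deceleration
        trial = make_bell_trial(go_ms=200.0)
        trial.imitator["wrist"] = make_series(pos, role="imitator")
        out = apply_exclusions(trial, self.CFG, hook)
        assert out.validity == "excluded"
        assert out.exclusion_reason == "unfinished"

    def test_clean_trial_valid(self):
        trial = make_bell_trial(mt_ms=800.0, go_ms=200.0)
        out = apply_exclusions(trial, self.CFG, hook)
        assert out.validity == "valid"
        assert out.exclusion_reason is None

    def test_missing_wrist_excluded(self):
        trial = make_bell_trial()
        del trial.imitator["wrist"]
        out = apply_exclusions(trial, self.CFG, hook)
        assert out.exclusion_reason == "missing_tracker"

    def test_sample_data_never_mutated(self):
        trial = make_bell_trial(mt_ms=300.0)
        before = trial.imitator["wrist"].positions.copy()
        out = apply_exclusions(trial, self.CFG, hook)
        np.testing.assert_array_equal(out.imitator["wrist"].positions, before)


class TestDropArtifactTrackers:
    def full_trial(self):
        cfg = GeneratorConfig.low_noise(seed=3)
        rng = np.random.default_rng(3)
        trial, _ = make_trial(("pMTG", "meaningful", "hand"), cfg, rng)
        return trial

    def test_flagged_tracker_removed(self):
        trial = self.full_trial()
        out = drop_artifact_trackers(trial, [("actor", "little")])
        assert len(out.actor) + len(out.imitator) == 15
        assert "little" not in out.actor
        assert "little" in out.imitator
        assert out.validity == "valid"

    def test_wrist_removal_excludes_trial(self):
        out = drop_artifact_trackers(self.full_trial(), [("imitator", "wrist")])
        assert out.validity == "excluded"
        assert out.exclusion_reason == "missing_tracker"

    def test_empty_flags_no_change(self):
        trial = self.full_trial()
        out = drop_artifact_trackers(trial, [])
        assert out is trial
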