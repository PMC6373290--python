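import dataclasses

import numpy as np
import pytest

from imikin.kinematics import (SegmentationConfig, SegmentationError,
                               digit_relative_pv, extract_wrist_kinematics,
                               segment_movement, speed_profile)
from imikin.preprocess import preprocess_trial
from imikin.synthetic import GeneratorConfig, make_speed_profile, make_trial

from conftest import bell_positions, make_bell_trial, make_series

FS = 240.0
SEG = SegmentationConfig()


class TestSpeedProfile:
    def test_stationary_series_zero_speed(self):
        speed = speed_profile(make_series(np.full((50, 3), 2.0)))
        np.testing.assert_allclose(speed, 0.0)

    def test_uniform_straight_line(self):
        t = np.arange(100) / FS
        pos = np.column_stack([10.0 * t, np.zeros_like(t), np.zeros_like(t)])
        speed = speed_profile(make_series(pos))
        np.testing.assert_allclose(speed, 10.0, rtol=1e-12)

    def test_peak_matches_commanded_pv(self):
        pos = bell_positions(pv=70.0, mt_ms=800.0, tpv=0.45)
        speed = speed_profile(make_series(pos))
        assert speed.max() == pytest.approx(70.0, abs=1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            speed_profile(make_series(np.zeros((2, 3))))


class TestSegmentMovement:
    def test_symmetric_bell_symmetric_about_peak(self):
        profile = make_speed_profile(60.0, 800.0, 0.5, FS)
        speed = np.concatenate([np.zeros(100), profile, np.zeros(100)])
        onset, offset = segment_movement(speed, SEG, FS)
        peak = int(np.argmax(speed))
        assert abs((peak - onset) - (offset - peak)) <= 1
        assert onset < peak < offset

    def test_recovers_commanded_duration(self):
        rng = np.random.default_rng(4)
        cfg = GeneratorConfig(noise_sd_cm=0.05, spike_prob=0.0,
                              contamination={"too_short": 0.0,
                                             "false_start": 0.0,
                                             "unfinished": 0.0},
                              seed=4)
        errors = []
        for _ in range(10):
            trial, truth = make_trial(("vertex", "meaningful", "hand"),
                                      cfg, rng)
            clean, _ = preprocess_trial(trial)
            wrist = clean.imitator["wrist"]
            onset, offset = segment_movement(speed_profile(wrist), SEG, FS)
            mt = (offset - onset) / FS * 1000.0
            errors.append(abs(mt - truth.imit_mt) / truth.imit_mt)
        assert np.mean(errors) < 0.05

    def test_flat_trace_raises(self):
        with pytest.raises(SegmentationError):
            segment_movement(np.zeros(100), SEG, FS)


class TestExtractWristKinematics:
    def test_symmetric_bell_tpv_half(self):
        trial = make_bell_trial(tpv=0.5, mt_ms=800.0)
        summary = extract_wrist_kinematics(trial, "imitator", SEG)
        n = summary.offset_idx - summary.onset_idx
        assert summary.tpv_over_mt == pytest.approx(0.5, abs=1.5 / n)

    def test_recovers_commanded_asymmetry(self):
        trial = make_bell_trial(tpv=0.40, mt_ms=800.0,
                                threshold_fraction=0.05)
        summary = extract_wrist_kinematics(trial, "imitator", SEG)
        assert summary.tpv_over_mt == pytest.approx(0.40, abs=0.02)
        assert summary.mt_ms == pytest.approx(800.0, rel=0.02)
        assert summary.pv == pytest.approx(70.0, rel=0.02)

    def test_deceleration_peak_follows_velocity_peak(self):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(seed=5)
        for cond in (("pMTG", "meaningful", "hand"),
                     ("vertex", "meaningless", "finger")):
            trial, truth = make_trial(cond, cfg, rng)
            if truth.contamination != "none":
                continue
            clean, _ = preprocess_trial(trial)
            s = extract_wrist_kinematics(clean, "imitator", SEG)
            assert 0.0 < s.tpv_over_mt < s.tpd_over_mt <= 1.0

    def test_time_rescaling_invariance(self):
        # same positions replayed at half the rate: PV halves, MT doubles,
        # and the dimensionless landmarks TPV/MT, TPD/MT stay put
        trial = make_bell_trial(tpv=0.42, mt_ms=800.0)
        fast = extract_wrist_kinematics(trial, "imitator", SEG)
        slow_trial = dataclasses.replace(
            trial,
            imitator={"wrist": dataclasses.replace(
                trial.imitator["wrist"], sample_rate=FS / 2)},
        )
        slow = extract_wrist_kinematics(slow_trial, "imitator", SEG)
        assert slow.mt_ms == pytest.approx(2 * fast.mt_ms)
        assert slow.pv == pytest.approx(fast.pv / 2)
        assert slow.tpv_over_mt == pytest.approx(fast.tpv_over_mt)
        assert slow.tpd_over_mt == pytest.approx(fast.tpd_over_mt)

    def test_noise_robustness_of_mt(self):
        rng = np.random.default_rng(6)
        base = make_bell_trial(mt_ms=800.0, threshold_fraction=0.05)
        clean, _ = preprocess_trial(base)
        ref = extract_wrist_kinematics(clean, "imitator", SEG)
        noisy = dataclasses.replace(base, imitator={
            "wrist": base.imitator["wrist"].with_positions(
                base.imitator["wrist"].positions
                + rng.normal(0, 0.1, base.imitator["wrist"].positions.shape))})
        noisy_clean, _ = preprocess_trial(noisy)
        out = extract_wrist_kinematics(noisy_clean, "imitator", SEG)
        assert abs(out.mt_ms - ref.mt_ms) / ref.mt_ms < 0.05


class TestDigitRelativePV:
    def test_rigid_digits_zero(self):
        trial = make_bell_trial()
        wrist = trial.imitator["wrist"]
        for label in ("thumb", "index", "middle", "ring", "little"):
            trial.imitator[label] = dataclasses.replace(
                wrist, label=label,
                positions=wrist.positions + np.array([5.0, 1.0, 0.0]))
        assert digit_relative_pv(trial, "imitator", SEG) == pytest.approx(0.0)

    def test_single_moving_digit_mean(self):
        trial = make_bell_trial()
        wrist = trial.imitator["wrist"]
        n = wrist.n_samples
        for label in ("index", "middle", "ring", "little"):
            trial.imitator[label] = dataclasses.replace(
                wrist, label=label, positions=wrist.positions + 2.0)
        drift = np.outer(np.arange(n) / FS * 8.0, [1.0, 0.0, 0.0])
        trial.imitator["thumb"] = dataclasses.replace(
            wrist, label="thumb", positions=wrist.positions + 1.0 + drift)
        out = digit_relative_pv(trial, "imitator", SEG)
        assert out == pytest.approx(8.0 / 5.0, rel=1e-6)

    def test_no_digits_returns_none(self):
        trial = make_bell_trial()
        assert digit_relative_pv(trial, "imitator", SEG) is None

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(7)
        cfg = GeneratorConfig.low_noise(noise_sd_cm=0.0, spike_prob=0.0,
                                        seed=7)
        trial, _ = make_trial(("pMTG", "meaningless", "finger"), cfg, rng)
        ref = digit_relative_pv(trial, "imitator", SEG)
        shift = np.array([13.0, -4.0, 2.0])
        shifted = dataclasses.replace(trial, imitator={
            k: v.with_positions(v.positions + shift)
            for k, v in trial.imitator.items()})
        out = digit_relative_pv(shifted, "imitator", SEG)
        assert out == pytest.approx(ref, rel=1e-9)

    def test_generator_recovery(self):
        rng = np.random.default_rng(8)
        cfg = GeneratorConfig.low_noise(spike_prob=0.0, seed=8)
        vals = []
        for _ in range(8):
            trial, truth = make_trial(("vertex", "meaningful", "hand"),
                                      cfg, rng)
            clean, _ = preprocess_trial(trial)
            measured = digit_relative_pv(clean, "imitator", SEG)
            # commanded value is the across-digit mean of the injected peaks
            vals.append(measured / truth.digit_pv)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)
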