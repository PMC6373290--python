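"""Seeded generator of two-person gesture-imitation datasets.

The generator emulates the trial structure of a dyadic imitation experiment:
an actor performs a discrete gesture after a go tone, and an imitator copies
it in a separate epoch of the same trial.  Wrist speed follows a
single-peaked, asymmetric beta-family bell; digits ride the wrist with their
own relative motion; shoulder and elbow carry attenuated copies of the wrist
displacement.  Sensor noise, single-sample electromagnetic spikes, and
trials that violate the exclusion rules (too short, false start, unfinished)
are injected at configurable rates, and every trial carries a complete
ground-truth record.

Commanded kinematics are threshold-referenced: the configured MT, PV and
TPV/MT are defined at the relative speed threshold a standard segmenter uses
(5 % of PV by default), so the profile's sub-threshold tails extend beyond
the commanded MT and a threshold-based pipeline recovers the commanded
values rather than systematically clipped ones.

The injected actor-imitator lag ground truth is defined operationally: the
lag at maximum Pearson correlation between the *clean* (pre-sensor-noise)
windowed speed profiles, found by exhaustive scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .io_trials import (DIGIT_LABELS, EFFECTORS, MEANINGS, SITES,
                        TrackerSeries, Trial, write_trial)
from .kinematics import SegmentationConfig, SegmentationError, segment_movement

CONDITIONS = tuple((s, m, e) for s in SITES for m in MEANINGS
                   for e in EFFECTORS)

#: fixed per-digit scaling of the commanded mean digit speed (mean 1, so the
#: across-digit mean equals the commanded value)
DIGIT_GAIN = {"thumb": 1.2, "index": 1.1, "middle": 1.0,
              "ring": 0.9, "little": 0.8}
DIGIT_OFFSET_CM = {
    "thumb": (3.0, 2.0, 0.5), "index": (6.5, 3.0, 1.0),
    "middle": (7.5, 3.5, 1.5), "ring": (7.0, 3.0, 2.5),
    "little": (6.0, 2.5, 3.5),
}
ARM_ATTENUATION = {"elbow": 0.45, "shoulder": 0.12}


def default_cell_means() -> dict[str, dict[tuple[str, str, str], float]]:
    """Per-condition means of the imitator wrist markers and digit speed.

    Built from meaningful/meaningless x hand/finger cell values with small
    additive stimulation-site offsets, so the generated data carry meaning
    and effector main effects (higher, longer, earlier-peaked movements for
    hand gestures; faster but longer movements for meaningless gestures) and
    only weak site effects.
    """
    pv_me = {("meaningful", "hand"): 76.6, ("meaningless", "hand"): 82.3,
             ("meaningful", "finger"): 55.7, ("meaningless", "finger"): 56.7}
    tpv_me = {("meaningful", "hand"): 0.412, ("meaningless", "hand"): 0.381,
              ("meaningful", "finger"): 0.426, ("meaningless", "finger"): 0.415}
    mt_me = {("meaningful", "hand"): 833.0, ("meaningless", "hand"): 897.0,
             ("meaningful", "finger"): 736.0, ("meaningless", "finger"): 750.0}
    digit_e = {"hand": 72.6, "finger": 66.3}
    site_offset = {"PV": {"pMTG": -1.45, "vertex": +1.45},
                   "TPV": {"pMTG": +0.001, "vertex": -0.001},
                   "MT": {"pMTG": -4.0, "vertex": +4.0},
                   "digit_PV": {"pMTG": 0.0, "vertex": 0.0}}
    out: dict[str, dict[tuple[str, str, str], float]] = {
        "PV": {}, "TPV": {}, "MT": {}, "digit_PV": {}}
    for site, meaning, effector in CONDITIONS:
        out["PV"][(site, meaning, effector)] = (
            pv_me[(meaning, effector)] + site_offset["PV"][site])
        out["TPV"][(site, meaning, effector)] = (
            tpv_me[(meaning, effector)] + site_offset["TPV"][site])
        out["MT"][(site, meaning, effector)] = (
            mt_me[(meaning, effector)] + site_offset["MT"][site])
        out["digit_PV"][(site, meaning, effector)] = digit_e[effector]
    return out


@dataclass
class GeneratorConfig:
    """Study-structure and noise parameters of the synthetic experiment.

    Defaults follow the emulated design: 12 participants, two sessions
    (stimulation sites), two action-meaning blocks per session, 64 trials
    per block with hand and finger gestures interleaved, 240 Hz trackers.
    ``cell_means`` hold per-condition means of PV (cm/s), MT (ms), TPV/MT
    and mean relative digit PV (cm/s); ``between_sd`` are between-participant
    SDs of stable individual offsets, ``trial_sd`` within-participant
    trial-to-trial SDs.
    """

    n_participants: int = 12
    trials_per_block: int = 64
    sample_rate: float = 240.0
    cell_means: dict = field(default_factory=default_cell_means)
    between_sd: dict = field(default_factory=lambda: {
        "PV": 10.5, "TPV": 0.025, "MT": 70.0, "digit_PV": 12.0})
    trial_sd: dict = field(default_factory=lambda: {
        "PV": 6.0, "TPV": 0.02, "MT": 50.0, "digit_PV": 6.0})
    target_correlation: float = 0.9
    lag_mean_ms: float = 0.0
    lag_sd_ms: float = 25.0
    noise_sd_cm: float = 0.05
    spike_prob: float = 0.01
    spike_amplitude_cm: float = 10.0
    contamination: dict = field(default_factory=lambda: {
        "too_short": 0.08, "false_start": 0.07, "unfinished": 0.08})
    shape_k: float = 8.0
    onset_threshold: float = 0.05
    epoch_ms: float = 3250.0
    go_ms: float = 1000.0
    stop_ms: float = 3000.0
    reaction_ms: tuple[float, float] = (250.0, 400.0)
    actor_sd_scale: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sds in (("between_sd", self.between_sd),
                          ("trial_sd", self.trial_sd)):
            if any(v < 0 for v in sds.values()):
                raise ValueError(f"{name} entries must be >= 0")
        for k, p in self.contamination.items():
            if not 0 <= p <= 1:
                raise ValueError(f"contamination[{k}] must be in [0, 1]")
        if not 0 < self.target_correlation <= 1:
            raise ValueError("target_correlation must be in (0, 1]")

    @classmethod
    def low_noise(cls, **overrides) -> "GeneratorConfig":
        """Parameter-recovery regime: sensor noise in the sub-sample-jitter
        range, no contaminated trials."""
        defaults = dict(
            noise_sd_cm=0.01, spike_prob=0.005,
            contamination={"too_short": 0.0, "false_start": 0.0,
                           "unfinished": 0.0},
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """Commanded parameters and injected artifacts for one trial."""

    participant_id: str
    session_index: int
    site: str
    meaning: str
    effector: str
    gesture_id: str
    trial_index: int
    actor_pv: float
    actor_mt: float
    actor_tpv: float
    imit_pv: float
    imit_mt: float
    imit_tpv: float
    digit_pv: float
    target_r: float
    clean_r: float
    lag_samples: float
    lag_ms: float
    spike_count: int
    contamination: str  # "none" or comma-joined rule names

    @property
    def clean(self) -> bool:
        return self.contamination == "none"


def ground_truth_frame(records: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(g) for g in records])


# ---------------------------------------------------------------------------
# speed profiles


def _bell(s: np.ndarray, a: float, b: float) -> np.ndarray:
    """Beta-family bell on s in [0, 1], normalised to peak 1."""
    peak = a / (a + b)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (s ** a) * ((1.0 - s) ** b)
    return v / (peak ** a * (1.0 - peak) ** b)


@lru_cache(maxsize=4096)
def _shape_for_measured_tpv(tpv_meas: float, k: float,
                            threshold: float) -> tuple[float, float, float]:
    """Shape exponents and threshold crossings giving a measured TPV/MT.

    Returns (a, s_lo, s_hi) such that the bell with exponents
    (a, k - a) crosses ``threshold`` x peak at s_lo and s_hi and the peak
    sits at the fraction ``tpv_meas`` of the [s_lo, s_hi] span.
    """

    def crossings(a: float) -> tuple[float, float]:
        b = k - a
        peak = a / k
        f = lambda s: _bell(np.array(s), a, b) - threshold
        s_lo = optimize.brentq(f, 1e-12, peak)
        s_hi = optimize.brentq(f, peak, 1.0 - 1e-12)
        return s_lo, s_hi

    def measured(a: float) -> float:
        s_lo, s_hi = crossings(a)
        return (a / k - s_lo) / (s_hi - s_lo)

    lo, hi = 0.08 * k, 0.92 * k
    a = optimize.brentq(lambda x: measured(x) - tpv_meas, lo, hi)
    s_lo, s_hi = crossings(a)
    return a, s_lo, s_hi


def make_speed_profile(pv: float, mt_ms: float, tpv_frac: float,
                       sample_rate: float = 240.0, shape_k: float = 8.0,
                       threshold_fraction: float | None = None,
                       ) -> np.ndarray:
    """Single-peak, twice-differentiable bell speed trace (cm/s).

    With ``threshold_fraction=None`` the profile has support exactly
    [0, MT] with its maximum PV at time ``tpv_frac x MT`` and zero at both
    ends.  With a threshold fraction (e.g. the segmenter's 0.05), MT and
    ``tpv_frac`` are instead referenced to the threshold crossings: the
    span between the two crossings is MT and the peak sits at ``tpv_frac``
    of that span, with sub-threshold tails extending the support — the form
    a threshold-based movement segmenter recovers without bias.
    """
    if not 0.0 < tpv_frac < 1.0:
        raise ValueError("tpv_frac must be in (0, 1)")
    if pv <= 0 or mt_ms <= 0:
        raise ValueError("pv and mt_ms must be positive")
    if threshold_fraction is None:
        a = shape_k * tpv_frac
        b = shape_k - a
        # keep the profile twice differentiable at the ends
        if min(a, b) <= 1.0:
            scale = 1.05 / min(a, b)
            a, b = a * scale, b * scale
        n = int(round(mt_ms / 1000.0 * sample_rate)) + 1
        s = np.linspace(0.0, 1.0, n)
        return pv * _bell(s, a, b)

    a, s_lo, s_hi = _shape_for_measured_tpv(
        round(float(tpv_frac), 4), float(shape_k), float(threshold_fraction))
    b = shape_k - a
    full_ms = mt_ms / (s_hi - s_lo)
    n = int(round(full_ms / 1000.0 * sample_rate)) + 1
    s = np.linspace(0.0, 1.0, n)
    return pv * _bell(s, a, b)


def _smooth_noise(n: int, rng: np.random.Generator, sample_rate: float,
                  cutoff: float = 6.0) -> np.ndarray:
    """Low-pass (smooth) noise for velocity-profile shape perturbation."""
    e = rng.standard_normal(n + 40)
    sos = signal.butter(2, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, e)[20:-20]


def _decorrelate_profile(profile: np.ndarray, pv: float, target_r: float,
                         threshold: float, rng: np.random.Generator,
                         sample_rate: float,
                         reference: np.ndarray | None = None) -> np.ndarray:
    """Shape-perturb a speed profile toward a target measured correlation.

    Two smooth perturbations are combined, both constructed so the commanded
    kinematic markers survive:

    * a random time-warp whose displacement is pinned to zero at the two
      threshold crossings and at the peak (tempo variation of the rise and
      fall, preserving PV, MT and TPV exactly), and
    * bounded additive sub-movement bumps whose envelope vanishes below
      2 x threshold and at the peak, keeping the perturbed speed inside
      (1.1 x threshold, PV) wherever it acts — so neither the segmenter's
      crossings nor the maximum can move.

    A single scale in [0, 1] drives both components and is calibrated by
    bisection so that the correlation the analysis will actually report hits
    ``target_r``: when ``reference`` (the partner's windowed speed trace) is
    given, the calibration target is the maximum lagged correlation against
    it; otherwise the zero-lag correlation with the clean profile over its
    above-threshold window.  Because any two single-peaked profiles remain
    strongly correlated, low targets saturate at the perturbation family's
    floor (~0.92 for typical bells); the realized correlation — recorded per
    trial in the ground truth — is then higher than requested.
    """
    if target_r >= 1.0:
        return profile
    n = len(profile)
    thr = threshold * pv
    above = np.flatnonzero(profile >= thr)
    peak = int(np.argmax(profile))
    lo, hi = int(above[0]), int(above[-1])
    t = np.arange(n, dtype=float)

    raw = _smooth_noise(n, rng, sample_rate, cutoff=5.0)
    raw /= max(np.abs(raw).max(), 1e-12)
    taper = np.zeros(n)
    for a, b in ((lo, peak), (peak, hi)):
        if b - a >= 4:
            x = (t[a:b + 1] - a) / (b - a)
            taper[a:b + 1] = np.sin(np.pi * x) ** 2
    warp_base = raw * taper
    # largest displacement field with a strictly monotone time map
    slope = np.max(np.abs(np.diff(warp_base)))
    warp_max = warp_base * (0.9 / slope) if slope > 0 else warp_base

    bump = _smooth_noise(n, rng, sample_rate, cutoff=6.0)
    sd = bump.std()
    # bounded |.| <= 1 with rms ~0.7, so the margin budget is actually used
    bump_unit = np.tanh(1.2 * bump / sd) if sd > 0 else bump

    def realize(scale: float) -> np.ndarray:
        w = np.interp(t + scale * warp_max, t, profile)
        # deviations bounded inside (1.5 x threshold, 0.93 x PV): the
        # perturbed speed can neither cross the segmentation threshold nor
        # compete with the true peak (7% headroom beats filter + noise jitter)
        margin = np.minimum(w - 1.5 * thr, 0.93 * pv - w).clip(min=0.0)
        return w + scale * margin * bump_unit

    window = profile >= thr
    clean = profile[window]

    if reference is None:
        def corr_at(scale: float) -> float:
            return float(np.corrcoef(clean, realize(scale)[window])[0, 1])
    else:
        def corr_at(scale: float) -> float:
            best = _exhaustive_best_lag(reference, realize(scale)[window])
            return best[0] if best is not None else 1.0

    if corr_at(1.0) > target_r:
        return realize(1.0)  # saturated: floor of the perturbation family
    s_lo, s_hi = 0.0, 1.0
    for _ in range(25):
        mid = 0.5 * (s_lo + s_hi)
        if corr_at(mid) > target_r:
            s_lo = mid
        else:
            s_hi = mid
    return realize(0.5 * (s_lo + s_hi))


def _exhaustive_best_lag(a: np.ndarray, b: np.ndarray,
                         min_overlap: int = 3) -> tuple[float, int] | None:
    """Definition of the injected-lag ground truth: plain exhaustive scan of
    the +/-|len difference| lag window on the clean profiles."""
    d = abs(len(b) - len(a))
    best: tuple[float, int] | None = None
    for lag in sorted(range(-d, d + 1), key=lambda s: (abs(s), s)):
        t0 = max(0, -lag)
        t1 = min(len(a), len(b) - lag)
        if t1 - t0 < min_overlap:
            continue
        x, y = a[t0:t1], b[t0 + lag:t1 + lag]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or r > best[0]:
            best = (r, lag)
    return best


# ---------------------------------------------------------------------------
# trial assembly


def _sample_marker(cell: float, trial_sd: float,
                   rng: np.random.Generator, offset: float = 0.0) -> float:
    return cell + offset + rng.normal(0.0, trial_sd)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _integrate(speed: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative arc length of a speed trace (trapezoid rule)."""
    arc = np.zeros_like(speed)
    arc[1:] = np.cumsum((speed[1:] + speed[:-1]) / 2.0) * dt
    return arc


def _embed(profile: np.ndarray, onset_sample: int,
           n_epoch: int) -> np.ndarray:
    v = np.zeros(n_epoch)
    start = max(onset_sample, 0)
    take = min(len(profile), n_epoch - start)
    if take > 0:
        v[start:start + take] = profile[:take]
    return v


def make_trial(condition: tuple[str, str, str],
               config: GeneratorConfig,
               rng: np.random.Generator,
               participant_id: str = "P01",
               session_index: int = 0,
               gesture_id: str = "g00",
               trial_index: int = 0,
               offsets: dict[str, float] | None = None,
               ) -> tuple[Trial, GroundTruth]:
    """Generate one trial (actor epoch + imitator epoch) with ground truth.

    ``offsets`` carries the participant's stable kinematic offsets (keys PV,
    TPV, MT, digit_PV); the actor — a trained confederate — gets none.
    """
    site, meaning, effector = condition
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition}")
    offsets = offsets or {k: 0.0 for k in ("PV", "TPV", "MT", "digit_PV")}
    fs = config.sample_rate
    dt = 1.0 / fs
    n_epoch = int(round(config.epoch_ms / 1000.0 * fs))
    cm = config.cell_means
    tsd = config.trial_sd
    a_scale = config.actor_sd_scale

    # --- commanded kinematics --------------------------------------------
    actor_pv = max(10.0, _sample_marker(cm["PV"][condition],
                                        tsd["PV"] * a_scale, rng))
    actor_mt = max(420.0, _sample_marker(cm["MT"][condition],
                                         tsd["MT"] * a_scale, rng))
    actor_tpv = float(np.clip(_sample_marker(
        cm["TPV"][condition], tsd["TPV"] * a_scale, rng), 0.28, 0.60))

    imit_pv = max(10.0, _sample_marker(cm["PV"][condition], tsd["PV"],
                                       rng, offsets["PV"]))
    imit_mt = max(420.0, _sample_marker(cm["MT"][condition], tsd["MT"],
                                        rng, offsets["MT"]))
    imit_tpv = _sample_marker(cm["TPV"][condition], tsd["TPV"], rng,
                              offsets["TPV"])
    digit_pv = max(5.0, _sample_marker(cm["digit_PV"][condition],
                                       tsd["digit_PV"], rng,
                                       offsets["digit_PV"]))

    # injected lag shifts the imitator's peak within its movement window
    lag_target_ms = rng.normal(config.lag_mean_ms, config.lag_sd_ms)
    imit_tpv = float(np.clip(imit_tpv + lag_target_ms / imit_mt, 0.28, 0.60))

    # --- contamination ----------------------------------------------------
    rates = config.contamination
    flags = [name for name in ("too_short", "false_start", "unfinished")
             if rng.random() < rates.get(name, 0.0)]
    if "too_short" in flags:
        imit_mt = rng.uniform(250.0, 340.0)

    actor_rt = rng.uniform(*config.reaction_ms)
    imit_rt = rng.uniform(*config.reaction_ms)
    actor_onset_ms = config.go_ms + actor_rt
    imit_onset_ms = config.go_ms + imit_rt
    if "false_start" in flags:
        imit_onset_ms = config.go_ms - rng.uniform(80.0, 200.0)

    # --- clean wrist speed profiles --------------------------------------
    thr = config.onset_threshold
    actor_profile = make_speed_profile(actor_pv, actor_mt, actor_tpv, fs,
                                       config.shape_k, threshold_fraction=thr)
    imit_profile = make_speed_profile(imit_pv, imit_mt, imit_tpv, fs,
                                      config.shape_k, threshold_fraction=thr)
    actor_window = actor_profile[actor_profile >= thr * actor_pv]
    imit_profile = _decorrelate_profile(imit_profile, imit_pv,
                                        config.target_correlation, thr, rng,
                                        fs, reference=actor_window)

    if "unfinished" in flags:
        # place the movement so it is still ongoing at epoch end
        imit_onset_ms = config.epoch_ms - 0.55 * len(imit_profile) * 1000 / fs

    actor_onset = int(round(actor_onset_ms / 1000.0 * fs))
    imit_onset = int(round(imit_onset_ms / 1000.0 * fs))
    actor_speed = _embed(actor_profile, actor_onset, n_epoch)
    imit_speed = _embed(imit_profile, imit_onset, n_epoch)

    # --- ground-truth lag from the clean profiles -------------------------
    seg = SegmentationConfig(onset_speed_fraction=thr)
    clean_r = np.nan
    lag_samples: float = np.nan
    try:
        a_on, a_off = segment_movement(actor_speed, seg, fs)
        i_on, i_off = segment_movement(imit_speed, seg, fs)
        best = _exhaustive_best_lag(actor_speed[a_on:a_off + 1],
                                    imit_speed[i_on:i_off + 1])
        if best is not None:
            clean_r, lag_samples = best[0], float(best[1])
    except SegmentationError:
        pass

    # --- positions --------------------------------------------------------
    trackers: dict[str, dict[str, TrackerSeries]] = {"actor": {},
                                                     "imitator": {}}
    for role, speed, profile, onset in (
            ("actor", actor_speed, actor_profile, actor_onset),
            ("imitator", imit_speed, imit_profile, imit_onset)):
        start = (np.array([0.0, 20.0, 0.0]) if role == "actor"
                 else np.array([0.0, -20.0, 0.0])) + rng.normal(0, 1.0, 3)
        direction = _unit_vector(rng)
        wrist_arc = _integrate(speed, dt)
        wrist_pos = start + wrist_arc[:, None] * direction

        role_pv = actor_pv if role == "actor" else imit_pv
        role_digit_pv = digit_pv if role == "imitator" else max(
            5.0, _sample_marker(cm["digit_PV"][condition],
                                tsd["digit_PV"] * a_scale, rng))
        positions = {"wrist": wrist_pos}
        for label, atten in ARM_ATTENUATION.items():
            base = start + np.array({"elbow": [-25.0, 0.0, 2.0],
                                     "shoulder": [-50.0, 0.0, 5.0]}[label])
            positions[label] = base + atten * (wrist_pos - start)
        rel_shape = speed / role_pv  # digit motion co-timed with the wrist
        for label in DIGIT_LABELS:
            rel_peak = role_digit_pv * DIGIT_GAIN[label]
            rel_arc = _integrate(rel_peak * rel_shape, dt)
            d_dir = _unit_vector(rng)
            positions[label] = (wrist_pos + np.asarray(DIGIT_OFFSET_CM[label])
                                + rel_arc[:, None] * d_dir)

        for label, pos in positions.items():
            noisy = pos + rng.normal(0.0, config.noise_sd_cm, pos.shape)
            trackers[role][label] = TrackerSeries(
                label=label, role=role, positions=noisy, sample_rate=fs)

    # --- spikes -----------------------------------------------------------
    spike_count = 0
    for role in ("actor", "imitator"):
        for label, series in trackers[role].items():
            if rng.random() < config.spike_prob:
                idx = int(rng.integers(5, series.n_samples - 5))
                pos = series.positions.copy()
                pos[idx] += config.spike_amplitude_cm * _unit_vector(rng)
                trackers[role][label] = series.with_positions(pos)
                spike_count += 1

    trial = Trial(
        participant_id=participant_id,
        session_index=session_index,
        site=site, meaning=meaning, effector=effector,
        gesture_id=gesture_id,
        actor=trackers["actor"],
        imitator=trackers["imitator"],
        event_times={role: {"go_ms": config.go_ms, "stop_ms": config.stop_ms}
                     for role in ("actor", "imitator")},
    )
    truth = GroundTruth(
        participant_id=participant_id, session_index=session_index,
        site=site, meaning=meaning, effector=effector,
        gesture_id=gesture_id, trial_index=trial_index,
        actor_pv=actor_pv, actor_mt=actor_mt, actor_tpv=actor_tpv,
        imit_pv=imit_pv, imit_mt=imit_mt, imit_tpv=imit_tpv,
        digit_pv=digit_pv, target_r=config.target_correlation,
        clean_r=clean_r, lag_samples=lag_samples,
        lag_ms=(lag_samples * 1000.0 / fs if np.isfinite(lag_samples)
                else np.nan),
        spike_count=spike_count,
        contamination=",".join(flags) if flags else "none",
    )
    return trial, truth


def sample_participant_offsets(config: GeneratorConfig,
                               rng: np.random.Generator) -> dict[str, float]:
    return {k: rng.normal(0.0, sd) for k, sd in config.between_sd.items()}


def generate_experiment(config: GeneratorConfig,
                        out_dir: str | Path | None = None,
                        ) -> tuple[list[Trial], pd.DataFrame]:
    """Generate the full within-participant design, optionally on disk.

    Per participant: 2 sessions (stimulation sites, order counterbalanced by
    participant parity) x 2 action-meaning blocks x ``trials_per_block``
    trials with hand and finger gestures interleaved.  The same seed yields
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    half = config.trials_per_block // 2
    trials: list[Trial] = []
    records: list[GroundTruth] = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        offsets = sample_participant_offsets(config, rng)
        site_order = SITES if p % 2 == 0 else tuple(reversed(SITES))
        for session_index, site in enumerate(site_order):
            meaning_order = (MEANINGS if (p + session_index) % 2 == 0
                             else tuple(reversed(MEANINGS)))
            for meaning in meaning_order:
                effectors = np.array(["hand"] * half + ["finger"] * half)
                rng.shuffle(effectors)
                for t, effector in enumerate(effectors):
                    gesture = f"g{t:02d}_{effector}"
                    trial, truth = make_trial(
                        (site, meaning, str(effector)), config, rng,
                        participant_id=pid, session_index=session_index,
                        gesture_id=gesture, trial_index=t, offsets=offsets)
                    trials.append(trial)
                    records.append(truth)
    truth_df = ground_truth_frame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, trial in enumerate(trials):
            name = (f"{trial.participant_id}_s{trial.session_index}"
                    f"_{trial.site}_{trial.meaning}_{i:04d}.csv")
            write_trial(trial, out_dir / name)
        truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    return trials, truth_df
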