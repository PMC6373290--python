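"""Movement segmentation and wrist/digit kinematic marker extraction.

The wrist speed profile of a discrete gesture is a single-peaked bell.  Four
markers summarise it: movement time (MT, ms), peak velocity (PV, cm/s), and
the times of peak velocity and peak deceleration as fractions of MT (TPV/MT,
TPD/MT).  Low TPV/MT and TPD/MT mean a proportionally longer tail after the
deceleration peak — the feedback-driven correction phase.

Onset and offset are found with a relative speed threshold (a fraction of PV)
plus a dwell-time hysteresis, the standard rule in reach kinematics; both
parameters are exposed in :class:`SegmentationConfig` because published
datasets rarely state the exact rule and sensitivity must be checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_trials import DIGIT_LABELS, TrackerSeries, Trial


class SegmentationError(RuntimeError):
    """Raised when a speed trace has no identifiable movement.

    ``reason`` is ``"no_movement"`` (no threshold crossing) or
    ``"unfinished"`` (speed never settles below threshold after the peak).
    """

    def __init__(self, message: str, reason: str = "no_movement"):
        super().__init__(message)
        self.reason = reason


@dataclass
class SegmentationConfig:
    """Onset/offset rule: speed must cross ``onset_speed_fraction`` x PV and
    stay across it for at least ``min_above_ms``."""

    onset_speed_fraction: float = 0.05
    min_above_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.onset_speed_fraction < 1:
            raise ValueError("onset_speed_fraction must be in (0, 1)")
        if self.min_above_ms < 0:
            raise ValueError("min_above_ms must be >= 0")


@dataclass
class KinematicSummary:
    """Markers for one movement; times in ms, speeds in cm/s, path in cm."""

    onset_idx: int
    offset_idx: int
    mt_ms: float
    pv: float
    tpv_over_mt: float
    tpd_over_mt: float
    path_length: float


def speed_profile(series: TrackerSeries) -> np.ndarray:
    """Scalar speed (cm/s): Euclidean norm of the per-axis first derivative.

    Central differences, one-sided at the endpoints; output length equals
    input length.  The trace should already be low-pass filtered — no extra
    smoothing is applied before differentiation.
    """
    if series.n_samples < 3:
        raise ValueError("speed profile needs at least 3 samples")
    vel = np.gradient(series.positions, series.dt, axis=0)
    return np.linalg.norm(vel, axis=1)


def _first_run(mask: np.ndarray, min_len: int, start: int = 0) -> int | None:
    """Index of the first run of True of length >= min_len (runs truncated by
    the end of the trace count if they reach it)."""
    n = len(mask)
    i = start
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if (j - i) >= min_len or j == n:
                return i
            i = j
        else:
            i += 1
    return None


def segment_movement(speed: np.ndarray,
                     config: SegmentationConfig,
                     sample_rate: float) -> tuple[int, int]:
    """Find (onset_idx, offset_idx) of the primary movement in a speed trace.

    Onset: first sample where speed exceeds ``onset_speed_fraction`` x PV and
    stays above for ``min_above_ms``.  Offset: first sample after the global
    peak where speed falls below the same threshold and stays below for
    ``min_above_ms`` (a shorter below-run is accepted if it reaches the end
    of the trace).  Guarantees onset < argmax(speed) <= offset.
    """
    speed = np.asarray(speed, dtype=float)
    pv = float(speed.max(initial=0.0))
    if pv <= 0:
        raise SegmentationError("flat speed trace", reason="no_movement")
    thr = config.onset_speed_fraction * pv
    k = max(1, int(round(config.min_above_ms / 1000.0 * sample_rate)))
    above = speed > thr
    peak = int(np.argmax(speed))

    onset = _first_run(above, k)
    if onset is None or onset > peak:
        raise SegmentationError("no sustained threshold crossing",
                                reason="no_movement")
    offset = _first_run(~above, k, start=peak + 1)
    if offset is None:
        raise SegmentationError("speed never settles after the peak",
                                reason="unfinished")
    return onset, offset


def extract_wrist_kinematics(trial: Trial,
                             role: str,
                             seg_config: SegmentationConfig | None = None,
                             ) -> KinematicSummary:
    """Extract MT, PV, TPV/MT, TPD/MT and path length for one role's wrist.

    PV is the speed maximum within [onset, offset]; peak deceleration is the
    minimum of the first derivative of scalar speed in (t_PV, t_offset] — a
    speed-profile landmark, not the norm of the 3D acceleration vector.
    """
    seg_config = seg_config or SegmentationConfig()
    wrist = trial.wrist(role)
    if wrist is None:
        raise ValueError(f"no wrist tracker for role {role!r}")
    speed = speed_profile(wrist)
    onset, offset = segment_movement(speed, seg_config, wrist.sample_rate)

    window = speed[onset:offset + 1]
    i_pv = onset + int(np.argmax(window))
    pv = float(speed[i_pv])
    n_window = offset - onset
    mt_ms = n_window / wrist.sample_rate * 1000.0

    accel = np.gradient(speed, wrist.dt)
    decel_slice = accel[i_pv + 1:offset + 1]
    if decel_slice.size == 0:
        raise SegmentationError("no samples after the velocity peak",
                                reason="no_movement")
    i_pd = i_pv + 1 + int(np.argmin(decel_slice))

    steps = np.diff(wrist.positions[onset:offset + 1], axis=0)
    path_length = float(np.linalg.norm(steps, axis=1).sum())

    return KinematicSummary(
        onset_idx=onset,
        offset_idx=offset,
        mt_ms=mt_ms,
        pv=pv,
        tpv_over_mt=(i_pv - onset) / n_window,
        tpd_over_mt=(i_pd - onset) / n_window,
        path_length=path_length,
    )


def digit_relative_pv(trial: Trial,
                      role: str,
                      seg_config: SegmentationConfig | None = None,
                      window: tuple[int, int] | None = None,
                      ) -> float | None:
    """Mean peak speed of the digits relative to the wrist (cm/s).

    Wrist position is subtracted from each digit position sample-wise, so the
    measure isolates digit motion from arm transport.  Each available digit
    contributes the maximum of its relative speed over the wrist's
    [onset, offset] window; the mean across available digits is returned, or
    ``None`` when no digit tracker is present (absence, not zero).
    """
    seg_config = seg_config or SegmentationConfig()
    wrist = trial.wrist(role)
    if wrist is None:
        raise ValueError(f"no wrist tracker for role {role!r}")
    if window is None:
        speed = speed_profile(wrist)
        window = segment_movement(speed, seg_config, wrist.sample_rate)
    onset, offset = window

    peaks = []
    for label in DIGIT_LABELS:
        digit = trial.series(role).get(label)
        if digit is None:
            continue
        if digit.n_samples != wrist.n_samples:
            raise ValueError(
                f"{role}/{label} length {digit.n_samples} does not match "
                f"wrist length {wrist.n_samples}"
            )
        rel = digit.with_positions(digit.positions - wrist.positions)
        rel_speed = speed_profile(rel)
        peaks.append(float(rel_speed[onset:offset + 1].max()))
    if not peaks:
        return None
    return float(np.mean(peaks))
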