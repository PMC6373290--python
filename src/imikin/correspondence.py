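"""Actor-imitator imitation-fidelity scoring by lagged cross-correlation.

For each tracker carried by both people, the scalar speed profiles of the two
primary movements (each clipped to its own onset-offset window) are compared
by Pearson correlation at every integer lag within a window of +/- the
difference of the two movement lengths.  The maximum r and its lag quantify
how faithfully, and with what temporal offset, the imitator reproduced the
actor's velocity profile.  r values are Fisher-transformed
(Z = 0.5 ln((1+r)/(1-r))) before parametric aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_trials import TRACKER_LABELS, Trial
from .kinematics import SegmentationConfig, segment_movement, speed_profile

log = logging.getLogger(__name__)

#: trackers per person; the alpha for per-tracker analyses is 0.05 divided by
#: this family size.
N_TRACKERS = len(TRACKER_LABELS)
MIN_OVERLAP = 3


class CorrelationError(RuntimeError):
    """The correlation is undefined at every admissible lag."""


@dataclass
class CorrespondenceResult:
    tracker: str
    r_max: float
    z_max: float
    lag_samples: int
    lag_ms: float
    lag_window: tuple[int, int]


def lag_window(actor_len: int, imit_len: int) -> tuple[int, int]:
    """Lag search window (-d, +d) with d the absolute length difference.

    E.g. actor 180 samples and imitator 240 samples give lags -60..+60 in
    1-sample steps; equal lengths give the single lag 0.
    """
    if actor_len <= 0 or imit_len <= 0:
        raise ValueError("trace lengths must be positive")
    d = abs(imit_len - actor_len)
    return (-d, d)


def max_lagged_correlation(actor_speed: np.ndarray,
                           imit_speed: np.ndarray,
                           ) -> tuple[float, int]:
    """Maximum Pearson correlation over the lag window, with its lag.

    Positive lag means the imitator's profile is shifted later than the
    actor's.  At each lag the correlation is computed over the overlapping
    aligned region only (no zero padding, which would bias r toward 0 at
    large lags).  Lags with overlap < 3 samples or zero variance on either
    side are skipped; ties are broken toward the smallest absolute lag.
    """
    a = np.asarray(actor_speed, dtype=float)
    b = np.asarray(imit_speed, dtype=float)
    na, nb = len(a), len(b)
    lo, hi = lag_window(na, nb)

    best_r = -np.inf
    best_lag: int | None = None
    # scanning by increasing |lag| makes the tie-break a strict comparison
    for lag in sorted(range(lo, hi + 1), key=lambda s: (abs(s), s)):
        t0 = max(0, -lag)
        t1 = min(na, nb - lag)
        if t1 - t0 < MIN_OVERLAP:
            continue
        x = a[t0:t1]
        y = b[t0 + lag:t1 + lag]
        if x.std() == 0.0 or y.std() == 0.0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    if best_lag is None:
        raise CorrelationError(
            "correlation undefined at every lag (zero variance or no overlap)"
        )
    return best_r, best_lag


def fisher_z(r: float) -> float:
    """Fisher r-to-Z transform, Z = 0.5 ln((1+r)/(1-r)); requires |r| < 1."""
    if abs(r) >= 1.0:
        raise ValueError(f"Fisher transform undefined for |r| >= 1 (r={r})")
    return 0.5 * float(np.log((1.0 + r) / (1.0 - r)))


def clamped_fisher_z(r: float, eps: float = 1e-9) -> float:
    """Fisher transform with |r| clamped below 1 (logged, for perfect
    correlations produced by noiseless or duplicated traces)."""
    if abs(r) >= 1.0:
        log.warning("clamping |r| = %g to %g for the Fisher transform",
                    abs(r), 1 - eps)
        r = np.sign(r) * (1.0 - eps)
    return fisher_z(r)


def score_trial(trial: Trial,
                seg_config: SegmentationConfig | None = None,
                ) -> list[CorrespondenceResult]:
    """One CorrespondenceResult per tracker present for both roles.

    Each role's movement window is taken from its own wrist segmentation and
    applied to all of that role's trackers, so every tracker of a person is
    scored over the same primary-movement interval.  Trackers present for one
    role only, or with degenerate (constant-speed) windows, are skipped with
    a log entry.
    """
    seg_config = seg_config or SegmentationConfig()
    windows: dict[str, tuple[int, int]] = {}
    for role in ("actor", "imitator"):
        wrist = trial.wrist(role)
        if wrist is None:
            raise ValueError(f"no wrist tracker for role {role!r}")
        windows[role] = segment_movement(
            speed_profile(wrist), seg_config, wrist.sample_rate)

    results: list[CorrespondenceResult] = []
    sample_rate = trial.wrist("actor").sample_rate
    for label in TRACKER_LABELS:
        a_series = trial.actor.get(label)
        i_series = trial.imitator.get(label)
        if a_series is None or i_series is None:
            if a_series is not None or i_series is not None:
                log.info("trial %s/%s: tracker %s present for one role only",
                         trial.participant_id, trial.gesture_id, label)
            continue
        a_on, a_off = windows["actor"]
        i_on, i_off = windows["imitator"]
        a_speed = speed_profile(a_series)[a_on:a_off + 1]
        i_speed = speed_profile(i_series)[i_on:i_off + 1]
        try:
            r_max, lag = max_lagged_correlation(a_speed, i_speed)
        except CorrelationError:
            log.info("trial %s/%s: correlation undefined for tracker %s",
                     trial.participant_id, trial.gesture_id, label)
            continue
        results.append(CorrespondenceResult(
            tracker=label,
            r_max=r_max,
            z_max=clamped_fisher_z(r_max),
            lag_samples=lag,
            lag_ms=lag * 1000.0 / sample_rate,
            lag_window=lag_window(len(a_speed), len(i_speed)),
        ))
    return results
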