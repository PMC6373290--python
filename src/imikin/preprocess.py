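"""Artifact despiking, zero-phase low-pass filtering, and trial exclusion.

Electromagnetic trackers occasionally emit single-sample position spikes.
These are detected on the double-differenced trace (successive first-order
differences applied twice, length n-2) as samples deviating more than a
configurable number of SDs from the within-trial mean of that trace, and
repaired by linear interpolation bridging from a few samples before to a few
samples after the spike.  The criterion is evaluated per coordinate axis; a
spike on any axis triggers replacement of that sample on all three axes,
because the artifact hits the sensor, not a single coordinate.

Filtering is a bidirectional (zero-phase, forward-backward) low-pass
Butterworth, 4th order at 12 Hz by default — each pass contributes the filter
once, so the effective magnitude response is the single-pass response squared
and the phase response is identically zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy import signal

from .io_trials import TrackerSeries, Trial

EXCLUSION_REASONS = (
    "too_short", "false_start", "unfinished", "missing_tracker",
    "pipeline_error",
)


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Despiking, filtering and exclusion-rule parameters.

    spike_sd_threshold : SD units on the double-differenced trace (default 3).
    interp_halfwidth : samples bridged on each side of a spike (default 3).
    filter_order, filter_cutoff : Butterworth order / cutoff Hz (4, 12).
    min_movement_ms : movements shorter than this exclude the trial (400).
    """

    spike_sd_threshold: float = 3.0
    interp_halfwidth: int = 3
    filter_order: int = 4
    filter_cutoff: float = 12.0
    min_movement_ms: float = 400.0

    def __post_init__(self) -> None:
        if min(self.spike_sd_threshold, self.interp_halfwidth,
               self.filter_order, self.filter_cutoff,
               self.min_movement_ms) <= 0:
            raise PreprocessError("all preprocessing thresholds must be > 0")

    def validate_rate(self, sample_rate: float) -> None:
        if self.filter_cutoff >= sample_rate / 2:
            raise PreprocessError(
                f"filter cutoff {self.filter_cutoff} Hz not below the Nyquist "
                f"frequency {sample_rate / 2} Hz"
            )


def despike(series: TrackerSeries,
            config: PreprocessConfig | None = None,
            ) -> tuple[TrackerSeries, int]:
    """Remove single-sample spikes; returns (cleaned series, spike count).

    The double-differenced trace element ``d2[j]`` is attributed to sample
    ``j + 1``.  Flagged samples are replaced, on all axes, by the straight
    line between the samples ``interp_halfwidth`` before and after the spike
    (clipped at the trace ends).  Output length equals input length.
    """
    config = config or PreprocessConfig()
    pos = series.positions
    n = pos.shape[0]
    h = config.interp_halfwidth
    if n <= 2 * h + 1:
        raise PreprocessError(
            f"series of {n} samples too short to despike (need > {2 * h + 1})"
        )

    d2 = np.diff(pos, n=2, axis=0)  # (n-2, 3)
    mu = d2.mean(axis=0)
    sd = d2.std(axis=0, ddof=1)
    # absolute floor keeps machine-precision residue on perfectly smooth
    # traces from registering as physical spikes
    limit = np.maximum(config.spike_sd_threshold * sd, 1e-9)
    outlier = np.abs(d2 - mu) > limit
    spike_samples = np.flatnonzero(outlier.any(axis=1)) + 1
    if spike_samples.size == 0:
        return series, 0

    clean = pos.copy()
    for s in spike_samples:
        lo = max(s - h, 0)
        hi = min(s + h, n - 1)
        span = hi - lo
        if span < 2:
            continue
        w = (np.arange(1, span) / span)[:, None]
        clean[lo + 1:hi] = (1 - w) * pos[lo] + w * pos[hi]
    return series.with_positions(clean), int(spike_samples.size)


def lowpass(series: TrackerSeries,
            config: PreprocessConfig | None = None) -> TrackerSeries:
    """Zero-phase Butterworth low-pass of each coordinate axis.

    Forward-backward application gives DC gain exactly 1 and no phase
    distortion; edges are handled by odd-reflection padding (scipy default,
    well above 3x the filter order).
    """
    config = config or PreprocessConfig()
    config.validate_rate(series.sample_rate)
    sos = signal.butter(config.filter_order, config.filter_cutoff,
                        btype="low", fs=series.sample_rate, output="sos")
    # default padlen for sosfiltfilt: 3 * (2 * n_sections + 1 - ...) ~ edges
    ntaps = 3 * (2 * sos.shape[0] + 1)
    if series.n_samples <= ntaps:
        raise PreprocessError(
            f"series of {series.n_samples} samples shorter than the filter "
            f"padding requirement ({ntaps})"
        )
    filtered = signal.sosfiltfilt(sos, series.positions, axis=0)
    return series.with_positions(filtered)


def preprocess_series(series: TrackerSeries,
                      config: PreprocessConfig | None = None,
                      ) -> tuple[TrackerSeries, int]:
    """Despike then filter one tracker series (despiking first, so the filter
    cannot smear spikes)."""
    cleaned, n_spikes = despike(series, config)
    return lowpass(cleaned, config), n_spikes


def preprocess_trial(trial: Trial,
                     config: PreprocessConfig | None = None,
                     ) -> tuple[Trial, int]:
    """Despike and filter every tracker series of both roles."""
    total = 0
    new_roles: dict[str, dict[str, TrackerSeries]] = {}
    for role in ("actor", "imitator"):
        out = {}
        for label, series in trial.series(role).items():
            cleaned, n_spikes = preprocess_series(series, config)
            out[label] = cleaned
            total += n_spikes
        new_roles[role] = out
    return (dataclasses.replace(trial, actor=new_roles["actor"],
                                imitator=new_roles["imitator"]), total)


def apply_exclusions(trial: Trial,
                     config: PreprocessConfig,
                     kinematics_hook: Callable,
                     ) -> Trial:
    """Apply the three movement-based exclusion rules to both roles.

    ``kinematics_hook(speed, sample_rate)`` must return ``(onset_idx,
    offset_idx)`` for a wrist speed trace or raise an exception whose
    ``reason`` attribute is ``"unfinished"`` when the movement never settles
    before the end of the recording.  A trial is excluded when either role
    moved for less than ``min_movement_ms``, started before its go tone, or
    failed to finish; a missing wrist tracker also excludes the trial.
    Sample data are never mutated — only the validity state changes.
    """
    from .kinematics import SegmentationError, speed_profile

    for role in ("actor", "imitator"):
        wrist = trial.wrist(role)
        if wrist is None:
            return trial.excluded("missing_tracker")
        speed = speed_profile(wrist)
        try:
            onset, offset = kinematics_hook(speed, wrist.sample_rate)
        except SegmentationError as err:
            reason = getattr(err, "reason", "unfinished")
            return trial.excluded(reason)
        mt_ms = (offset - onset) / wrist.sample_rate * 1000.0
        onset_ms = onset / wrist.sample_rate * 1000.0
        go_ms = trial.event_times.get(role, {}).get("go_ms", 0.0)
        if mt_ms < config.min_movement_ms:
            return trial.excluded("too_short")
        if onset_ms < go_ms:
            return trial.excluded("false_start")
    return trial


def drop_artifact_trackers(trial: Trial,
                           flags: Iterable[tuple[str, str]]) -> Trial:
    """Remove flagged (role, tracker) series from this trial only.

    Losing a wrist series for either role makes the trial unanalysable and
    excludes it outright.
    """
    flags = set(flags)
    if not flags:
        return trial
    actor = {k: v for k, v in trial.actor.items()
             if ("actor", k) not in flags}
    imitator = {k: v for k, v in trial.imitator.items()
                if ("imitator", k) not in flags}
    out = dataclasses.replace(trial, actor=actor, imitator=imitator)
    if "wrist" not in actor or "wrist" not in imitator:
        out = out.excluded("missing_tracker")
    return out
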