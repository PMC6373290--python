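"""Canonical trial file format, readers/writers, and dataset assembly.

A trial is stored as a long-format CSV with header ``sample,role,tracker,x,y,z``
(one row per sample per tracker, coordinates in cm, time implied by row order at
a fixed sample rate) plus a YAML sidecar holding the condition labels and tone
times.  One file pair per trial.  Orientation channels (azimuth, elevation,
roll), if present as extra columns, are stored but unused by the analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

TRACKER_LABELS = (
    "shoulder", "elbow", "wrist", "thumb", "index", "middle", "ring", "little",
)
DIGIT_LABELS = ("thumb", "index", "middle", "ring", "little")
ROLES = ("actor", "imitator")
SITES = ("pMTG", "vertex")
MEANINGS = ("meaningful", "meaningless")
EFFECTORS = ("hand", "finger")

#: column order of the canonical trial CSV
TRIAL_COLUMNS = ("sample", "role", "tracker", "x", "y", "z")

KINEMATIC_VARIABLES = ("PV", "MT", "TPV_MT", "TPD_MT", "mean_digit_PV")


class TrialFormatError(ValueError):
    """Raised when a trial file violates the canonical format."""


class IntegrityError(ValueError):
    """Raised when a table violates its uniqueness/completeness invariants."""


@dataclass
class TrackerSeries:
    """One tracker's uniformly sampled 3D position trace for one person.

    Parameters
    ----------
    label : str
        Anatomical landmark, one of :data:`TRACKER_LABELS`.
    role : str
        ``"actor"`` or ``"imitator"``.
    positions : ndarray, shape (n, 3)
        x, y, z position in cm; samples uniformly spaced at ``1/sample_rate``.
    sample_rate : float
        Sampling rate in Hz (electromagnetic tracking hardware runs at 240).
    orientation : ndarray, shape (n, 3), optional
        Azimuth/elevation/roll in degrees.  Stored, never analysed.
    """

    label: str
    role: str
    positions: np.ndarray
    sample_rate: float = 240.0
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label not in TRACKER_LABELS:
            raise TrialFormatError(f"unknown tracker label {self.label!r}")
        if self.role not in ROLES:
            raise TrialFormatError(f"unknown role {self.role!r}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrialFormatError(
                f"positions must be (n, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise TrialFormatError("a tracker series needs at least 2 samples")
        if not np.all(np.isfinite(self.positions)):
            bad = int(np.argwhere(~np.isfinite(self.positions))[0, 0])
            raise TrialFormatError(
                f"non-finite coordinate at sample {bad} "
                f"({self.role}/{self.label})"
            )
        if self.sample_rate <= 0:
            raise TrialFormatError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) / self.sample_rate * 1000.0

    def with_positions(self, positions: np.ndarray) -> "TrackerSeries":
        return dataclasses.replace(self, positions=positions)


@dataclass
class Trial:
    """Paired actor/imitator tracker sets with condition labels.

    ``event_times`` maps each role to ``{"go_ms": ..., "stop_ms": ...}``,
    offsets of the start/stop tones within that role's own recording epoch.
    """

    participant_id: str
    session_index: int
    site: str
    meaning: str
    effector: str
    gesture_id: str
    actor: dict[str, TrackerSeries] = field(default_factory=dict)
    imitator: dict[str, TrackerSeries] = field(default_factory=dict)
    event_times: dict[str, dict[str, float]] = field(default_factory=dict)
    validity: str = "valid"
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise TrialFormatError(f"unknown site {self.site!r}")
        if self.meaning not in MEANINGS:
            raise TrialFormatError(f"unknown meaning {self.meaning!r}")
        if self.effector not in EFFECTORS:
            raise TrialFormatError(f"unknown effector {self.effector!r}")

    def series(self, role: str) -> dict[str, TrackerSeries]:
        if role == "actor":
            return self.actor
        if role == "imitator":
            return self.imitator
        raise KeyError(role)

    def wrist(self, role: str) -> TrackerSeries | None:
        return self.series(role).get("wrist")

    @property
    def is_valid(self) -> bool:
        return self.validity == "valid"

    def excluded(self, reason: str) -> "Trial":
        """Return a copy marked excluded; sample data are never mutated."""
        return dataclasses.replace(
            self, validity="excluded", exclusion_reason=reason
        )

    def condition(self) -> tuple[str, str, str]:
        return (self.site, self.meaning, self.effector)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def read_trial(path: str | Path, sample_rate: float = 240.0) -> Trial:
    """Read a trial from the canonical CSV + YAML sidecar pair.

    Missing trackers are simply absent from the returned maps, never
    zero-filled.  Malformed headers, non-contiguous sample indices, unknown
    labels and non-finite coordinates all raise :class:`TrialFormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")

    meta_path = _sidecar_path(path)
    meta: dict = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    sample_rate = float(meta.get("sample_rate", sample_rate))

    actor: dict[str, TrackerSeries] = {}
    imitator: dict[str, TrackerSeries] = {}
    for (role, tracker), grp in df.groupby(["role", "tracker"], sort=False):
        grp = grp.sort_values("sample")
        idx = grp["sample"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise TrialFormatError(
                f"{path}: non-contiguous sample index for {role}/{tracker}"
            )
        pos = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)):
            row = grp.index[~np.all(np.isfinite(pos), axis=1)][0]
            raise TrialFormatError(
                f"{path}: non-finite coordinate on data row {row}"
            )
        try:
            series = TrackerSeries(
                label=str(tracker), role=str(role), positions=pos,
                sample_rate=sample_rate,
            )
        except TrialFormatError as err:
            raise TrialFormatError(f"{path}: {err}") from err
        (actor if role == "actor" else imitator)[str(tracker)] = series

    return Trial(
        participant_id=str(meta.get("participant_id", "P00")),
        session_index=int(meta.get("session_index", 0)),
        site=str(meta.get("site", "vertex")),
        meaning=str(meta.get("meaning", "meaningful")),
        effector=str(meta.get("effector", "hand")),
        gesture_id=str(meta.get("gesture_id", "g00")),
        actor=actor,
        imitator=imitator,
        event_times=meta.get("event_times", {}),
    )


def write_trial(trial: Trial, path: str | Path, decimals: int = 6) -> None:
    """Write a trial as canonical CSV + YAML sidecar.

    Coordinates are rounded to ``decimals`` places; a read/write round trip
    preserves values at that precision.
    """
    path = Path(path)
    frames = []
    sample_rate = 240.0
    for role in ROLES:
        for label in TRACKER_LABELS:
            series = trial.series(role).get(label)
            if series is None:
                continue
            sample_rate = series.sample_rate
            frames.append(pd.DataFrame({
                "sample": np.arange(series.n_samples),
                "role": role,
                "tracker": label,
                "x": series.positions[:, 0],
                "y": series.positions[:, 1],
                "z": series.positions[:, 2],
            }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=list(TRIAL_COLUMNS)))
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")

    meta = {
        "participant_id": trial.participant_id,
        "session_index": trial.session_index,
        "site": trial.site,
        "meaning": trial.meaning,
        "effector": trial.effector,
        "gesture_id": trial.gesture_id,
        "sample_rate": float(sample_rate),
        "event_times": trial.event_times,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


CONDITION_TABLE_COLUMNS = (
    "participant_id", "site", "meaning", "effector", "variable", "cell_mean",
)


def validate_condition_table(table: pd.DataFrame) -> None:
    """Check the participant x condition x variable uniqueness invariant."""
    missing = [c for c in CONDITION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise IntegrityError(f"condition table missing columns {missing}")
    keys = ["participant_id", "site", "meaning", "effector", "variable"]
    dup = table.duplicated(subset=keys)
    if dup.any():
        first = table.loc[dup, keys].iloc[0].to_dict()
        raise IntegrityError(f"duplicate condition row: {first}")


def write_condition_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write participant x condition cell means as CSV (re-readable losslessly)."""
    validate_condition_table(table)
    table.loc[:, CONDITION_TABLE_COLUMNS].to_csv(Path(path), index=False)


def read_condition_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(Path(path))
    validate_condition_table(table)
    return table


def load_dataset(directory: str | Path) -> Iterator[Trial]:
    """Yield trials from every canonical CSV in a directory, sorted by name."""
    directory = Path(directory)
    for csv_path in sorted(directory.glob("*.csv")):
        if csv_path.name == "ground_truth.csv":
            continue
        yield read_trial(csv_path)
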