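"""Boundary types and CSV I/O for head telemetry, vehicle traces, and trial records.

The on-disk dialect is the one produced by generic OpenVR-recorder style loggers:
a header row, a timestamp column in seconds, and three Euler rotation columns
(pitch, yaw, roll) in degrees.  Column names and units are remappable through
:class:`CsvDialect` so real exports can be ingested without code changes.

Sign convention (applied consistently to head and vehicle yaw): positive yaw is
a rightward turn, positive pitch is upward, positive roll is a rightward
ear-to-shoulder tilt.  Units are degrees and seconds at this boundary; a
dialect may declare radians, which are converted on read.

Missing cells are never imputed here: a NaN/empty angle cell is a
:class:`~vrheadmotion.errors.DataError`.  Dropped frames must appear as missing
rows (time gaps), which the kinematics stage detects and handles.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

AXES = ("pitch", "yaw", "roll")
SPEED_LEVELS = ("stationary", "slow", "fast")
LAP_SPEEDS = ("slow", "fast")

#: Ratings are verbal-anchored 1-20 integer scales (FMS-style for sickness).
RATING_MIN, RATING_MAX = 1, 20


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping for telemetry CSV files.

    ``units`` is ``"degrees"`` (default) or ``"radians"``; radian files are
    converted to degrees on read.
    """

    time: str = "time"
    pitch: str = "pitch"
    yaw: str = "yaw"
    roll: str = "roll"
    units: str = "degrees"

    def __post_init__(self) -> None:
        if self.units not in ("degrees", "radians"):
            raise FormatError(f"unknown angle units {self.units!r}")

    @property
    def angle_columns(self) -> dict[str, str]:
        return {"pitch": self.pitch, "yaw": self.yaw, "roll": self.roll}


DEFAULT_DIALECT = CsvDialect()
VEHICLE_DIALECT = CsvDialect(yaw="vehicle_yaw")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    return arr


def _check_time(t: np.ndarray) -> None:
    if t.size == 0:
        raise DataError("empty time axis")
    if not np.all(np.isfinite(t)):
        raise DataError("non-finite timestamp")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise DataError(f"timestamps not strictly increasing at row {bad}")


@dataclass
class HeadMotionTrace:
    """One participant-trial's head rotation time series.

    Angles are signed degrees.  After :func:`vrheadmotion.kinematics.center_and_unwrap`
    they are deviations from the lap-start forward-facing orientation (first
    sample zero on all axes); as read from disk they are raw headset angles.
    """

    participant_id: str
    trial_id: str
    t: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray
    centered: bool = False
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        _check_time(self.t)
        for axis in AXES:
            arr = _as_float_array(getattr(self, axis), axis)
            if arr.shape != self.t.shape:
                raise DataError(f"{axis} length {arr.size} != time length {self.t.size}")
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise DataError(f"non-finite {axis} value at row {bad}")
            setattr(self, axis, arr)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def sampling_rate(self) -> float:
        """Estimated rate in Hz ((n-1) / time span)."""
        if self.t.size < 2:
            raise DataError("cannot estimate a sampling rate from fewer than 2 samples")
        return (self.t.size - 1) / (self.t[-1] - self.t[0])

    @property
    def duration(self) -> float:
        """Nominal covered duration in seconds (span plus one sample period)."""
        return self.t.size / self.sampling_rate

    def channel(self, axis: str) -> np.ndarray:
        if axis not in AXES:
            raise KeyError(f"unknown axis {axis!r}; expected one of {AXES}")
        return getattr(self, axis)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        if self.t.size < 3:
            return True
        dt = np.diff(self.t)
        return bool(np.all(np.abs(dt - dt.mean()) <= rtol * dt.mean() + 1e-12))

    def replace(self, **kwargs) -> "HeadMotionTrace":
        return dataclasses.replace(self, **kwargs)

    def as_frame(self, dialect: CsvDialect = DEFAULT_DIALECT) -> pd.DataFrame:
        return pd.DataFrame(
            {
                dialect.time: self.t,
                dialect.pitch: self.pitch,
                dialect.yaw: self.yaw,
                dialect.roll: self.roll,
            }
        )


@dataclass
class VehicleTrace:
    """The lap's vehicle yaw/heading time series at a stated playback speed.

    The slow lap is the half-speed playback of the fast lap, so
    ``slow.yaw_at(t) == fast.yaw_at(t / 2)`` over a grid of identical duration.
    """

    lap_id: str
    speed_condition: str
    t: np.ndarray
    yaw: np.ndarray

    def __post_init__(self) -> None:
        if self.speed_condition not in LAP_SPEEDS:
            raise ValidationError(
                f"speed_condition must be one of {LAP_SPEEDS}, got {self.speed_condition!r}"
            )
        self.t = _as_float_array(self.t, "t")
        _check_time(self.t)
        self.yaw = _as_float_array(self.yaw, "vehicle_yaw")
        if self.yaw.shape != self.t.shape:
            raise DataError("vehicle yaw and time lengths differ")
        if not np.all(np.isfinite(self.yaw)):
            raise DataError("non-finite vehicle yaw value")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def sampling_rate(self) -> float:
        return (self.t.size - 1) / (self.t[-1] - self.t[0])


@dataclass
class TrialRecord:
    """Condition factors plus the five self-report measures for one trial.

    ``vection_onset`` / ``vection_duration`` (seconds) are recorded only when
    ``vection_magnitude >= 2``; a magnitude of 1 means no vection at all, so
    onset and duration are absent by construction.
    """

    participant_id: str
    experiment: int
    speed: str
    vection_magnitude: int
    sickness: int
    presence: int
    posture: str | None = None
    alignment: str | None = None
    direction: str | None = None
    vection_onset: float | None = None
    vection_duration: float | None = None
    trial_index: int | None = None

    def validate(self, lap_duration: float = 60.0) -> "TrialRecord":
        ctx = f"participant {self.participant_id} trial {self.trial_index}"
        if self.experiment not in (1, 2):
            raise ValidationError(f"{ctx}: experiment must be 1 or 2")
        if self.speed not in SPEED_LEVELS:
            raise ValidationError(f"{ctx}: unknown speed level {self.speed!r}")
        for name in ("vection_magnitude", "sickness", "presence"):
            value = getattr(self, name)
            if not float(value).is_integer():
                raise ValidationError(f"{ctx}: {name}={value} is not an integer rating")
            if not RATING_MIN <= value <= RATING_MAX:
                raise ValidationError(
                    f"{ctx}: {name}={value} outside [{RATING_MIN}, {RATING_MAX}]"
                )
        has_onset = self.vection_onset is not None
        has_duration = self.vection_duration is not None
        if self.vection_magnitude < 2:
            if has_onset or has_duration:
                raise ValidationError(
                    f"{ctx}: onset/duration present although vection magnitude is 1"
                )
        else:
            if not (has_onset and has_duration):
                raise ValidationError(
                    f"{ctx}: onset/duration missing although vection magnitude >= 2"
                )
            if self.vection_onset < 0 or self.vection_duration < 0:
                raise ValidationError(f"{ctx}: negative onset or duration")
            if self.vection_onset + self.vection_duration > lap_duration + 1e-9:
                raise ValidationError(
                    f"{ctx}: onset {self.vection_onset} + duration "
                    f"{self.vection_duration} exceeds the {lap_duration}-s lap"
                )
        return self

    @property
    def is_stationary(self) -> bool:
        return self.speed == "stationary"


# ---------------------------------------------------------------------------
# head-motion and vehicle CSV
# ---------------------------------------------------------------------------

def _read_telemetry_frame(path, columns: Mapping[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw = pd.read_csv(path)
    for role, name in columns.items():
        if name not in raw.columns:
            raise FormatError(f"{path.name}: missing column {name!r} (expected for {role})")
    out = {}
    for role, name in columns.items():
        col = pd.to_numeric(raw[name], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise DataError(
                f"{path.name}: non-numeric or missing value at row {int(bad[0])}, "
                f"column {name!r}"
            )
        out[role] = col.to_numpy(dtype=float)
    logger.info("read telemetry file %s (%d rows)", path, len(raw))
    return pd.DataFrame(out)


def read_head_motion_log(
    path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    participant_id: str = "",
    trial_id: str = "",
) -> HeadMotionTrace:
    """Read one per-trial head telemetry CSV into a validated trace (degrees)."""
    cols = {"t": dialect.time, **dialect.angle_columns}
    frame = _read_telemetry_frame(path, cols)
    angles = {ax: frame[ax].to_numpy() for ax in AXES}
    if dialect.units == "radians":
        angles = {ax: np.degrees(v) for ax, v in angles.items()}
    return HeadMotionTrace(
        participant_id=participant_id or Path(path).stem,
        trial_id=trial_id or Path(path).stem,
        t=frame["t"].to_numpy(),
        **angles,
    )


def write_head_motion_log(trace: HeadMotionTrace, path, dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    frame = trace.as_frame(dialect)
    if dialect.units == "radians":
        for name in (dialect.pitch, dialect.yaw, dialect.roll):
            frame[name] = np.radians(frame[name])
    frame.to_csv(path, index=False, float_format="%.12g")


def read_vehicle_trace(
    path,
    lap_id: str = "",
    speed_condition: str | None = None,
    dialect: CsvDialect = VEHICLE_DIALECT,
) -> VehicleTrace:
    """Read a per-lap vehicle yaw CSV.

    ``speed_condition`` defaults to a ``speed`` column in the file if present,
    otherwise it must be given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw = pd.read_csv(path)
    if speed_condition is None:
        if "speed" not in raw.columns:
            raise FormatError(f"{path.name}: no speed column and no speed_condition given")
        speed_condition = str(raw["speed"].iloc[0])
    frame = _read_telemetry_frame(path, {"t": dialect.time, "yaw": dialect.yaw})
    yaw = frame["yaw"].to_numpy()
    if dialect.units == "radians":
        yaw = np.degrees(yaw)
    return VehicleTrace(
        lap_id=lap_id or path.stem,
        speed_condition=speed_condition,
        t=frame["t"].to_numpy(),
        yaw=yaw,
    )


def write_vehicle_trace(trace: VehicleTrace, path, dialect: CsvDialect = VEHICLE_DIALECT) -> None:
    frame = pd.DataFrame(
        {
            dialect.time: trace.t,
            dialect.yaw: trace.yaw,
            "speed": trace.speed_condition,
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# trial records
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "trial_index",
    "posture",
    "alignment",
    "direction",
    "speed",
    "vection_magnitude",
    "vection_onset",
    "vection_duration",
    "sickness",
    "presence",
]


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def _opt_float(value, row: int, column: str) -> float | None:
    if value is None or value == "":
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise DataError(f"non-numeric value at row {row}, column {column!r}")
    if math.isnan(out):
        return None
    return out


def read_trial_records(path, lap_duration: float = 60.0) -> list[TrialRecord]:
    """Read a one-row-per-trial table, enforcing every TrialRecord invariant."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw = pd.read_csv(path)
    for name in TRIAL_COLUMNS:
        if name not in raw.columns:
            raise FormatError(f"{path.name}: missing column {name!r}")
    records = []
    for i, row in raw.iterrows():
        rating = {}
        for name in ("vection_magnitude", "sickness", "presence"):
            value = _opt_float(row[name], i, name)
            if value is None:
                raise DataError(f"{path.name}: missing rating at row {i}, column {name!r}")
            rating[name] = int(value) if float(value).is_integer() else value
        trial_index = _opt_float(row["trial_index"], i, "trial_index")
        record = TrialRecord(
            participant_id=str(row["participant_id"]),
            experiment=int(row["experiment"]),
            trial_index=None if trial_index is None else int(trial_index),
            posture=_opt_str(row["posture"]),
            alignment=_opt_str(row["alignment"]),
            direction=_opt_str(row["direction"]),
            speed=str(row["speed"]),
            vection_onset=_opt_float(row["vection_onset"], i, "vection_onset"),
            vection_duration=_opt_float(row["vection_duration"], i, "vection_duration"),
            **rating,
        )
        records.append(record.validate(lap_duration))
    logger.info("read %d trial records from %s", len(records), path)
    return records


def trial_records_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({name: getattr(r, name) for name in TRIAL_COLUMNS})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial_records(records: Sequence[TrialRecord], path) -> None:
    trial_records_frame(records).to_csv(path, index=False, float_format="%.12g")
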