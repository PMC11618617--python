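"""Trace preprocessing and the per-lap head-velocity summaries.

The preprocessing chain is: unwrap each Euler channel to remove +/-360 degree
jumps, re-reference it to the lap-start forward orientation (first sample = 0),
and linearly resample onto the uniform analysis grid (nominally 90 Hz x 60 s =
5400 points).  Velocity is summarized per axis as the mean absolute first
difference times the sampling rate, in degrees per second — no smoothing is
applied before differencing, so a constant channel scores exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GridError, InferenceError
from .io_formats import AXES, HeadMotionTrace

logger = logging.getLogger(__name__)

#: Gaps no longer than this are bridged by linear interpolation; longer gaps
#: flag the trial as excluded from head-motion analysis.  100 ms (9 frames at
#: 90 Hz) is well below the duration of any turn-driven head excursion, so
#: interpolation cannot fabricate a turn.
GAP_TOLERANCE_S = 0.100

#: A trace must cover at least this fraction of the requested duration.
MIN_COVERAGE = 0.95


@dataclass
class VelocitySummary:
    """Per-axis mean absolute head velocity (degrees/second) for one lap."""

    participant_id: str
    speed_condition: str
    pitch: float
    yaw: float
    roll: float

    def value(self, axis: str) -> float:
        if axis not in AXES:
            raise KeyError(axis)
        return getattr(self, axis)


def center_and_unwrap(trace: HeadMotionTrace) -> HeadMotionTrace:
    """Unwrap each channel (360-degree period) and zero it at the first sample.

    Continuity wins over range: if genuine cumulative rotation exceeds
    (-180, 180], the unwrapped deviation is kept rather than re-wrapped.
    Idempotent on already-centered traces.
    """
    if trace.n_samples == 0:
        raise DataError("cannot center an empty trace")
    channels = {}
    for axis in AXES:
        unwrapped = np.unwrap(trace.channel(axis), period=360.0)
        channels[axis] = unwrapped - unwrapped[0]
    return trace.replace(centered=True, **channels)


def resample_uniform(trace: HeadMotionTrace, rate: float, duration: float) -> HeadMotionTrace:
    """Linearly interpolate a trace onto the uniform grid round(rate*duration).

    Timestamp gaps above :data:`GAP_TOLERANCE_S` do not abort the resampling
    but mark the returned trace with ``excluded_reason`` so downstream stages
    can drop it from head-motion analysis with an exclusion count.
    """
    if trace.n_samples < 2:
        raise DataError("cannot resample a trace with fewer than 2 samples")
    span = trace.t[-1] - trace.t[0]
    if span < MIN_COVERAGE * duration - 1.0 / rate:
        raise DataError(
            f"trace covers {span:.3f}s of the requested {duration}s "
            f"(< {MIN_COVERAGE:.0%}); refusing to extrapolate"
        )
    n = int(round(rate * duration))
    grid = trace.t[0] + np.arange(n) / rate
    gaps = np.diff(trace.t)
    excluded = trace.excluded_reason
    if gaps.max() > GAP_TOLERANCE_S:
        at = float(trace.t[int(np.argmax(gaps))])
        excluded = f"gap of {gaps.max() * 1000:.0f} ms at t={at:.2f}s exceeds {GAP_TOLERANCE_S * 1000:.0f} ms"
        logger.warning(
            "trace %s/%s: %s; flagged excluded-from-head-motion-analysis",
            trace.participant_id,
            trace.trial_id,
            excluded,
        )
    channels = {
        axis: np.interp(grid, trace.t, trace.channel(axis)) for axis in AXES
    }
    return trace.replace(t=grid - grid[0], excluded_reason=excluded, **channels)


def mean_absolute_velocity(trace: HeadMotionTrace) -> VelocitySummary:
    """Mean absolute velocity per axis across the lap, degrees/second."""
    if trace.n_samples < 2:
        raise DataError("need at least 2 samples to compute a velocity")
    if not trace.is_uniform():
        raise GridError(
            "mean_absolute_velocity requires a uniform grid; run resample_uniform first"
        )
    rate = trace.sampling_rate
    values = {
        axis: float(np.mean(np.abs(np.diff(trace.channel(axis)))) * rate) for axis in AXES
    }
    speed = getattr(trace, "speed_condition", None) or _speed_from_trial_id(trace.trial_id)
    return VelocitySummary(
        participant_id=trace.participant_id, speed_condition=speed, **values
    )


def _speed_from_trial_id(trial_id: str) -> str:
    for speed in ("slow", "fast"):
        if speed in trial_id:
            return speed
    return "unknown"


def velocity_frame(summaries) -> pd.DataFrame:
    """Long-format table keyed by participant x speed x axis."""
    rows = []
    for s in summaries:
        for axis in AXES:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "speed_condition": s.speed_condition,
                    "axis": axis,
                    "mean_abs_velocity": s.value(axis),
                }
            )
    return pd.DataFrame(rows)


def compare_axes(summaries, speed_condition: str) -> pd.DataFrame:
    """Paired t-tests of yaw vs pitch and yaw vs roll velocities at one speed.

    Zero-variance nonzero differences are reported with ``degenerate=True``
    rather than an infinite t statistic; identically zero differences give
    t = 0, p = 1.
    """
    rows = [s for s in summaries if s.speed_condition == speed_condition]
    if len(rows) < 2:
        raise InferenceError(
            f"paired axis comparison at speed {speed_condition!r} needs n >= 2, got {len(rows)}"
        )
    out = []
    yaw = np.array([s.yaw for s in rows])
    for other in ("pitch", "roll"):
        values = np.array([s.value(other) for s in rows])
        diff = yaw - values
        n = diff.size
        sd = diff.std(ddof=1)
        degenerate = False
        if sd == 0.0:
            degenerate = not np.allclose(diff, 0.0)
            t = 0.0
            p = 1.0
        else:
            t, p = stats.ttest_rel(yaw, values)
        out.append(
            {
                "speed_condition": speed_condition,
                "comparison": f"yaw_vs_{other}",
                "n": n,
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "df": n - 1,
                "p": float(p),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(out)
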