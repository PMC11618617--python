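"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from vrheadmotion.io_formats import HeadMotionTrace, VehicleTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(
    yaw,
    pitch=None,
    roll=None,
    rate: float = 90.0,
    participant_id: str = "p0",
    trial_id: str = "t0",
) -> HeadMotionTrace:
    """Build a uniform-grid trace from channel arrays (defaults: zeros)."""
    yaw = np.asarray(yaw, dtype=float)
    n = yaw.size
    return HeadMotionTrace(
        participant_id=participant_id,
        trial_id=trial_id,
        t=np.arange(n) / rate,
        yaw=yaw,
        pitch=np.zeros(n) if pitch is None else np.asarray(pitch, dtype=float),
        roll=np.zeros(n) if roll is None else np.asarray(roll, dtype=float),
    )


def make_vehicle(yaw, rate: float = 90.0, speed: str = "fast") -> VehicleTrace:
    yaw = np.asarray(yaw, dtype=float)
    return VehicleTrace(
        lap_id="lap", speed_condition=speed, t=np.arange(yaw.size) / rate, yaw=yaw
    )
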