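"""Signed head-to-vehicle lag estimation (anticipatory steering analysis).

For every candidate lag d on a symmetric grid, the Pearson correlation between
head yaw at time t and vehicle yaw at time t - d is computed over the
overlapping region (truncation, not padding: padding would bias r toward zero
asymmetrically).  The returned lag maximizes r; *negative lags mean the head
leads the vehicle*, i.e. anticipatory head turns.  Ties at the peak are broken
toward the smallest |lag|, which is conservative against over-claiming
anticipation.

The default grid spans +/-2000 ms at one-sample resolution (~11.1 ms at
90 Hz): it brackets sub-second anticipation generously while keeping the
overlap at >= 96% of a 60-s lap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, GridError, InferenceError
from .io_formats import HeadMotionTrace, VehicleTrace

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG_MS = 2000.0


@dataclass
class LagEstimate:
    """Argmax-correlation lag for one head trace against the vehicle trace."""

    participant_id: str
    speed_condition: str
    lag_ms: float  # negative = head leads vehicle
    peak_r: float
    max_lag_ms: float
    step_ms: float
    n_overlap: int
    r_at_zero: float | None = None
    n_lags_skipped: int = 0


@dataclass
class LagProfile:
    """Cohort location/spread summary of per-participant lag estimates."""

    n: int
    median_ms: float
    q1_ms: float
    q3_ms: float
    bin_edges_ms: np.ndarray
    bin_counts: np.ndarray

    @property
    def iqr_ms(self) -> float:
        return self.q3_ms - self.q1_ms


def _corr_at_shift(head: np.ndarray, vehicle: np.ndarray, m: int) -> tuple[float | None, int]:
    """Pearson r of pairs (head[i], vehicle[i-m]) over the overlap; None if degenerate."""
    n = head.size
    if m >= 0:
        h, v = head[m:], vehicle[: n - m]
    else:
        h, v = head[: n + m], vehicle[-m:]
    if h.size < 3:
        return None, h.size
    hs, vs = h.std(), v.std()
    if hs == 0.0 or vs == 0.0:
        return None, h.size
    r = float(np.mean((h - h.mean()) * (v - v.mean())) / (hs * vs))
    return r, h.size


def estimate_lag(
    head: HeadMotionTrace,
    vehicle: VehicleTrace,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    step_ms: float | None = None,
    axis: str = "yaw",
) -> LagEstimate:
    """Brute-force argmax of Pearson r over the signed lag grid.

    ``step_ms`` must be an integer multiple of the sample period; it defaults
    to exactly one sample.  Lags whose overlap has zero variance are skipped
    with a log entry; if every lag is skipped an InferenceError is raised.
    """
    y = head.channel(axis)
    v = vehicle.yaw
    if y.shape != v.shape or not np.allclose(head.t, vehicle.t, atol=1e-9):
        raise GridError("head and vehicle traces must share one uniform grid")
    if not head.is_uniform():
        raise GridError("estimate_lag requires a uniform grid; resample first")
    rate = head.sampling_rate
    period_ms = 1000.0 / rate
    if step_ms is None:
        step = 1
        step_ms = period_ms
    else:
        step = step_ms / period_ms
        if abs(step - round(step)) > 1e-6:
            raise ConfigurationError(
                f"step {step_ms} ms is not an integer multiple of the "
                f"{period_ms:.3f} ms sample period"
            )
        step = int(round(step))
    lap_ms = 1000.0 * head.n_samples / rate
    if max_lag_ms >= lap_ms / 2:
        raise ConfigurationError(
            f"max lag {max_lag_ms} ms must be below half the lap ({lap_ms / 2:.0f} ms)"
        )
    max_shift = int(max_lag_ms / period_ms)
    shifts = np.arange(-max_shift, max_shift + 1, step)

    best = None  # (r, |lag|, lag, m, overlap)
    r_at_zero = None
    skipped = 0
    for m in shifts:
        r, overlap = _corr_at_shift(y, v, int(m))
        if r is None:
            skipped += 1
            continue
        lag_ms = m * period_ms
        if m == 0:
            r_at_zero = r
        key = (-r, abs(lag_ms), lag_ms)
        if best is None or key < best[0]:
            best = (key, lag_ms, r, overlap)
    if skipped:
        logger.info(
            "estimate_lag %s/%s: skipped %d degenerate lags",
            head.participant_id,
            head.trial_id,
            skipped,
        )
    if best is None:
        raise InferenceError("every candidate lag had a zero-variance overlap")
    _, lag_ms, peak_r, overlap = best
    return LagEstimate(
        participant_id=head.participant_id,
        speed_condition=vehicle.speed_condition,
        lag_ms=float(lag_ms),
        peak_r=peak_r,
        max_lag_ms=max_lag_ms,
        step_ms=float(step_ms),
        n_overlap=overlap,
        r_at_zero=r_at_zero,
        n_lags_skipped=skipped,
    )


def estimate_lag_median_trace(
    traces: Sequence[HeadMotionTrace],
    vehicle: VehicleTrace,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    step_ms: float | None = None,
    axis: str = "yaw",
) -> LagEstimate:
    """Pooled-mode lag: estimate on the pointwise median head trace of a cohort."""
    if not traces:
        raise InferenceError("no traces given")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, atol=1e-9):
            raise GridError("cohort traces must share one grid")
    med = np.median(np.stack([tr.channel(axis) for tr in traces]), axis=0)
    pooled = traces[0].replace(
        participant_id="cohort-median", trial_id="pooled", **{axis: med}
    )
    return estimate_lag(pooled, vehicle, max_lag_ms=max_lag_ms, step_ms=step_ms, axis=axis)


def cohort_lag_profile(
    estimates: Sequence[LagEstimate], bin_width_ms: float = 100.0
) -> LagProfile:
    """Median, IQR, and histogram-ready bins of per-participant lags."""
    if not estimates:
        raise InferenceError("cohort_lag_profile needs at least one estimate")
    lags = np.array([e.lag_ms for e in estimates], dtype=float)
    lo = np.floor(lags.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(lags.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts, edges = np.histogram(lags, bins=edges)
    return LagProfile(
        n=lags.size,
        median_ms=float(np.median(lags)),
        q1_ms=float(np.percentile(lags, 25)),
        q3_ms=float(np.percentile(lags, 75)),
        bin_edges_ms=edges,
        bin_counts=counts,
    )
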