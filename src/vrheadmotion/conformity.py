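"""Conformity of head motion to the cohort's normative (median) trajectory.

A participant's conformity score on one axis and lap is the Pearson
correlation between their head-deviation time series and the pointwise
*median* series of every other participant (leave-one-out), computed across
all grid points of the lap.  The median reference is used instead of the mean
to limit the influence of outliers.  Pearson correlation is location- and
positive-scale-invariant, so centering conventions do not change the score.

Even-count medians are the mean of the two central values.  Constant
(zero-variance) traces cannot be scored; they are flagged degenerate and
excluded from cohort summaries with a logged count rather than scored 0,
since 0 would assert "uncorrelated" without evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, InferenceError
from .io_formats import AXES, HeadMotionTrace

logger = logging.getLogger(__name__)


@dataclass
class ConformityScore:
    """One participant x lap x axis correlation against the LOO median."""

    participant_id: str
    axis: str
    speed_condition: str
    r: float
    n_points: int
    degenerate: bool = False


@dataclass
class ConformitySummary:
    """Cohort summary of conformity scores: mean, SD, one-sample t against 0."""

    axis: str
    speed_condition: str
    n: int
    mean_r: float
    sd: float
    t: float
    df: int
    p: float
    n_degenerate_excluded: int = 0


def _trace_matrix(traces: Sequence[HeadMotionTrace], axis: str) -> tuple[np.ndarray, list[str]]:
    if axis not in AXES:
        raise KeyError(f"unknown axis {axis!r}")
    if len(traces) < 3:
        raise DataError(
            f"leave-one-out median conformity needs >= 3 participants, got {len(traces)}"
        )
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, atol=1e-9):
            raise DataError(
                f"traces are not on a shared grid (participant {tr.participant_id})"
            )
    X = np.stack([tr.channel(axis) for tr in traces])
    return X, [tr.participant_id for tr in traces]


def loo_median_matrix(X: np.ndarray) -> np.ndarray:
    """Row i of the result is the pointwise median of all rows except i.

    Sort once per column, then each leave-one-out median is read off the order
    statistics: removing the value of rank k shifts the central positions by
    one when k is below them.  O(n T log n) overall instead of O(n^2 T log n).
    """
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if n < 2:
        raise DataError("leave-one-out median needs at least 2 rows")
    S = np.sort(X, axis=0)
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[:, None] * np.ones((1, T), dtype=int), axis=0)
    m = n - 1  # rows remaining after exclusion
    p_lo, p_hi = (m - 1) // 2, m // 2
    out = np.empty_like(X)
    cols = np.arange(T)
    for i in range(n):
        r = ranks[i]
        lo = S[(p_lo + (p_lo >= r).astype(int)), cols]
        hi = S[(p_hi + (p_hi >= r).astype(int)), cols]
        out[i] = 0.5 * (lo + hi)
    return out


def loo_median_trajectory(
    traces: Sequence[HeadMotionTrace], target_participant: str, axis: str
) -> np.ndarray:
    """Pointwise median trajectory over every participant except the target."""
    X, ids = _trace_matrix(traces, axis)
    if target_participant not in ids:
        raise DataError(f"target participant {target_participant!r} not in cohort")
    i = ids.index(target_participant)
    return loo_median_matrix(X)[i]


def conformity_score(
    trace: HeadMotionTrace,
    reference: np.ndarray,
    axis: str,
    speed_condition: str = "unknown",
) -> ConformityScore:
    """Pearson correlation of one trace's axis channel with a reference trajectory."""
    y = trace.channel(axis)
    reference = np.asarray(reference, dtype=float)
    if y.shape != reference.shape:
        raise DataError(
            f"trace ({y.size} points) and reference ({reference.size}) differ in length"
        )
    if np.std(y) == 0.0 or np.std(reference) == 0.0:
        logger.warning(
            "degenerate conformity score for %s (%s/%s): zero variance",
            trace.participant_id,
            axis,
            speed_condition,
        )
        return ConformityScore(
            participant_id=trace.participant_id,
            axis=axis,
            speed_condition=speed_condition,
            r=float("nan"),
            n_points=y.size,
            degenerate=True,
        )
    r = float(np.corrcoef(y, reference)[0, 1])
    return ConformityScore(
        participant_id=trace.participant_id,
        axis=axis,
        speed_condition=speed_condition,
        r=r,
        n_points=y.size,
    )


def cohort_conformity(
    traces: Sequence[HeadMotionTrace], axis: str, speed_condition: str
) -> list[ConformityScore]:
    """Leave-one-out conformity scores for every participant in one cell."""
    X, ids = _trace_matrix(traces, axis)
    refs = loo_median_matrix(X)
    scores = []
    for i, pid in enumerate(ids):
        scores.append(
            conformity_score(traces[i], refs[i], axis, speed_condition)
        )
    return scores


def fisher_mean(rs: Sequence[float]) -> float:
    """Average correlations via Fisher z (used when a cell holds several laps)."""
    z = np.arctanh(np.clip(np.asarray(rs, dtype=float), -1 + 1e-15, 1 - 1e-15))
    return float(np.tanh(z.mean()))


def summarize_conformity(
    scores: Sequence[ConformityScore],
    axis: str | None = None,
    speed_condition: str | None = None,
) -> ConformitySummary:
    """Mean, SD, and a two-tailed one-sample t-test of the scores against zero."""
    pool = [
        s
        for s in scores
        if (axis is None or s.axis == axis)
        and (speed_condition is None or s.speed_condition == speed_condition)
    ]
    degenerate = [s for s in pool if s.degenerate]
    valid = [s.r for s in pool if not s.degenerate]
    if degenerate:
        logger.info(
            "summarize_conformity: excluding %d degenerate scores (%s/%s)",
            len(degenerate),
            axis,
            speed_condition,
        )
    if len(valid) < 2:
        raise InferenceError(
            f"conformity summary needs >= 2 non-degenerate scores, got {len(valid)}"
        )
    arr = np.asarray(valid)
    if arr.std(ddof=1) == 0.0:
        # all scores identical: t is 0 when the common value is 0, else undefined
        t = 0.0 if arr[0] == 0.0 else float("inf")
        p = 1.0 if arr[0] == 0.0 else 0.0
    else:
        t, p = stats.ttest_1samp(arr, 0.0)
    return ConformitySummary(
        axis=axis or pool[0].axis,
        speed_condition=speed_condition or pool[0].speed_condition,
        n=arr.size,
        mean_r=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        t=float(t),
        df=arr.size - 1,
        p=float(p),
        n_degenerate_excluded=len(degenerate),
    )
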