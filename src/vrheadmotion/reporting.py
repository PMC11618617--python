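"""End-to-end pipeline orchestration and report emission.

``run_pipeline`` executes ingest (or synthesis) -> preprocessing -> velocity
-> conformity -> lag -> inferential statistics -> report, writing every table
as CSV, a plain-text report shaped like the study's summary tables, the
trajectory summary data behind the figures, and a run log with seed, library
versions, and exclusion counts.  The bundle is a pure function of
(input data, config, seed): identical runs produce byte-identical CSVs.
Figures are emitted as image files *plus* their underlying CSV, so no
downstream consumer ever needs to read pixels.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import cohort_configs, load_config
from .conformity import ConformityScore, cohort_conformity, summarize_conformity
from .errors import DataError, InferenceError, VRHeadMotionError
from .inferential_stats import (
    analysis_condition_mask,
    conformity_association_table,
    rating_intercorrelation,
    rm_anova,
)
from .io_formats import (
    AXES,
    LAP_SPEEDS,
    HeadMotionTrace,
    VehicleTrace,
    read_head_motion_log,
    read_trial_records,
    read_vehicle_trace,
    trial_records_frame,
)
from .kinematics import (
    center_and_unwrap,
    compare_axes,
    mean_absolute_velocity,
    resample_uniform,
    velocity_frame,
)
from .lag_analysis import (
    cohort_lag_profile,
    estimate_lag,
    estimate_lag_median_trace,
)
from .synthetic_cohort import Cohort, generate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass
class TrajectorySummary:
    """Pointwise mean deviation and SEM across a cohort, one axis x speed."""

    axis: str
    speed_condition: str
    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "mean_deviation": self.mean, "sem": self.sem}
        )


def trajectory_summary(
    traces: Sequence[HeadMotionTrace], axis: str, speed_condition: str
) -> TrajectorySummary:
    """Grand-mean trajectory with its standard error (sd/sqrt(n)) per time point."""
    if len(traces) < 2:
        raise InferenceError("trajectory summary needs >= 2 traces")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, atol=1e-9):
            raise DataError("trajectory summary requires a shared grid")
    X = np.stack([tr.channel(axis) for tr in traces])
    return TrajectorySummary(
        axis=axis,
        speed_condition=speed_condition,
        t=t0.copy(),
        mean=X.mean(axis=0),
        sem=X.std(axis=0, ddof=1) / np.sqrt(X.shape[0]),
        n=X.shape[0],
    )


# ---------------------------------------------------------------------------
# study container (synthetic or on-disk)
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Unified in-memory view of a study: records, vehicle laps, head traces."""

    records: pd.DataFrame
    vehicle: dict[str, VehicleTrace]
    traces: dict[tuple[str, int], HeadMotionTrace]
    trace_speed: dict[tuple[str, int], str]

    @classmethod
    def from_cohorts(cls, cohorts: Sequence[Cohort]) -> "StudyData":
        records = pd.concat(
            [trial_records_frame(c.records) for c in cohorts], ignore_index=True
        )
        vehicle = cohorts[0].vehicle
        traces: dict[tuple[str, int], HeadMotionTrace] = {}
        speeds: dict[tuple[str, int], str] = {}
        for c in cohorts:
            for (pid, idx), trace in c.head_traces.items():
                traces[(pid, idx)] = trace
                speeds[(pid, idx)] = next(
                    t.speed for t in c.schedules[pid] if t.trial_index == idx
                )
        return cls(records=records, vehicle=vehicle, traces=traces, trace_speed=speeds)

    @classmethod
    def from_dir(cls, data_dir, lap_duration: float = 60.0) -> "StudyData":
        """Read the on-disk layout written by ``synthetic_cohort.write_cohort``.

        Only ``trials.csv``, ``vehicle_*.csv``, ``head_index.csv`` and the head
        CSVs are consumed; a ``ground_truth.json`` sidecar, if present, is
        deliberately ignored.
        """
        root = Path(data_dir)
        records = trial_records_frame(read_trial_records(root / "trials.csv", lap_duration))
        vehicle = {
            speed: read_vehicle_trace(root / f"vehicle_{speed}.csv", speed_condition=speed)
            for speed in LAP_SPEEDS
        }
        index = pd.read_csv(root / "head_index.csv")
        traces: dict[tuple[str, int], HeadMotionTrace] = {}
        speeds: dict[tuple[str, int], str] = {}
        for row in index.itertuples():
            key = (str(row.participant_id), int(row.trial_index))
            traces[key] = read_head_motion_log(
                root / row.path,
                participant_id=key[0],
                trial_id=f"t{key[1]:02d}_{row.speed_condition}",
            )
            speeds[key] = str(row.speed_condition)
        return cls(records=records, vehicle=vehicle, traces=traces, trace_speed=speeds)


@dataclass
class PipelineResult:
    out_dir: Path
    velocity: pd.DataFrame
    velocity_tests: pd.DataFrame
    conformity_scores: list[ConformityScore]
    conformity_summary: pd.DataFrame
    lag_estimates: pd.DataFrame
    lag_profile: pd.DataFrame
    anova: dict[int, dict[str, pd.DataFrame]]
    association: pd.DataFrame
    correlations: pd.DataFrame
    trajectories: list[TrajectorySummary]
    n_excluded: int


@contextmanager
def _stage(name: str):
    logger.info("stage=%s start", name)
    try:
        yield
    except VRHeadMotionError as err:
        raise type(err)(f"[stage {name}] {err}") from err
    logger.info("stage=%s done", name)


def _analysis_keys(records: pd.DataFrame) -> dict[tuple[str, int], str]:
    """(participant, trial_index) -> speed for upright/aligned/forward laps."""
    frame = records[analysis_condition_mask(records)]
    return {
        (str(r.participant_id), int(r.trial_index)): str(r.speed)
        for r in frame.itertuples()
    }


def run_pipeline(config, out_dir, seed: int | None = None) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    (out / "figures").mkdir(parents=True, exist_ok=True)
    rate = float(cfg["io"]["rate"])
    lap = float(cfg["io"]["lap_duration"])
    alpha = float(cfg["analysis"]["alpha"])
    run_seed = int(cfg["synthetic"]["seed"] if seed is None else seed)
    log_lines = [
        f"vrheadmotion {__version__}",
        f"numpy {np.__version__} pandas {pd.__version__}",
        f"seed {run_seed}",
    ]

    with _stage("ingest"):
        if cfg["io"]["data_dir"]:
            study = StudyData.from_dir(cfg["io"]["data_dir"], lap)
            log_lines.append(f"ingest data_dir={cfg['io']['data_dir']}")
        else:
            cohorts = [generate_cohort(c) for c in cohort_configs(cfg, run_seed)]
            study = StudyData.from_cohorts(cohorts)
            log_lines.append(
                "ingest synthetic n=" + ",".join(str(c.config.n_participants) for c in cohorts)
            )
        log_lines.append(
            f"ingest traces={len(study.traces)} records={len(study.records)}"
        )

    with _stage("preprocess"):
        processed: dict[tuple[str, int], HeadMotionTrace] = {}
        n_excluded = 0
        for key, trace in study.traces.items():
            resampled = resample_uniform(center_and_unwrap(trace), rate, lap)
            if resampled.excluded_reason:
                n_excluded += 1
                continue
            processed[key] = resampled
        analysis_speed = _analysis_keys(study.records)
        by_speed: dict[str, list[HeadMotionTrace]] = {s: [] for s in LAP_SPEEDS}
        for key, trace in sorted(processed.items()):
            if key in analysis_speed:
                by_speed[analysis_speed[key]].append(trace)
        log_lines.append(
            f"preprocess in={len(study.traces)} out={len(processed)} excluded={n_excluded}"
        )

    with _stage("velocity"):
        summaries = []
        for speed in LAP_SPEEDS:
            for trace in by_speed[speed]:
                s = mean_absolute_velocity(trace)
                s.speed_condition = speed
                summaries.append(s)
        vel = velocity_frame(summaries)
        vel_tests = pd.concat(
            [compare_axes(summaries, speed) for speed in LAP_SPEEDS], ignore_index=True
        )
        log_lines.append(f"velocity laps={len(summaries)}")

    with _stage("conformity"):
        scores: list[ConformityScore] = []
        summary_rows = []
        for axis in AXES:
            for speed in LAP_SPEEDS:
                cell = cohort_conformity(by_speed[speed], axis, speed)
                scores.extend(cell)
                s = summarize_conformity(cell, axis, speed)
                summary_rows.append(vars(s))
        conf_summary = pd.DataFrame(summary_rows)
        log_lines.append(
            f"conformity scores={len(scores)} "
            f"degenerate={sum(s.degenerate for s in scores)}"
        )

    with _stage("lag"):
        max_lag = float(cfg["analysis"]["max_lag_ms"])
        lag_rows = []
        for speed in LAP_SPEEDS:
            vehicle = study.vehicle[speed]
            if not np.allclose(vehicle.t, vehicle.t[0] + np.arange(vehicle.n_samples) / rate):
                raise DataError("vehicle trace is not on the analysis grid")
            for trace in by_speed[speed]:
                est = estimate_lag(trace, vehicle, max_lag_ms=max_lag)
                lag_rows.append(vars(est))
            pooled = estimate_lag_median_trace(by_speed[speed], vehicle, max_lag_ms=max_lag)
            pooled_row = vars(pooled)
            lag_rows.append(pooled_row)
        lag_df = pd.DataFrame(lag_rows)
        individual = lag_df[lag_df.participant_id != "cohort-median"]
        profiles = []
        for speed in LAP_SPEEDS:
            prof = cohort_lag_profile(
                [e for e in _as_estimates(individual) if e.speed_condition == speed]
            )
            profiles.append(
                {
                    "speed_condition": speed,
                    "n": prof.n,
                    "median_ms": prof.median_ms,
                    "q1_ms": prof.q1_ms,
                    "q3_ms": prof.q3_ms,
                    "iqr_ms": prof.iqr_ms,
                }
            )
        overall = cohort_lag_profile(list(_as_estimates(individual)))
        profiles.append(
            {
                "speed_condition": "pooled",
                "n": overall.n,
                "median_ms": overall.median_ms,
                "q1_ms": overall.q1_ms,
                "q3_ms": overall.q3_ms,
                "iqr_ms": overall.iqr_ms,
            }
        )
        profile_df = pd.DataFrame(profiles)
        log_lines.append(f"lag estimates={len(individual)} pooled_median={overall.median_ms:.1f}ms")

    with _stage("stats"):
        records = study.records
        laps = records[records.speed.isin(LAP_SPEEDS)]
        anova: dict[int, dict[str, pd.DataFrame]] = {}
        for experiment, within in ((1, ["posture", "alignment", "speed"]), (2, ["direction", "speed"])):
            sub = laps[laps.experiment == experiment]
            if sub.empty:
                continue
            anova[experiment] = {
                dv: rm_anova(sub, dv, within=within)
                for dv in ("vection_magnitude", "sickness", "presence")
            }
        association = conformity_association_table(scores, records, alpha=alpha)
        corr_rows = []
        for experiment in sorted(laps.experiment.unique()):
            for mx, my in (
                ("vection_magnitude", "presence"),
                ("vection_magnitude", "sickness"),
                ("sickness", "presence"),
            ):
                res = rating_intercorrelation(records, mx, my, experiment=int(experiment))
                corr_rows.append(
                    {
                        "experiment": int(experiment),
                        "measure_x": mx,
                        "measure_y": my,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                    }
                )
        corr_df = pd.DataFrame(corr_rows)
        log_lines.append(f"stats anova_experiments={sorted(anova)} association_rows={len(association)}")

    with _stage("report"):
        trajectories = [
            trajectory_summary(by_speed[speed], axis, speed)
            for axis in AXES
            for speed in LAP_SPEEDS
        ]
        _write_csvs(
            out,
            vel,
            vel_tests,
            scores,
            conf_summary,
            lag_df,
            profile_df,
            anova,
            association,
            corr_df,
            trajectories,
        )
        report_text = _render_report(
            conf_summary, association, profile_df, vel_tests, corr_df, alpha
        )
        (out / "report.txt").write_text(report_text)
        if cfg["report"]["figures"]:
            _render_figures(out / "figures", trajectories, conf_summary, individual)
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        out_dir=out,
        velocity=vel,
        velocity_tests=vel_tests,
        conformity_scores=scores,
        conformity_summary=conf_summary,
        lag_estimates=lag_df,
        lag_profile=profile_df,
        anova=anova,
        association=association,
        correlations=corr_df,
        trajectories=trajectories,
        n_excluded=n_excluded,
    )


def _as_estimates(frame: pd.DataFrame):
    from .lag_analysis import LagEstimate

    for row in frame.itertuples(index=False):
        yield LagEstimate(
            participant_id=row.participant_id,
            speed_condition=row.speed_condition,
            lag_ms=row.lag_ms,
            peak_r=row.peak_r,
            max_lag_ms=row.max_lag_ms,
            step_ms=row.step_ms,
            n_overlap=row.n_overlap,
        )


def _write_csvs(
    out: Path,
    vel: pd.DataFrame,
    vel_tests: pd.DataFrame,
    scores: list[ConformityScore],
    conf_summary: pd.DataFrame,
    lag_df: pd.DataFrame,
    profile_df: pd.DataFrame,
    anova: Mapping[int, Mapping[str, pd.DataFrame]],
    association: pd.DataFrame,
    corr_df: pd.DataFrame,
    trajectories: Sequence[TrajectorySummary],
) -> None:
    opts = dict(index=False, float_format=_FLOAT_FORMAT)
    vel.to_csv(out / "velocity.csv", **opts)
    vel_tests.to_csv(out / "velocity_tests.csv", **opts)
    pd.DataFrame([vars(s) for s in scores]).to_csv(out / "conformity_scores.csv", **opts)
    conf_summary.to_csv(out / "conformity_summary.csv", **opts)
    lag_df.to_csv(out / "lag_estimates.csv", **opts)
    profile_df.to_csv(out / "lag_profile.csv", **opts)
    for experiment, tables in anova.items():
        for dv, table in tables.items():
            table.to_csv(out / f"anova_exp{experiment}_{dv}.csv", **opts)
    association.to_csv(out / "association_table.csv", **opts)
    corr_df.to_csv(out / "correlations.csv", **opts)
    for ts in trajectories:
        ts.as_frame().to_csv(
            out / f"trajectory_{ts.axis}_{ts.speed_condition}.csv", **opts
        )


def _bold(text: str, significant: bool) -> str:
    return f"**{text}**" if significant else text


def _render_report(
    conf_summary: pd.DataFrame,
    association: pd.DataFrame,
    profile_df: pd.DataFrame,
    vel_tests: pd.DataFrame,
    corr_df: pd.DataFrame,
    alpha: float,
) -> str:
    lines = []
    lines.append("Conformity of head motion to the leave-one-out median trajectory")
    lines.append(f"(one-sample t vs 0; bold = p < {alpha:g})")
    lines.append(f"{'Axis':<8}{'Speed':<8}{'t (p)':<26}{'Mean r':<10}{'SD':<8}")
    for row in conf_summary.itertuples():
        cell = _bold(f"t({row.df}) = {row.t:.2f} (p = {row.p:.3g})", row.p < alpha)
        lines.append(
            f"{row.axis:<8}{row.speed_condition:<8}{cell:<26}{row.mean_r:<10.2f}{row.sd:<8.2f}"
        )
    lines.append("")
    lines.append("Conformity-rating correlations (bold = significant)")
    lines.append(f"{'Measure':<10}{'Speed':<8}" + "".join(f"{a:<22}" for a in AXES))
    for (measure, speed), group in association.groupby(
        ["measure", "speed_condition"], sort=False
    ):
        cells = []
        for axis in AXES:
            r_ = group[group.axis == axis].iloc[0]
            cells.append(_bold(f"{r_.r:.2f} (p = {r_.p:.2g})", bool(r_.significant)))
        lines.append(f"{measure:<10}{speed:<8}" + "".join(f"{c:<22}" for c in cells))
    lines.append("")
    lines.append("Head-vehicle lag (negative = head leads vehicle)")
    for row in profile_df.itertuples():
        lines.append(
            f"  {row.speed_condition:<8} n={row.n:<4} median {row.median_ms:7.1f} ms  "
            f"IQR [{row.q1_ms:.1f}, {row.q3_ms:.1f}]"
        )
    lines.append("")
    lines.append("Axis velocity comparisons (paired t, yaw vs pitch/roll)")
    for row in vel_tests.itertuples():
        lines.append(
            f"  {row.speed_condition:<6}{row.comparison:<14}"
            f"t({row.df}) = {row.t:.2f}, p = {row.p:.3g}"
        )
    lines.append("")
    lines.append("Rating intercorrelations (participant means over lap trials)")
    for row in corr_df.itertuples():
        lines.append(
            f"  exp {row.experiment}: {row.measure_x} ~ {row.measure_y}: "
            f"r({row.n - 2}) = {row.r:.2f}, p = {row.p:.3g}"
        )
    return "\n".join(lines) + "\n"


def _render_figures(fig_dir: Path, trajectories, conf_summary, lag_df) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes_grid = plt.subplots(3, 2, figsize=(10, 8), sharex=True)
    for ts in trajectories:
        i = AXES.index(ts.axis)
        j = LAP_SPEEDS.index(ts.speed_condition)
        ax = axes_grid[i][j]
        ax.plot(ts.t, ts.mean, color="black", lw=0.8)
        ax.fill_between(
            ts.t, ts.mean - ts.sem, ts.mean + ts.sem, color="grey", alpha=0.5
        )
        ax.set_title(f"{ts.axis} / {ts.speed_condition} (n={ts.n})", fontsize=9)
        ax.set_ylabel("deviation (deg)")
    axes_grid[-1][0].set_xlabel("time (s)")
    axes_grid[-1][1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(fig_dir / "trajectories.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for speed, marker in zip(LAP_SPEEDS, ("o", "s")):
        sub = conf_summary[conf_summary.speed_condition == speed]
        ax.errorbar(
            sub.axis, sub.mean_r, yerr=sub.sd, marker=marker, capsize=4, label=speed
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_ylabel("mean conformity r")
    ax.legend()
    fig.tight_layout()
    fig.savefig(fig_dir / "conformity.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(lag_df.lag_ms, bins=20, color="steelblue")
    ax.set_xlabel("lag (ms), negative = head leads")
    ax.set_ylabel("participants")
    fig.tight_layout()
    fig.savefig(fig_dir / "lag_histogram.png", dpi=120)
    plt.close(fig)
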