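"""Synthetic study generator with known planted parameters.

Every analysis stage in this package can be verified against ground truth by
generating a full synthetic study: a stylized track, per-lap vehicle yaw
traces, per-participant head-motion traces, and 1-20 ordinal ratings with
planted condition effects and conformity coupling.

Model summary
-------------
* Vehicle yaw: ``n_turns`` alternating left/right raised-cosine lobes over a
  60-s lap, with seeded jitter of lobe centers, widths, and amplitudes so the
  profile is smooth but aperiodic.  The slow lap is the half-speed playback of
  the fast lap: ``slow(t) = fast(t/2)`` on a grid of the same duration and
  rate (half the distance, same 60 s).  Amplitudes are expressed on the
  head-excursion scale (degrees of head yaw an average participant produces),
  so "turn amplitude" means the same thing for track, head model, and noise.
* Head yaw: ``g * vehicle_yaw(t + lead) + AR(1) wander + random-walk drift``.
  ``lead >= 0`` means the head turns *before* the vehicle (anticipation).
  Pitch and roll are attenuated copies of the driven yaw signal plus their own
  (smaller) noise, which yields the yaw > pitch > roll ordering of both
  velocity and conformity.
* Ratings: a Gaussian latent per measure - intercept + condition effects +
  participant traits + conformity coupling + residual - rounded and clamped
  to the integer 1-20 scale.  Vection onset/duration are generated only when
  the magnitude is >= 2 and always satisfy onset + duration <= lap duration.

All generation is a pure function of (config, seed); per-participant
substreams are keyed by (seed, stream, participant index) so enlarging a
cohort never perturbs earlier participants.  Planted parameters are stored in
a :class:`GroundTruth` sidecar that no analysis operation reads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import conformity as conformity_mod
from .errors import ConfigurationError
from .io_formats import (
    AXES,
    HeadMotionTrace,
    TrialRecord,
    VehicleTrace,
)
from .study_design import (
    EXPERIMENT_1,
    EXPERIMENT_2,
    DesignSpec,
    ScheduledTrial,
    assign_orders,
    build_session_schedule,
)

logger = logging.getLogger(__name__)

#: fixed relative couplings of the driven signal into pitch and roll
PITCH_GAIN = 0.55
ROLL_GAIN = 0.35
#: relative noise scale of pitch and roll wander/drift vs yaw
PITCH_NOISE_SCALE = 0.75
ROLL_NOISE_SCALE = 0.70

_MEASURES = ("vection", "sickness", "presence")


@dataclass(frozen=True)
class TrackConfig:
    """Stylized lap geometry, in head-excursion degrees and seconds."""

    n_turns: int = 6
    turn_amplitude: float = 4.5
    turn_duration: float = 3.5
    lap_duration: float = 60.0
    rate: float = 90.0
    amplitude_jitter: float = 0.25
    spacing_jitter: float = 0.3
    duration_jitter: float = 0.2

    def n_samples(self) -> int:
        n = self.rate * self.lap_duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"rate x lap duration = {n} is not an integer sample count"
            )
        return int(round(n))


@dataclass(frozen=True)
class HeadModelParams:
    """One participant's head-motion model parameters."""

    gain: float = 1.0
    lead_ms: float = 750.0
    noise_sd: float = 0.5  # stationary sd of the AR(1) wander, degrees
    ar_coef: float = 0.999  # at 90 Hz: wander correlation time ~11 s
    drift_sd: float = 0.1  # random-walk intensity, degrees per sqrt(second)

    def validated(self) -> "HeadModelParams":
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ConfigurationError("noise and drift sd must be >= 0")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigurationError("AR(1) coefficient must be in [0, 1)")
        if self.gain < 0:
            raise ConfigurationError("conformity gain must be >= 0")
        return self


@dataclass(frozen=True)
class HeadPopulation:
    """Population distribution the per-participant head models are drawn from."""

    gain_mean: float = 1.0
    gain_sd: float = 0.45
    gain_floor: float = 0.05
    lead_ms_mean: float = 750.0
    lead_ms_sd: float = 100.0
    noise_sd: float = 0.5
    noise_log_sd: float = 0.6  # lognormal spread of per-participant noise sd
    ar_coef: float = 0.999
    drift_sd: float = 0.1

    def draw(self, rng: np.random.Generator) -> HeadModelParams:
        gain = max(self.gain_floor, rng.normal(self.gain_mean, self.gain_sd))
        lead = max(0.0, rng.normal(self.lead_ms_mean, self.lead_ms_sd))
        noise = self.noise_sd * float(np.exp(rng.normal(0.0, self.noise_log_sd)))
        return HeadModelParams(
            gain=gain,
            lead_ms=lead,
            noise_sd=noise,
            ar_coef=self.ar_coef,
            drift_sd=self.drift_sd,
        ).validated()


@dataclass(frozen=True)
class RatingModel:
    """Latent-Gaussian ordinal rating model, clamped to the integer 1-20 scale.

    ``conformity_coupling`` is in rating points per unit correlation; it acts
    on the participant's measured yaw-conformity score for the matching
    upright/aligned/forward lap.  The default vection coupling is calibrated
    so the population conformity-vection correlation is ~0.3.
    """

    intercepts: Mapping[str, float] = field(
        default_factory=lambda: {"vection": 9.0, "sickness": 4.0, "presence": 11.0}
    )
    speed: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "vection": {"stationary": -7.5, "slow": 0.0, "fast": 2.0},
            "sickness": {"stationary": -2.5, "slow": 0.0, "fast": 1.0},
            "presence": {"stationary": -3.0, "slow": 0.0, "fast": 1.8},
        }
    )
    direction: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "vection": {"forward": 0.0, "reverse": -1.5, "lateral": -3.0},
            "sickness": {"forward": 0.0, "reverse": -1.2, "lateral": -1.2},
            "presence": {"forward": 0.0, "reverse": 0.0, "lateral": 0.0},
        }
    )
    posture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "vection": {"upright": 0.0, "reclined": 0.0},
            "sickness": {"upright": 0.0, "reclined": 0.0},
            "presence": {"upright": 0.0, "reclined": -0.7},
        }
    )
    alignment: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "vection": {"aligned": 0.0, "misaligned": 0.0},
            "sickness": {"aligned": 0.0, "misaligned": 0.0},
            "presence": {"aligned": 0.0, "misaligned": 0.0},
        }
    )
    #: bonus when the viewpoint is parallel to the road (upright-aligned or
    #: reclined-misaligned), i.e. when visual motion cues are fully available
    cue_availability: Mapping[str, float] = field(
        default_factory=lambda: {"vection": 1.2, "sickness": 0.0, "presence": 0.0}
    )
    conformity_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"vection": 0.0, "sickness": 0.0, "presence": 0.0}
    )
    #: fixed reference score the coupling acts around, so switching the
    #: coupling on shifts ratings relative to a typical conformer instead of
    #: inflating every intercept by beta * mean score
    conformity_reference: float = 0.85
    #: loading of the shared immersion trait (vection/presence) and the
    #: independent susceptibility trait (sickness)
    trait_loading: Mapping[str, float] = field(
        default_factory=lambda: {"vection": 3.0, "sickness": 1.5, "presence": 2.8}
    )
    residual_sd: float = 3.0

    def coefficient(self, table_name: str, measure: str, level: str | None) -> float:
        if level is None:
            return 0.0
        table = getattr(self, table_name)[measure]
        if level not in table:
            raise ConfigurationError(
                f"rating model has no {table_name} coefficient for level {level!r}"
            )
        return table[level]


def default_rating_model(conformity_coupling_vection: float = 9.5) -> RatingModel:
    """The default calibration, with the vection coupling switched on.

    9.5 rating points per unit correlation, against the default cohort's
    conformity-score spread (~0.15), lands the population conformity-vection
    correlation in the low-to-mid 0.3s (see docs/methods.md).
    """
    return RatingModel(
        conformity_coupling={
            "vection": conformity_coupling_vection,
            "sickness": 0.0,
            "presence": 0.0,
        }
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one experiment's synthetic cohort."""

    experiment: int = 1
    n_participants: int = 52
    seed: int = 0
    #: seed of the track geometry; both experiments replay the *same* recorded
    #: lap, so cohorts that are analysed together must share this value
    #: (defaults to ``seed``)
    track_seed: int | None = None
    track: TrackConfig = field(default_factory=TrackConfig)
    head: HeadPopulation = field(default_factory=HeadPopulation)
    ratings: RatingModel = field(default_factory=default_rating_model)
    #: "analysis" simulates head traces only for the upright/aligned/forward
    #: laps the combined head-motion analysis uses; "all" simulates every lap.
    head_trace_scope: str = "analysis"

    def design(self) -> DesignSpec:
        if self.experiment == 1:
            return EXPERIMENT_1
        if self.experiment == 2:
            return EXPERIMENT_2
        raise ConfigurationError(f"unknown experiment {self.experiment!r}")


@dataclass
class GroundTruth:
    """Planted parameters, stored beside a cohort; never consumed by analysis."""

    per_participant: pd.DataFrame  # participant_id, gain, lead_ms, noise_sd
    rating_model: RatingModel
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "per_participant": self.per_participant.to_dict(orient="records"),
            "rating_model": _dataclass_dict(self.rating_model),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _dataclass_dict(obj):
    return {
        f.name: dict(v) if isinstance(v := getattr(obj, f.name), Mapping) else v
        for f in dataclasses.fields(obj)
    }


@dataclass
class Cohort:
    """A complete generated dataset for one experiment."""

    config: CohortConfig
    vehicle: dict[str, VehicleTrace]
    schedules: dict[str, list[ScheduledTrial]]
    head_traces: dict[tuple[str, int], HeadMotionTrace]  # (participant, trial_index)
    records: list[TrialRecord]
    ground_truth: GroundTruth

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.schedules)

    def analysis_traces(self, speed: str, axis_check: bool = True) -> list[HeadMotionTrace]:
        """The upright/aligned/forward lap trace per participant at one speed."""
        out = []
        for pid in self.participant_ids:
            for trial in self.schedules[pid]:
                if _is_analysis_trial(self.config.experiment, trial) and trial.speed == speed:
                    key = (pid, trial.trial_index)
                    if key in self.head_traces:
                        out.append(self.head_traces[key])
        return out


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


# ---------------------------------------------------------------------------
# vehicle
# ---------------------------------------------------------------------------

def track_yaw_function(track: TrackConfig, seed: int) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous-time yaw profile of the *fast* lap as a callable of seconds."""
    if track.n_turns == 0:
        if track.turn_amplitude != 0.0:
            raise ConfigurationError(
                "a track with zero turns cannot have a nonzero turn amplitude"
            )
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if track.n_turns < 0 or track.turn_amplitude < 0:
        raise ConfigurationError("n_turns and turn_amplitude must be >= 0")
    rng = _rng(seed, 7)
    spacing = track.lap_duration / track.n_turns
    centers = (np.arange(track.n_turns) + 0.5) * spacing
    centers = centers + rng.uniform(-0.5, 0.5, track.n_turns) * track.spacing_jitter * spacing
    widths = track.turn_duration * (
        1.0 + rng.uniform(-1.0, 1.0, track.n_turns) * track.duration_jitter
    )
    amps = track.turn_amplitude * (
        1.0 + rng.uniform(-1.0, 1.0, track.n_turns) * track.amplitude_jitter
    )
    signs = (-1.0) ** (np.arange(track.n_turns) + rng.integers(0, 2))
    centers = np.clip(centers, widths / 2, track.lap_duration - widths / 2)

    def f(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        yaw = np.zeros_like(t)
        for c, w, a, s in zip(centers, widths, amps, signs):
            x = (t - c) / w
            mask = np.abs(x) <= 0.5
            yaw = yaw + np.where(mask, s * a * 0.5 * (1.0 + np.cos(2 * np.pi * x)), 0.0)
        return yaw

    return f


def generate_vehicle_trace(
    track: TrackConfig, speed_condition: str, seed: int
) -> VehicleTrace:
    """Sample the lap's vehicle yaw onto the uniform grid.

    The slow trace is the fast trace time-dilated by 2 (half-speed playback,
    half the track, same 60-s duration and rate).
    """
    f = track_yaw_function(track, seed)
    n = track.n_samples()
    t = np.arange(n) / track.rate
    yaw = f(t) if speed_condition == "fast" else f(t / 2.0)
    return VehicleTrace(
        lap_id=f"lap-{speed_condition}", speed_condition=speed_condition, t=t, yaw=yaw
    )


# ---------------------------------------------------------------------------
# head traces
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, sd: float, coef: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * np.sqrt(1.0 - coef**2), n)
    e[0] = rng.normal(0.0, sd)  # start in the stationary distribution
    return lfilter([1.0], [1.0, -coef], e)


def simulate_head_trace(
    vehicle: VehicleTrace,
    params: HeadModelParams,
    seed: int,
    participant_id: str = "sim",
    trial_id: str = "sim",
) -> HeadMotionTrace:
    """One lap of head motion: gain-scaled anticipated vehicle yaw plus wander.

    With ``noise_sd = drift_sd = 0``, ``gain = 1`` and ``lead_ms = 0`` the yaw
    channel equals the vehicle yaw exactly.  The lead shift is evaluated with
    boundary values held at the edges.
    """
    return _simulate_head_trace_rng(
        vehicle, params, _rng(seed, 13), participant_id, trial_id
    )


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def _latent(
    model: RatingModel,
    measure: str,
    trial: ScheduledTrial,
    conformity: float | None,
    traits: Mapping[str, float],
) -> float:
    value = model.intercepts[measure]
    value += model.coefficient("speed", measure, trial.speed)
    value += model.coefficient("direction", measure, trial.direction)
    value += model.coefficient("posture", measure, trial.posture)
    value += model.coefficient("alignment", measure, trial.alignment)
    if trial.posture is not None and trial.alignment is not None:
        cues_available = (trial.posture == "upright") == (trial.alignment == "aligned")
        if cues_available:
            value += model.cue_availability[measure]
    if conformity is not None:
        value += model.conformity_coupling[measure] * (
            conformity - model.conformity_reference
        )
    value += model.trait_loading[measure] * traits["sickness" if measure == "sickness" else "immersion"]
    return value


def simulate_ratings(
    schedule: Sequence[ScheduledTrial],
    conformity_by_trial: Mapping[int, float],
    model: RatingModel,
    seed: int,
    participant_id: str = "sim",
    experiment: int = 1,
    lap_duration: float = 60.0,
) -> list[TrialRecord]:
    """Generate one participant's validated trial records from the latent model.

    ``conformity_by_trial`` maps trial indices to the participant's measured
    yaw-conformity score for that lap (empty when coupling is off).
    """
    rng = _rng(seed, 17)
    traits = {"immersion": rng.normal(), "sickness": rng.normal()}
    records = []
    for trial in schedule:
        values = {}
        for measure in _MEASURES:
            latent = _latent(
                model,
                measure,
                trial,
                conformity_by_trial.get(trial.trial_index),
                traits,
            )
            latent += rng.normal(0.0, model.residual_sd)
            values[measure] = int(np.clip(np.rint(latent), 1, 20))
        onset = duration = None
        if values["vection"] >= 2:
            onset = float(
                np.clip(
                    rng.normal(12.0 - 0.5 * (values["vection"] - 10.0), 3.0),
                    0.5,
                    lap_duration - 1.0,
                )
            )
            duration = float((lap_duration - onset) * rng.beta(4.0, 2.0))
        records.append(
            TrialRecord(
                participant_id=participant_id,
                experiment=experiment,
                trial_index=trial.trial_index,
                posture=trial.posture,
                alignment=trial.alignment,
                direction=trial.direction,
                speed=trial.speed,
                vection_magnitude=values["vection"],
                vection_onset=onset,
                vection_duration=duration,
                sickness=values["sickness"],
                presence=values["presence"],
            ).validate(lap_duration)
        )
    return records


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def _is_analysis_trial(experiment: int, trial: ScheduledTrial) -> bool:
    if trial.speed not in ("slow", "fast"):
        return False
    if experiment == 1:
        return trial.posture == "upright" and trial.alignment == "aligned"
    return trial.direction == "forward"


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic experiment: traces, schedules, ratings, truth."""
    design = config.design()
    orders = assign_orders(design, config.n_participants)
    track_seed = config.seed if config.track_seed is None else config.track_seed
    vehicle = {
        speed: generate_vehicle_trace(config.track, speed, track_seed)
        for speed in ("slow", "fast")
    }

    schedules: dict[str, list[ScheduledTrial]] = {}
    head_traces: dict[tuple[str, int], HeadMotionTrace] = {}
    params: dict[str, HeadModelParams] = {}
    pids = []
    for i in range(config.n_participants):
        pid = f"E{config.experiment}P{i:03d}"
        pids.append(pid)
        params[pid] = config.head.draw(_rng(config.seed, 11, i))
        schedules[pid] = build_session_schedule(design, orders[i])

    for i, pid in enumerate(pids):
        for trial in schedules[pid]:
            simulate = (
                _is_analysis_trial(config.experiment, trial)
                if config.head_trace_scope == "analysis"
                else trial.speed in ("slow", "fast")
            )
            if simulate:
                trace_rngseed = _rng(config.seed, 13, i, trial.trial_index)
                head_traces[(pid, trial.trial_index)] = _simulate_head_trace_rng(
                    vehicle[trial.speed],
                    params[pid],
                    trace_rngseed,
                    participant_id=pid,
                    trial_id=f"t{trial.trial_index:02d}_{trial.speed}",
                )

    # measured yaw conformity feeds the rating coupling for matching trials
    conformity_by_pid_speed: dict[tuple[str, str], float] = {}
    if any(v != 0.0 for v in config.ratings.conformity_coupling.values()):
        for speed in ("slow", "fast"):
            traces = []
            for pid in pids:
                for trial in schedules[pid]:
                    if _is_analysis_trial(config.experiment, trial) and trial.speed == speed:
                        traces.append(head_traces[(pid, trial.trial_index)])
            if len(traces) >= 3:
                for score in conformity_mod.cohort_conformity(traces, "yaw", speed):
                    if not score.degenerate:
                        conformity_by_pid_speed[(score.participant_id, speed)] = score.r

    records: list[TrialRecord] = []
    for i, pid in enumerate(pids):
        conf = {
            trial.trial_index: conformity_by_pid_speed[(pid, trial.speed)]
            for trial in schedules[pid]
            if _is_analysis_trial(config.experiment, trial)
            and (pid, trial.speed) in conformity_by_pid_speed
        }
        records.extend(
            simulate_ratings(
                schedules[pid],
                conf,
                config.ratings,
                seed=_seed_for(config.seed, 17, i),
                participant_id=pid,
                experiment=config.experiment,
                lap_duration=config.track.lap_duration,
            )
        )

    truth = GroundTruth(
        per_participant=pd.DataFrame(
            {
                "participant_id": pids,
                "gain": [params[p].gain for p in pids],
                "lead_ms": [params[p].lead_ms for p in pids],
                "noise_sd": [params[p].noise_sd for p in pids],
            }
        ),
        rating_model=config.ratings,
        seed=config.seed,
    )
    logger.info(
        "generated cohort experiment=%d n=%d traces=%d records=%d",
        config.experiment,
        config.n_participants,
        len(head_traces),
        len(records),
    )
    return Cohort(
        config=config,
        vehicle=vehicle,
        schedules=schedules,
        head_traces=head_traces,
        records=records,
        ground_truth=truth,
    )


def _seed_for(seed: int, stream: int, index: int) -> int:
    # stable scalar sub-seed (simulate_ratings spawns its own SeedSequence)
    return int(
        np.random.SeedSequence((int(seed), stream, index)).generate_state(1)[0] % (2**31)
    )


def _simulate_head_trace_rng(
    vehicle: VehicleTrace,
    params: HeadModelParams,
    rng: np.random.Generator,
    participant_id: str,
    trial_id: str,
) -> HeadMotionTrace:
    """simulate_head_trace with an externally keyed generator (cohort substreams)."""
    params.validated()
    t = vehicle.t
    rate = vehicle.sampling_rate
    shifted = np.interp(t + params.lead_ms / 1000.0, t, vehicle.yaw)
    drift_step = params.drift_sd / np.sqrt(rate)
    channels = {}
    for axis, sig_gain, noise_scale in (
        ("yaw", 1.0, 1.0),
        ("pitch", PITCH_GAIN, PITCH_NOISE_SCALE),
        ("roll", ROLL_GAIN, ROLL_NOISE_SCALE),
    ):
        wander = _ar1(rng, t.size, params.noise_sd * noise_scale, params.ar_coef)
        if drift_step > 0:
            drift = np.cumsum(rng.normal(0.0, drift_step * noise_scale, t.size))
        else:
            drift = 0.0
        channels[axis] = params.gain * sig_gain * shifted + wander + drift
    return HeadMotionTrace(
        participant_id=participant_id, trial_id=trial_id, t=t.copy(), **channels
    )


# ---------------------------------------------------------------------------
# combined study and disk layout
# ---------------------------------------------------------------------------

def default_study_configs(seed: int) -> tuple[CohortConfig, CohortConfig]:
    """The default two-experiment study: n=52 and n=36 (combined head n=88)."""
    return (
        CohortConfig(experiment=1, n_participants=52, seed=seed, track_seed=seed),
        CohortConfig(experiment=2, n_participants=36, seed=seed + 1, track_seed=seed),
    )


def generate_study(seed: int, configs: Sequence[CohortConfig] | None = None) -> list[Cohort]:
    if configs is None:
        configs = default_study_configs(seed)
    return [generate_cohort(c) for c in configs]


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Lay a cohort out on disk exactly as the readers expect.

    ``trials.csv``, ``vehicle_<speed>.csv``, ``head/<pid>_t<idx>.csv``, a
    ``head_index.csv`` manifest, and the ``ground_truth.json`` sidecar (which
    the analysis pipeline never reads).
    """
    from .io_formats import write_head_motion_log, write_trial_records, write_vehicle_trace

    out = Path(out_dir)
    (out / "head").mkdir(parents=True, exist_ok=True)
    write_trial_records(cohort.records, out / "trials.csv")
    for speed, trace in cohort.vehicle.items():
        write_vehicle_trace(trace, out / f"vehicle_{speed}.csv")
    index_rows = []
    for (pid, idx), trace in sorted(cohort.head_traces.items()):
        rel = f"head/{pid}_t{idx:02d}.csv"
        write_head_motion_log(trace, out / rel)
        speed = next(
            t.speed for t in cohort.schedules[pid] if t.trial_index == idx
        )
        index_rows.append(
            {
                "participant_id": pid,
                "trial_index": idx,
                "speed_condition": speed,
                "path": rel,
            }
        )
    pd.DataFrame(index_rows).to_csv(out / "head_index.csv", index=False)
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    logger.info("wrote cohort to %s (%d head traces)", out, len(index_rows))
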