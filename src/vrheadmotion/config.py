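"""YAML run configuration: schema, defaults, validation, and object builders.

A run config has five sections — ``io``, ``design``, ``synthetic``,
``analysis``, ``report``.  :func:`load_config` performs no silent defaulting:
the file (or dict) must carry the full schema, and validation fails fast,
before any computation, naming every missing or inconsistent key.  Use
:func:`default_config` to obtain a complete template and edit from there.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .synthetic_cohort import (
    CohortConfig,
    HeadPopulation,
    RatingModel,
    TrackConfig,
    default_rating_model,
)

_REQUIRED = {
    "io": ["data_dir", "lap_duration", "rate"],
    "design": ["experiments"],
    "synthetic": ["enabled", "seed", "n_exp1", "n_exp2", "track", "head"],
    "analysis": ["max_lag_ms", "alpha"],
    "report": ["figures"],
}


def default_config() -> dict:
    """A complete, self-consistent configuration for the default synthetic study."""
    return {
        "io": {
            "data_dir": None,
            "lap_duration": 60.0,
            "rate": 90.0,
            "head_dialect": {
                "time": "time",
                "pitch": "pitch",
                "yaw": "yaw",
                "roll": "roll",
                "units": "degrees",
            },
        },
        "design": {"experiments": [1, 2]},
        "synthetic": {
            "enabled": True,
            "seed": 0,
            "n_exp1": 52,
            "n_exp2": 36,
            "track": {
                "n_turns": 6,
                "turn_amplitude": 4.5,
                "turn_duration": 3.5,
            },
            "head": {
                "gain_mean": 1.0,
                "gain_sd": 0.45,
                "lead_ms_mean": 750.0,
                "lead_ms_sd": 100.0,
                "noise_sd": 0.5,
                "noise_log_sd": 0.6,
                "ar_coef": 0.999,
                "drift_sd": 0.1,
            },
            "vection_coupling": 9.5,
        },
        "analysis": {"max_lag_ms": 2000.0, "alpha": 0.05},
        "report": {"figures": True},
    }


def load_config(source) -> dict:
    """Load and validate a config from a YAML path, YAML text, or mapping."""
    if isinstance(source, Mapping):
        cfg = copy.deepcopy(dict(source))
    else:
        path = Path(source)
        if path.exists():
            cfg = yaml.safe_load(path.read_text())
        else:
            cfg = yaml.safe_load(str(source))
        if not isinstance(cfg, dict):
            raise ConfigurationError(f"config {source!r} did not parse to a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: Mapping[str, Any]) -> None:
    problems = []
    for section, keys in _REQUIRED.items():
        if section not in cfg:
            problems.append(f"missing section {section!r}")
            continue
        for key in keys:
            if key not in cfg[section]:
                problems.append(f"missing key {section}.{key}")
    if problems:
        raise ConfigurationError("invalid configuration: " + "; ".join(problems))
    io = cfg["io"]
    if io["lap_duration"] is None or io["rate"] is None:
        raise ConfigurationError("io.lap_duration and io.rate must be set")
    n = float(io["rate"]) * float(io["lap_duration"])
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"rate x lap_duration = {n} is not an integer sample count"
        )
    syn = cfg["synthetic"]
    if not syn["enabled"] and not io["data_dir"]:
        raise ConfigurationError(
            "either synthetic.enabled must be true or io.data_dir must point at a dataset"
        )
    exps = cfg["design"]["experiments"]
    if not exps or any(e not in (1, 2) for e in exps):
        raise ConfigurationError(f"design.experiments must be a subset of [1, 2], got {exps}")


def cohort_configs(cfg: Mapping[str, Any], seed: int | None = None) -> list[CohortConfig]:
    """Build the per-experiment generator configs from a validated run config."""
    syn = cfg["synthetic"]
    io = cfg["io"]
    base_seed = int(syn["seed"] if seed is None else seed)
    track = TrackConfig(
        lap_duration=float(io["lap_duration"]),
        rate=float(io["rate"]),
        **{k: v for k, v in syn["track"].items()},
    )
    head = HeadPopulation(**syn["head"])
    ratings = default_rating_model(float(syn.get("vection_coupling", 0.0)))
    out = []
    for experiment in cfg["design"]["experiments"]:
        out.append(
            CohortConfig(
                experiment=experiment,
                n_participants=int(syn["n_exp1"] if experiment == 1 else syn["n_exp2"]),
                seed=base_seed + (experiment - 1),
                track_seed=base_seed,
                track=track,
                head=head,
                ratings=ratings,
            )
        )
    return out


def dump_config(cfg: Mapping[str, Any], path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=False))
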