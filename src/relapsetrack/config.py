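"""Run configuration: schema, defaults, and all-at-once validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .censoring import DEFAULT_VISIT_DAYS, FollowUpSchedule
from .cohort import CohortConfig, RelapseProcess, default_relapse_process
from .errors import ConfigError
from .survival import McmcConfig, SurvivalModelSpec


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end pipeline run needs."""

    cohort: CohortConfig
    schedule: FollowUpSchedule
    model: SurvivalModelSpec
    mcmc: McmcConfig
    study_end_day: int = 395
    imputation_m: int = 10
    tail_fraction: float = 0.27
    output_dir: str = "out"
    seed: int = 0
    raw: dict = field(default_factory=dict, compare=False)

    def stage_seeds(self) -> dict:
        """Deterministic per-stage seeds derived from the global seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "cohort": int(children[0].generate_state(1)[0] % (2**31)),
            "relapse": int(children[1].generate_state(1)[0] % (2**31)),
            "mcmc": int(children[2].generate_state(1)[0] % (2**31)),
        }


def default_config(seed: int = 0, output_dir: str = "out") -> dict:
    """The shipped default run configuration as a plain dict."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "study_end_day": 395,
        "cohort": {
            "n_subjects": 510,
            "assignment_rule": "seat_multiple_of_3",
            "socrates_mean": 72.47,
            "socrates_sd": 7.124,
            "hads_mean": 8.44,
            "hads_sd": 7.284,
            "release_window_days": 365,
        },
        "relapse_model": {
            "mode": "mixture",
            "shape": 1.0,
            "intercepts": {"experimental": 852.0, "control": 737.0},
            "motivation_coeff": 2.6,
            "p_early": {"experimental": 0.111, "control": 0.457},
            "relapse_fraction": 0.476,
        },
        "schedule": {"visit_days": list(DEFAULT_VISIT_DAYS)},
        "model": {"include_motivation": True, "fix_shape": None},
        "mcmc": {
            "n_iterations": 3000,
            "burn_in": 1000,
            "thinning": 1,
            "n_chains": 3,
            "param_sweeps": 5,
            "convergence_threshold": 1.002,
        },
        "imputation": {"m": 10},
        "risk": {"tail_fraction": 0.27},
    }


def _build(section: str, cls, kwargs: dict, errors: list):
    try:
        return cls(**kwargs)
    except ConfigError as exc:
        errors.extend(f"{section}: {e}" for e in exc.errors)
    except TypeError as exc:
        errors.append(f"{section}: {exc}")
    return None


def validate_config(raw) -> RunConfig:
    """Build a :class:`RunConfig` from a dict or a JSON/YAML file path.

    All schema violations are collected and reported together in the
    raised :class:`ConfigError`, not first-failure.
    """
    if isinstance(raw, (str, Path)):
        text = Path(raw).read_text()
        raw = json.loads(text) if str(raw).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])

    errors: list[str] = []
    known = {
        "seed", "output_dir", "study_end_day", "cohort", "relapse_model",
        "schedule", "model", "mcmc", "imputation", "risk",
    }
    for key in raw:
        if key not in known:
            errors.append(f"unknown top-level key {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
        seed = 0

    process = _build("relapse_model", RelapseProcess, raw.get("relapse_model", {}), errors) \
        if "relapse_model" in raw else default_relapse_process()
    cohort_kwargs = dict(raw.get("cohort", {}))
    cohort_kwargs.setdefault("seed", seed)
    if process is not None:
        cohort_kwargs["relapse_model"] = process
    cohort = _build("cohort", CohortConfig, cohort_kwargs, errors)

    schedule = _build("schedule", FollowUpSchedule,
                      {"visit_days": tuple(raw.get("schedule", {}).get("visit_days", DEFAULT_VISIT_DAYS))},
                      errors)
    model_kwargs = dict(raw.get("model", {}))
    for pr in ("prior_shape", "prior_intercept", "prior_slope"):
        if pr in model_kwargs:
            model_kwargs[pr] = tuple(model_kwargs[pr])
    model = _build("model", SurvivalModelSpec, model_kwargs, errors)
    mcmc_kwargs = dict(raw.get("mcmc", {}))
    mcmc_kwargs.setdefault("seed", seed)
    mcmc = _build("mcmc", McmcConfig, mcmc_kwargs, errors)

    study_end = raw.get("study_end_day", 395)
    if not (isinstance(study_end, int) and study_end >= 2):
        errors.append(f"study_end_day: must be an integer >= 2, got {study_end!r}")
    elif cohort is not None and cohort.release_window_days >= study_end:
        errors.append("study_end_day must exceed cohort.release_window_days so every subject has follow-up")

    m = raw.get("imputation", {}).get("m", 10)
    if not (isinstance(m, int) and m >= 1):
        errors.append(f"imputation.m: must be a positive integer, got {m!r}")

    tail = raw.get("risk", {}).get("tail_fraction", 0.27)
    if not (isinstance(tail, (int, float)) and 0.0 < tail <= 0.5):
        errors.append(f"risk.tail_fraction: must lie in (0, 0.5], got {tail!r}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        cohort=cohort, schedule=schedule, model=model, mcmc=mcmc,
        study_end_day=study_end, imputation_m=m, tail_fraction=float(tail),
        output_dir=str(raw.get("output_dir", "out")), seed=seed, raw=raw,
    )
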