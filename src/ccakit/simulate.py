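"""Synthetic youth-athlete cohorts for developing and testing the CCA pipeline.

No raw data were deposited for the instrument's normative sample, so every
downstream stage (cut-point derivation, scoring, diagnostics, reliability)
is exercised on synthetic cohorts that emulate its stated structure: ~854
athletes aged 9-18, both sexes, per-task raw measures with positive support
and task-specific error processes, plus paired test-retest records with a
controllable true single-measure ICC.

Distribution families: completion times are lognormal (positive, right
skewed, as timed motor tasks are), repetitions are rounded normals
truncated at 0, and jump distances are normals truncated at 0 with three
trials per athlete. Error counts are Poisson; the default rates are set so
the probability of committing at least one error equals the error
prevalence published for each task (1.8% jumping jacks, 2.4% pylon course,
55.3% backwards tandem walking, 11.8% shuttle run, 25.5% ins and outs).
Older and male strata receive additive location shifts in the "better"
direction (faster times, more repetitions, longer jumps).

Test-retest pairs are drawn from the additive decomposition
``value = location + subject_effect + occasion_noise`` with the
between-subject share of total variance equal to ``true_icc``, so the
population single-measure ICC equals ``true_icc`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ccakit.exceptions import ConfigurationError
from ccakit.instrument import TASKS, TASK_IDS

__all__ = [
    "TaskSimParams",
    "SimConfig",
    "generate_normative_sample",
    "generate_retest_sample",
    "generate_retest_pairs",
]


def _rate_from_prevalence(p: float) -> float:
    """Poisson rate with P(count >= 1) equal to a target error prevalence."""
    return -math.log1p(-p)


@dataclass(frozen=True)
class TaskSimParams:
    """Per-task generator parameters.

    location/scale are the mean/SD of the raw measure on its natural scale
    (seconds, repetitions, or metres) for the reference stratum (female,
    ages 9-12). ``age_effect`` shifts the location for adolescents (13-18)
    and ``sex_effect`` for males; both are signed in raw units, chosen so
    older/male athletes perform better. ``error_rate`` is the expected
    Poisson error count per attempt. ``true_icc`` is the target
    test-retest ICC for paired samples.
    """

    family: str  # lognormal | rounded_normal | truncated_normal
    location: float
    scale: float
    error_rate: float
    age_effect: float = 0.0
    sex_effect: float = 0.0
    true_icc: float = 0.8

    def stratum_location(self, adolescent: bool, male: bool) -> float:
        return self.location + adolescent * self.age_effect + male * self.sex_effect


# Reference-stratum locations/scales follow the retest means and SDs
# published for the instrument where those are in usable units; the long
# jump is parameterised in metres (1.45 +/- 0.25 m, a realistic youth
# standing long jump) because the published table's jump units are
# inconsistent with metres.
DEFAULT_TASK_PARAMS: dict[str, TaskSimParams] = {
    "jumping_jacks": TaskSimParams(
        "rounded_normal", location=23.0, scale=2.6,
        error_rate=_rate_from_prevalence(0.018), age_effect=1.5, sex_effect=1.0,
        true_icc=0.56,
    ),
    "pylon_obstacle": TaskSimParams(
        "lognormal", location=7.0, scale=0.75,
        error_rate=_rate_from_prevalence(0.024), age_effect=-0.5, sex_effect=-0.3,
        true_icc=0.38,
    ),
    "backwards_tandem": TaskSimParams(
        "lognormal", location=20.0, scale=6.0,
        error_rate=_rate_from_prevalence(0.553), age_effect=-2.0, sex_effect=-1.0,
        true_icc=0.83,
    ),
    "shuttle_run": TaskSimParams(
        "lognormal", location=19.0, scale=1.6,
        error_rate=_rate_from_prevalence(0.118), age_effect=-1.0, sex_effect=-0.6,
        true_icc=0.48,
    ),
    "ins_and_outs": TaskSimParams(
        "lognormal", location=7.0, scale=1.5,
        error_rate=_rate_from_prevalence(0.255), age_effect=-0.5, sex_effect=-0.3,
        true_icc=0.73,
    ),
    "long_jump": TaskSimParams(
        "truncated_normal", location=1.45, scale=0.25,
        error_rate=_rate_from_prevalence(0.02), age_effect=0.15, sex_effect=0.08,
        true_icc=0.81,
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic cohort.

    ``n_participants`` defaults to 854 (the size of the instrument's
    normative sample); ``n_retest`` to 67 (its retest subsample).
    ``interval_months`` is the (low, high) range of uniformly drawn
    test-retest intervals, default 0.5-24 months. A single global ``seed``
    governs all randomness; per-task streams are derived deterministically.
    """

    n_participants: int = 854
    age_range: tuple[int, int] = (9, 18)
    sex_ratio: float = 0.5
    task_params: dict[str, TaskSimParams] = field(
        default_factory=lambda: dict(DEFAULT_TASK_PARAMS)
    )
    jump_trial_noise_sd: float = 0.05
    landing_failure_rate: float = 0.036
    n_retest: int = 67
    interval_months: tuple[float, float] = (0.5, 24.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1] or self.age_range[0] < 0:
            raise ConfigurationError("age_range must be a non-empty non-negative span")
        if not 0 <= self.landing_failure_rate < 1:
            raise ConfigurationError("landing_failure_rate must lie in [0, 1)")
        missing = [t for t in TASK_IDS if t not in self.task_params]
        if missing:
            raise ConfigurationError(f"task_params missing tasks: {missing}")
        for task_id, p in self.task_params.items():
            if p.scale <= 0:
                raise ConfigurationError(f"task_params[{task_id}].scale must be > 0")
            if p.location <= 0:
                raise ConfigurationError(f"task_params[{task_id}].location must be > 0")
            if p.error_rate < 0:
                raise ConfigurationError(f"task_params[{task_id}].error_rate must be >= 0")
            if not 0 < p.true_icc <= 1:
                raise ConfigurationError(f"task_params[{task_id}].true_icc must lie in (0, 1]")

    def with_icc(self, true_icc: float, tasks: tuple[str, ...] = TASK_IDS) -> "SimConfig":
        """Copy of this config with ``true_icc`` set on the given tasks."""
        params = {
            t: replace(p, true_icc=true_icc) if t in tasks else p
            for t, p in self.task_params.items()
        }
        return replace(self, task_params=params)


def _task_rng(seed: int, task_id: str, purpose: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, hash_name(task_id), hash_name(purpose)]))


def hash_name(name: str) -> int:
    """Stable 31-bit stream key for a named sub-stream."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _draw_raw(rng: np.random.Generator, family: str, loc: np.ndarray, scale: float) -> np.ndarray:
    """Draw raw measures with mean ~loc and SD ~scale under the stated family."""
    n = loc.shape[0]
    if family == "lognormal":
        # moment-matched lognormal: mean loc, SD scale on the natural scale
        sigma2 = np.log1p((scale / loc) ** 2)
        mu = np.log(loc) - sigma2 / 2
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    if family == "rounded_normal":
        return np.maximum(np.round(rng.normal(loc, scale, size=n)), 0.0)
    if family == "truncated_normal":
        return np.maximum(rng.normal(loc, scale, size=n), 0.0)
    raise ConfigurationError(f"unknown distribution family {family!r}")


def _demographics(config: SimConfig, n: int, prefix: str) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, hash_name(prefix), hash_name("demographics")]))
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    sexes = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    return pd.DataFrame(
        {
            "participant_id": [f"{prefix}{i:05d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
        }
    )


def generate_normative_sample(config: SimConfig) -> pd.DataFrame:
    """Generate a cross-sectional normative cohort.

    Returns one row per participant with columns ``participant_id``,
    ``age``, ``sex``, ``session`` (all ``t1``), per single-trial task
    ``{task}_value`` and ``{task}_errors``, and for the long jump
    ``long_jump_d1..d3`` with ``long_jump_valid1..3`` landing flags plus
    ``long_jump_errors``. Deterministic under a fixed config.
    """
    config.validate()
    df = _demographics(config, config.n_participants, "N")
    df["session"] = "t1"
    adolescent = (df["age"] >= 13).to_numpy()
    male = (df["sex"] == "male").to_numpy()
    n = len(df)
    for task_id in TASK_IDS:
        p = config.task_params[task_id]
        loc = p.stratum_location(adolescent, male)
        rng_raw = _task_rng(config.seed, task_id, "raw")
        rng_err = _task_rng(config.seed, task_id, "errors")
        if task_id == "long_jump":
            base = _draw_raw(rng_raw, p.family, loc, p.scale)
            for i in (1, 2, 3):
                noise = rng_raw.normal(0.0, config.jump_trial_noise_sd, size=n)
                df[f"long_jump_d{i}"] = np.maximum(base + noise, 0.0)
                df[f"long_jump_valid{i}"] = rng_raw.random(n) >= config.landing_failure_rate
        else:
            df[f"{task_id}_value"] = _draw_raw(rng_raw, p.family, loc, p.scale)
        df[f"{task_id}_errors"] = rng_err.poisson(p.error_rate, size=n)
    return df


def generate_retest_sample(config: SimConfig) -> pd.DataFrame:
    """Generate a paired test-retest cohort (two rows per participant).

    For each task, t1/t2 values share a Gaussian subject effect with
    variance ``true_icc * scale**2`` plus independent occasion noise with
    variance ``(1 - true_icc) * scale**2``; the population single-measure
    ICC therefore equals ``true_icc``. Long-jump trials at each session
    perturb the session value by small trial noise (all landings valid, so
    the session's derived measure keeps the target ICC). Error counts are
    drawn independently per session.
    """
    config.validate()
    demo = _demographics(config, config.n_retest, "R")
    rng_int = np.random.default_rng(np.random.SeedSequence([config.seed, hash_name("retest"), hash_name("interval")]))
    lo, hi = config.interval_months
    demo["interval_months"] = rng_int.uniform(lo, hi, size=config.n_retest)
    adolescent = (demo["age"] >= 13).to_numpy()
    male = (demo["sex"] == "male").to_numpy()
    n = len(demo)

    sessions = []
    session_values: dict[str, dict[str, np.ndarray]] = {t: {} for t in TASK_IDS}
    for task_id in TASK_IDS:
        p = config.task_params[task_id]
        loc = p.stratum_location(adolescent, male)
        rng = _task_rng(config.seed, task_id, "retest")
        # stratum location shifts already contribute between-subject
        # variance; the latent subject effect supplies only the remainder
        # so the total between-subject share equals true_icc.
        var_loc = float(np.var(loc, ddof=1)) if n > 1 else 0.0
        between = max(p.true_icc * p.scale**2 - var_loc, 0.0)
        subject = rng.normal(0.0, math.sqrt(between), size=n)
        for session in ("t1", "t2"):
            noise = rng.normal(0.0, math.sqrt(1.0 - p.true_icc) * p.scale, size=n)
            session_values[task_id][session] = np.maximum(loc + subject + noise, 1e-6)
    for session in ("t1", "t2"):
        block = demo.copy()
        block["session"] = session
        for task_id in TASK_IDS:
            p = config.task_params[task_id]
            value = session_values[task_id][session]
            rng_err = _task_rng(config.seed, task_id, f"retest-errors-{session}")
            if task_id == "long_jump":
                rng_tr = _task_rng(config.seed, task_id, f"retest-trials-{session}")
                # trial 1 carries the session value exactly; extra trials sit below it
                block["long_jump_d1"] = value
                for i in (2, 3):
                    block[f"long_jump_d{i}"] = np.maximum(
                        value - np.abs(rng_tr.normal(0.0, config.jump_trial_noise_sd, size=n)), 0.0
                    )
                for i in (1, 2, 3):
                    block[f"long_jump_valid{i}"] = True
            else:
                block[f"{task_id}_value"] = value
            block[f"{task_id}_errors"] = rng_err.poisson(p.error_rate, size=n)
        sessions.append(block)
    return pd.concat(sessions, ignore_index=True)


def generate_retest_pairs(config: SimConfig, task_id: str) -> pd.DataFrame:
    """Paired (t1, t2) raw measures for one task, one row per participant.

    Columns: participant_id, age, sex, interval_months, t1, t2. The
    long-jump measure is the session's best valid distance.
    """
    if task_id not in TASKS:
        raise ConfigurationError(f"unknown task {task_id!r}")
    sample = generate_retest_sample(config)
    from ccakit.cutpoints import derivation_values  # late import to avoid a cycle

    wide = None
    for session in ("t1", "t2"):
        block = sample[sample["session"] == session]
        vals = derivation_values(block, task_id)
        cols = block[["participant_id", "age", "sex", "interval_months"]].reset_index(drop=True)
        cols[session] = vals.reset_index(drop=True)
        wide = cols if wide is None else wide.merge(cols, on=["participant_id", "age", "sex", "interval_months"])
    return wide
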