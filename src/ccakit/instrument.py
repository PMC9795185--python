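"""CCA task definitions, scoring forms, error rules, and the scoring engine.

Each of the six tasks yields a raw measure (time in seconds, repetitions, or
jump distance in metres) plus a count of performance errors (e.g. touching a
pylon, a non-tandem step). Scoring is a two-stage map:

1. ``bin_score`` places the raw measure into one of four performance bins
   using three ordered cut points (the 5-point 0-4 response scale; the
   legacy 4-point 0-3 scale uses one or two cut points), best bin -> 4
   (or 3), worst -> 1.
2. ``apply_error_rule`` caps or zeroes the bin score as a function of the
   error count. Score 0 is reserved for error-driven failure or inability
   to perform; error-free performance never scores below 1.

A raw value exactly on a cut point takes the *better* adjacent bin (a 1.5 m
standing long jump with a 1.5 m top cut point scores 4).

The three outcome items (backwards_tandem, ins_and_outs, long_jump) sum to
the 0-12 outcome summary; the three exertion items are standalone scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ccakit.exceptions import (
    FormValidationError,
    InputShapeError,
    MissingDataError,
)

__all__ = [
    "TASKS",
    "TASK_IDS",
    "OUTCOME_TASKS",
    "EXERTION_TASKS",
    "DEFAULT_ERROR_RULES",
    "TaskDefinition",
    "ErrorRule",
    "ScoringForm",
    "ScoreResult",
    "bin_score",
    "apply_error_rule",
    "score_task",
    "score_long_jump",
    "score_sample",
    "summarize",
]

MAX_SCORE = 4


@dataclass(frozen=True)
class TaskDefinition:
    """Static description of one CCA task."""

    task_id: str
    label: str
    measure_kind: str  # time_seconds | repetitions | distance_metres
    direction: str  # lower_better | higher_better
    n_trials: int
    domain_tags: tuple[str, ...]
    item_class: str  # outcome | exertion

    def __post_init__(self) -> None:
        if (self.direction == "lower_better") != (self.measure_kind == "time_seconds"):
            raise ValueError(f"{self.task_id}: lower_better iff time_seconds")


TASKS: dict[str, TaskDefinition] = {
    t.task_id: t
    for t in (
        TaskDefinition(
            "jumping_jacks", "Jumping Jacks", "repetitions", "higher_better",
            1, ("coordination",), "exertion",
        ),
        TaskDefinition(
            "pylon_obstacle", "Pylon Obstacle Course", "time_seconds", "lower_better",
            1, ("speed_agility",), "exertion",
        ),
        TaskDefinition(
            "backwards_tandem", "Backwards Tandem Walking", "time_seconds", "lower_better",
            1, ("coordination", "dynamic_balance"), "outcome",
        ),
        TaskDefinition(
            "shuttle_run", "Modified Shuttle Run", "time_seconds", "lower_better",
            1, ("speed_agility", "dynamic_balance"), "exertion",
        ),
        TaskDefinition(
            "ins_and_outs", "Ins and Outs", "time_seconds", "lower_better",
            1, ("coordination",), "outcome",
        ),
        TaskDefinition(
            "long_jump", "Standing Long Jump", "distance_metres", "higher_better",
            3, ("strength", "dynamic_balance"), "outcome",
        ),
    )
}

TASK_IDS: tuple[str, ...] = tuple(TASKS)
OUTCOME_TASKS: tuple[str, ...] = ("backwards_tandem", "ins_and_outs", "long_jump")
EXERTION_TASKS: tuple[str, ...] = ("jumping_jacks", "pylon_obstacle", "shuttle_run")


@dataclass(frozen=True)
class ErrorRule:
    """Per-task map from error count to the maximum attainable score.

    ``zero_score_at`` is the smallest error count that forces a score of 0
    regardless of performance. Below it, ``cap_by_errors[e]`` bounds the
    score from above; the cap at zero errors is always 4 and caps are
    non-increasing in the error count.
    """

    task_id: str
    zero_score_at: int
    cap_by_errors: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zero_score_at < 1:
            raise ValueError(f"{self.task_id}: zero_score_at must be >= 1")
        caps = [self.cap(e) for e in range(self.zero_score_at)]
        if caps[0] != MAX_SCORE:
            raise ValueError(f"{self.task_id}: cap at 0 errors must be {MAX_SCORE}")
        if any(b > a for a, b in zip(caps, caps[1:])):
            raise ValueError(f"{self.task_id}: caps must be non-increasing")

    def cap(self, error_count: int) -> int:
        """Maximum attainable score with ``error_count`` errors (0 at/beyond the zero threshold)."""
        if error_count >= self.zero_score_at:
            return 0
        if error_count == 0:
            return MAX_SCORE
        return self.cap_by_errors.get(error_count, 0)


# Published error-score modifications. Five tasks with error prevalence
# below 5% in the normative athlete sample auto-zero on any error; the two
# error-prone tasks keep graded caps (one error caps Backwards Tandem
# Walking at 3, Ins and Outs at 2, Modified Shuttle Run at 1). Long-jump
# landing failure is handled separately in score_long_jump.
DEFAULT_ERROR_RULES: dict[str, ErrorRule] = {
    "jumping_jacks": ErrorRule("jumping_jacks", zero_score_at=1),
    "pylon_obstacle": ErrorRule("pylon_obstacle", zero_score_at=1),
    "shuttle_run": ErrorRule("shuttle_run", zero_score_at=2, cap_by_errors={1: 1}),
    "ins_and_outs": ErrorRule("ins_and_outs", zero_score_at=3, cap_by_errors={1: 2, 2: 1}),
    "backwards_tandem": ErrorRule(
        "backwards_tandem", zero_score_at=5, cap_by_errors={1: 3, 2: 2, 3: 1, 4: 1}
    ),
    "long_jump": ErrorRule("long_jump", zero_score_at=1),
}


@dataclass
class ScoringForm:
    """A stratum-specific set of per-task cut points.

    ``stratum`` is ``("pooled",)`` or ``(age_band, sex)`` with age_band in
    {"9-12", "13-18"} and sex in {"male", "female"}. ``thresholds`` maps
    task_id to a strictly increasing tuple of raw-measure cut points
    (1 or 2 for the mean +/- SD method, 3 for the quartile method), stored
    in ascending raw units regardless of direction.
    """

    stratum: tuple[str, ...]
    method: str  # mean_sd_4pt | quartile_5pt
    thresholds: dict[str, tuple[float, ...]]
    provenance: dict = field(default_factory=dict)

    _EXPECTED_N = {"mean_sd_4pt": (1, 2), "quartile_5pt": (3,)}

    def validate(self) -> None:
        if self.method not in self._EXPECTED_N:
            raise FormValidationError(f"unknown method {self.method!r}")
        for task_id, cuts in self.thresholds.items():
            if task_id not in TASKS:
                raise FormValidationError(f"unknown task {task_id!r}")
            if len(cuts) not in self._EXPECTED_N[self.method]:
                raise FormValidationError(
                    f"{task_id}: {len(cuts)} thresholds invalid for {self.method}"
                )
            if any(b < a for a, b in zip(cuts, cuts[1:])):
                raise FormValidationError(f"{task_id}: thresholds not ordered: {cuts}")

    def matches(self, age: float, sex: str) -> bool:
        """Whether this form's stratum covers a participant."""
        if self.stratum == ("pooled",):
            return True
        age_band, form_sex = self.stratum
        in_band = age <= 12 if age_band == "9-12" else age >= 13
        return in_band and sex == form_sex

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "stratum": list(self.stratum),
            "method": self.method,
            "thresholds": {k: list(v) for k, v in self.thresholds.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ScoringForm":
        form = cls(
            stratum=tuple(payload["stratum"]),
            method=payload["method"],
            thresholds={k: tuple(v) for k, v in payload["thresholds"].items()},
            provenance=dict(payload.get("provenance", {})),
        )
        form.validate()
        return form


@dataclass(frozen=True)
class ScoreResult:
    """Per-task 0-4 item scores plus the three-item outcome summary."""

    item_scores: dict[str, int]
    outcome_summary: int
    exertion_scores: dict[str, int]


def bin_score(raw_value: float, thresholds: Sequence[float], direction: str) -> int:
    """Place a raw measure into a performance bin (best bin = n_cuts + 1).

    ``thresholds`` are ascending raw-measure cut points. For higher-better
    measures the best bin lies above the last cut; for lower-better (times)
    it lies below the first. A value exactly on a cut point takes the
    better adjacent bin.
    """
    cuts = np.asarray(thresholds, dtype=float)
    if cuts.ndim != 1 or cuts.size == 0:
        raise FormValidationError("thresholds must be a non-empty 1-d sequence")
    if np.any(np.diff(cuts) < 0):
        raise FormValidationError(f"thresholds not ordered: {thresholds}")
    if not np.isfinite(raw_value):
        raise MissingDataError(f"raw value is not finite: {raw_value}")
    if direction == "higher_better":
        return 1 + int(np.sum(raw_value >= cuts))
    if direction == "lower_better":
        return 1 + int(np.sum(raw_value <= cuts))
    raise ValueError(f"unknown direction {direction!r}")


def apply_error_rule(bin_score_value: int, error_count: int, rule: ErrorRule) -> int:
    """Cap or zero a bin score according to the task's error rule."""
    if error_count < 0:
        raise ValueError("error_count must be non-negative")
    return min(int(bin_score_value), rule.cap(int(error_count)))


def score_long_jump(
    trials: Sequence[tuple[float, bool]],
    form: ScoringForm,
    error_count: int = 0,
    rule: ErrorRule | None = None,
) -> int:
    """Score the Standing Long Jump from its three trials.

    Scores 0 if no trial has a valid two-foot landing; otherwise bins the
    maximum distance among valid trials and applies the error rule.
    """
    trials = list(trials)
    if len(trials) != 3:
        raise InputShapeError(f"long_jump requires exactly 3 trials, got {len(trials)}")
    rule = rule or DEFAULT_ERROR_RULES["long_jump"]
    valid = [float(d) for d, ok in trials if ok]
    if not valid:
        return 0
    raw = bin_score(max(valid), form.thresholds["long_jump"], TASKS["long_jump"].direction)
    return apply_error_rule(raw, error_count, rule)


def score_task(
    record: Mapping,
    task_id: str,
    form: ScoringForm,
    rule: ErrorRule | None = None,
) -> int:
    """Score one task for one participant-session record.

    ``record`` is a mapping (e.g. a DataFrame row) using the documented
    column schema: ``{task}_value`` and ``{task}_errors`` for single-trial
    tasks; ``long_jump_d1..d3`` / ``long_jump_valid1..3`` for the jump.
    """
    if task_id not in TASKS:
        raise ValueError(f"unknown task {task_id!r}")
    task = TASKS[task_id]
    rule = rule or DEFAULT_ERROR_RULES[task_id]
    if task_id not in form.thresholds:
        raise FormValidationError(f"form has no thresholds for {task_id}")
    pid = record.get("participant_id", "<unknown>")
    errors = record.get(f"{task_id}_errors")
    if errors is None or pd.isna(errors):
        raise MissingDataError(f"participant {pid}: missing error count for {task_id}")
    if task_id == "long_jump":
        try:
            trials = [
                (record[f"long_jump_d{i}"], bool(record[f"long_jump_valid{i}"]))
                for i in (1, 2, 3)
            ]
        except KeyError as exc:
            raise MissingDataError(f"participant {pid}: missing long_jump trial {exc}") from None
        return score_long_jump(trials, form, int(errors), rule)
    raw = record.get(f"{task_id}_value")
    if raw is None or pd.isna(raw):
        raise MissingDataError(f"participant {pid}: missing raw value for {task_id}")
    return apply_error_rule(
        bin_score(float(raw), form.thresholds[task_id], task.direction), int(errors), rule
    )


def summarize(scores: Mapping[str, int]) -> ScoreResult:
    """Combine six item scores into a ScoreResult.

    The outcome summary is the unweighted sum of the three outcome items;
    exertion items are passed through unaggregated.
    """
    missing = [t for t in TASK_IDS if t not in scores]
    if missing:
        raise MissingDataError(f"missing item scores for: {', '.join(missing)}")
    for t, s in scores.items():
        if not (0 <= int(s) <= MAX_SCORE):
            raise ValueError(f"{t}: item score {s} outside 0-{MAX_SCORE}")
    item_scores = {t: int(scores[t]) for t in TASK_IDS}
    return ScoreResult(
        item_scores=item_scores,
        outcome_summary=sum(item_scores[t] for t in OUTCOME_TASKS),
        exertion_scores={t: item_scores[t] for t in EXERTION_TASKS},
    )


def _form_for(forms: Sequence[ScoringForm], age: float, sex: str) -> ScoringForm:
    for form in forms:
        if form.matches(age, sex):
            return form
    raise FormValidationError(f"no scoring form covers age={age}, sex={sex}")


def score_sample(
    records: pd.DataFrame,
    forms: ScoringForm | Sequence[ScoringForm],
    rules: Mapping[str, ErrorRule] | None = None,
) -> pd.DataFrame:
    """Score every record in a sample, selecting the stratum form per participant.

    Returns one row per input row: identifiers, six item-score columns and
    the ``outcome_summary``.
    """
    if isinstance(forms, ScoringForm):
        forms = [forms]
    rules = dict(DEFAULT_ERROR_RULES) | dict(rules or {})
    rows = []
    for _, rec in records.iterrows():
        form = _form_for(forms, rec["age"], rec["sex"])
        scores = {t: score_task(rec, t, form, rules[t]) for t in TASK_IDS}
        result = summarize(scores)
        out = {
            "participant_id": rec["participant_id"],
            "session": rec.get("session", "t1"),
            **{f"{t}_score": result.item_scores[t] for t in TASK_IDS},
            "outcome_summary": result.outcome_summary,
        }
        rows.append(out)
    return pd.DataFrame(rows)
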