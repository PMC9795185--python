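"""Normative cut-point derivation for the CCA scoring forms.

Cut points are derived only from participants who completed a task without
error (so that speed or distance is never credited at the expense of
accuracy). Two derivation methods are supported:

* ``mean_sd``: the legacy 4-point method — mean +/- 1 SD for a single cut
  point, adding mean +/- 2 SD for a second, signed toward the worse
  direction so the best category lies beyond mean +/- 1 SD on the better
  side. SD is the sample SD (ddof=1).
* ``quartile``: the 5-point method — cut points at the 25th/50th/75th
  percentiles of the error-free distribution (numpy's default linear
  interpolation between order statistics, Hyndman-Fan type 7), so the
  derivation sample splits into four ~25% performance bins.

Forms may be pooled or stratified into the four age-band x sex strata
(female/male children aged 9-12, female/male adolescents aged 13-18).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ccakit.exceptions import DerivationError
from ccakit.instrument import TASKS, TASK_IDS, ScoringForm

__all__ = [
    "AGE_BANDS",
    "NormativeSummary",
    "filter_error_free",
    "derivation_values",
    "derive_mean_sd_thresholds",
    "derive_quartile_thresholds",
    "build_scoring_forms",
    "normative_summary",
]

AGE_BANDS: dict[str, tuple[int, int]] = {"9-12": (9, 12), "13-18": (13, 18)}


@dataclass(frozen=True)
class NormativeSummary:
    """Error-free performance summary for one task in one stratum."""

    task_id: str
    stratum: tuple[str, ...]
    n_total: int
    n_error_free: int
    mean: float
    sd: float
    quartiles: tuple[float, float, float]


def filter_error_free(sample: pd.DataFrame, task_id: str) -> pd.DataFrame:
    """Records that completed a task without error.

    For the long jump this additionally requires at least one valid
    landing (otherwise there is no distance to learn from).
    """
    if sample.empty:
        raise DerivationError("sample is empty")
    if task_id not in TASKS:
        raise ValueError(f"unknown task {task_id!r}")
    mask = sample[f"{task_id}_errors"] == 0
    if task_id == "long_jump":
        any_valid = (
            sample["long_jump_valid1"] | sample["long_jump_valid2"] | sample["long_jump_valid3"]
        )
        mask &= any_valid
    out = sample[mask]
    if out.empty:
        raise DerivationError(
            f"no error-free records for {task_id}; collect a larger normative sample"
        )
    return out


def derivation_values(sample: pd.DataFrame, task_id: str) -> pd.Series:
    """The raw measure each record contributes to derivation (and scoring).

    Single-trial tasks contribute ``{task}_value``; the long jump
    contributes the maximum distance over valid trials (NaN if none).
    """
    if task_id != "long_jump":
        return sample[f"{task_id}_value"].astype(float)
    dist = sample[["long_jump_d1", "long_jump_d2", "long_jump_d3"]].to_numpy(float)
    valid = sample[["long_jump_valid1", "long_jump_valid2", "long_jump_valid3"]].to_numpy(bool)
    best = np.where(valid.any(axis=1), np.where(valid, dist, -np.inf).max(axis=1), np.nan)
    return pd.Series(best, index=sample.index, name="long_jump_value")


def derive_mean_sd_thresholds(
    values, n_cuts: int, direction: str
) -> tuple[float, ...]:
    """Mean +/- SD cut points (ascending raw units).

    For lower-better measures the best category requires value <=
    mean - 1 SD, so cuts sit below the mean; mirrored for higher-better.
    With two cuts the outer cut is at 2 SD. Zero-variance input yields
    coincident cuts and a degeneracy warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise DerivationError(f"need >= 2 error-free values, got {vals.size}")
    if n_cuts not in (1, 2):
        raise ValueError("n_cuts must be 1 or 2")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance: degenerate coincident cut points", stacklevel=2)
    sign = -1.0 if direction == "lower_better" else 1.0
    cuts = [mean + sign * k * sd for k in range(1, n_cuts + 1)]
    return tuple(sorted(cuts))


def derive_quartile_thresholds(values, direction: str) -> tuple[float, float, float]:
    """Quartile cut points (Q1, Q2, Q3) of the error-free distribution.

    Returned in ascending raw units; ``direction`` governs which end is
    the best bin at scoring time, not the ordering here. Identical values
    yield coincident cuts and a degeneracy warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise DerivationError(f"need >= 4 error-free values, got {vals.size}")
    if direction not in ("lower_better", "higher_better"):
        raise ValueError(f"unknown direction {direction!r}")
    q1, q2, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    if q1 == q3:
        warnings.warn("degenerate quartiles: all cut points coincide", stacklevel=2)
    return float(q1), float(q2), float(q3)


def _strata(stratify: bool):
    if not stratify:
        yield ("pooled",), None
        return
    for band in AGE_BANDS:
        for sex in ("female", "male"):
            yield (band, sex), (AGE_BANDS[band], sex)


def _stratum_mask(sample: pd.DataFrame, selector) -> pd.Series:
    if selector is None:
        return pd.Series(True, index=sample.index)
    (lo, hi), sex = selector
    return (sample["age"] >= lo) & (sample["age"] <= hi) & (sample["sex"] == sex)


def build_scoring_forms(
    sample: pd.DataFrame,
    method: str = "quartile",
    stratify: bool = False,
    min_n: int = 30,
    mean_sd_cuts: int = 2,
    sample_id: str = "normative",
) -> list[ScoringForm]:
    """Derive one pooled or four stratified scoring forms from a cohort.

    ``method`` is ``"quartile"`` (5-point, 3 cuts) or ``"mean_sd"``
    (4-point, ``mean_sd_cuts`` cuts). Each stratum must retain at least
    ``min_n`` error-free records per task. Forms carry provenance (sample
    id, per-task error-free n, stratum, method).
    """
    if method not in ("quartile", "mean_sd"):
        raise ValueError(f"unknown method {method!r}")
    forms = []
    for stratum, selector in _strata(stratify):
        subsample = sample[_stratum_mask(sample, selector)]
        if subsample.empty:
            raise DerivationError(f"stratum {stratum}: no records")
        thresholds: dict[str, tuple[float, ...]] = {}
        n_used: dict[str, int] = {}
        for task_id in TASK_IDS:
            error_free = filter_error_free(subsample, task_id)
            vals = derivation_values(error_free, task_id).dropna().to_numpy()
            if vals.size < min_n:
                raise DerivationError(
                    f"stratum {stratum}, task {task_id}: only {vals.size} "
                    f"error-free records (minimum {min_n})"
                )
            direction = TASKS[task_id].direction
            if method == "quartile":
                thresholds[task_id] = derive_quartile_thresholds(vals, direction)
            else:
                thresholds[task_id] = derive_mean_sd_thresholds(vals, mean_sd_cuts, direction)
            n_used[task_id] = int(vals.size)
        form = ScoringForm(
            stratum=stratum,
            method="quartile_5pt" if method == "quartile" else "mean_sd_4pt",
            thresholds=thresholds,
            provenance={
                "sample_id": sample_id,
                "n_total": int(len(subsample)),
                "n_error_free": n_used,
            },
        )
        form.validate()
        forms.append(form)
    return forms


def normative_summary(sample: pd.DataFrame, stratify: bool = False) -> pd.DataFrame:
    """Per task x stratum error-free summary (n, mean, SD, quartiles)."""
    rows = []
    for stratum, selector in _strata(stratify):
        subsample = sample[_stratum_mask(sample, selector)]
        for task_id in TASK_IDS:
            error_free = filter_error_free(subsample, task_id)
            vals = derivation_values(error_free, task_id).dropna().to_numpy()
            q1, q2, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
            rows.append(
                NormativeSummary(
                    task_id=task_id,
                    stratum=stratum,
                    n_total=int(len(subsample)),
                    n_error_free=int(vals.size),
                    mean=float(np.mean(vals)),
                    sd=float(np.std(vals, ddof=1)),
                    quartiles=(float(q1), float(q2), float(q3)),
                )
            )
    return pd.DataFrame(
        {
            "task_id": [r.task_id for r in rows],
            "stratum": ["/".join(r.stratum) for r in rows],
            "n_total": [r.n_total for r in rows],
            "n_error_free": [r.n_error_free for r in rows],
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "q1": [r.quartiles[0] for r in rows],
            "median": [r.quartiles[1] for r in rows],
            "q3": [r.quartiles[2] for r in rows],
        }
    )
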