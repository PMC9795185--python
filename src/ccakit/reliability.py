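"""Single-measure test-retest ICC estimation and outcome-item selection.

The reliability index is the intraclass correlation for single measures
from a two-way random-effects, absolute-agreement decomposition — ICC(A,1)
in McGraw & Wong's taxonomy — chosen because assessors differed between
sessions, so session-to-session shifts count against agreement. From the
two-way ANOVA mean squares of the n x 2 (subject x session) table:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR the between-subject, MSC the between-session, and MSE the
residual mean square, k = 2 sessions. 95% confidence intervals follow
McGraw & Wong's F-based construction (Satterthwaite degrees of freedom for
the session term). Negative estimates are reported as computed. A one-way
random-effects form, ICC(1), is available as a config option.

Stability bands: ICC < 0.60 unstable, 0.60-0.70 (inclusive) marginal,
> 0.70 stable. Tasks whose whole-group ICC exceeds 0.70 over a <= 12-month
retest interval are retained as outcome items (combined into the summary
score); the remainder serve as standalone exertion items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ccakit.exceptions import ReliabilityError, SchemaError, SelectionError
from ccakit.instrument import TASK_IDS

__all__ = [
    "PUBLISHED_RETEST_ICC_0_12",
    "ReliabilityResult",
    "icc_single",
    "classify_reliability",
    "subgroup_reliability",
    "select_outcome_items",
]

UNSTABLE_BELOW = 0.60
STABLE_ABOVE = 0.70
MIN_PAIRS = 4

# Whole-group 0-12-month test-retest ICCs published for the CCA's
# development sample; used as reference inputs for the outcome/exertion
# partition, not as values this package claims to reproduce.
PUBLISHED_RETEST_ICC_0_12: dict[str, float] = {
    "jumping_jacks": 0.56,
    "pylon_obstacle": 0.38,
    "backwards_tandem": 0.83,
    "shuttle_run": 0.48,
    "ins_and_outs": 0.73,
    "long_jump": 0.81,
}


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC for one task in one subgroup, with session summaries."""

    task_id: str
    stratifier: str  # all | interval | age_band | sex
    subgroup: str
    n_pairs: int
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    icc: float
    ci_lower: float
    ci_upper: float
    classification: str  # unstable | marginal | stable | insufficient_n


def _anova_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) from the two-way subject x session table."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((y - grand) ** 2).sum())
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_single(
    pairs,
    model: str = "two_way_random",
    alpha: float = 0.05,
    min_n: int = MIN_PAIRS,
) -> tuple[float, float, float]:
    """Single-measure ICC with a 95% (or 1-alpha) confidence interval.

    ``pairs`` is an (n, 2) array-like of (t1, t2) raw measures.
    ``model`` selects ``two_way_random`` (absolute agreement, ICC(A,1);
    the default) or ``one_way`` (ICC(1)). Returns (icc, ci_lower,
    ci_upper); estimates below 0 are not truncated.
    """
    y = np.asarray(pairs, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ReliabilityError(f"pairs must be (n, 2), got {y.shape}")
    n, k = y.shape
    if n < min_n:
        raise ReliabilityError(f"need at least {min_n} pairs, got {n}")
    if not np.all(np.isfinite(y)):
        raise ReliabilityError("pairs contain non-finite values")
    msr, msc, mse = _anova_mean_squares(y)

    if model == "one_way":
        msw = (msc * (k - 1) + mse * (n - 1) * (k - 1)) / (n * (k - 1))
        denom = msr + (k - 1) * msw
        if denom == 0.0:
            return 1.0, 1.0, 1.0
        icc = (msr - msw) / denom
        if msw == 0.0:
            return float(icc), float(icc), float(icc)
        f_obs = msr / msw
        df1, df2 = n - 1, n * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + k - 1)
        upper = (fu - 1) / (fu + k - 1)
        return float(icc), float(lower), float(upper)
    if model != "two_way_random":
        raise ValueError(f"unknown model {model!r}")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return 1.0, 1.0, 1.0
    icc = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: the F construction is degenerate
        return float(icc), float(icc), float(icc)
    # McGraw & Wong F-based interval with Satterthwaite df for the
    # session effect.
    a = (k * icc) / (n * (1 - icc)) if icc < 1.0 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = (n - 1) * (k - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lower), float(upper)


def classify_reliability(icc: float) -> str:
    """Three-band stability classification (0.60/0.70 map to marginal)."""
    if not np.isfinite(icc):
        raise ReliabilityError(f"ICC is not finite: {icc}")
    if icc < UNSTABLE_BELOW:
        return "unstable"
    if icc <= STABLE_ABOVE:
        return "marginal"
    return "stable"


def _interval_band(months: float) -> str:
    return "0-12" if months <= 12.0 else "12-24"


def _age_band(age: float) -> str:
    return "9-12" if age <= 12 else "13-18"


def _pairs_matrix(paired: pd.DataFrame, task_id: str) -> pd.DataFrame:
    """Wide (one row per participant) t1/t2 table for a task from a long paired sample."""
    from ccakit.cutpoints import derivation_values

    required = {"participant_id", "session", "interval_months", "age", "sex"}
    missing = required - set(paired.columns)
    if missing:
        raise SchemaError(f"paired sample missing columns: {sorted(missing)}")
    frames = []
    for session in ("t1", "t2"):
        block = paired[paired["session"] == session]
        vals = derivation_values(block, task_id)
        f = block[["participant_id", "age", "sex", "interval_months"]].copy()
        f[session] = vals
        frames.append(f)
    wide = frames[0].merge(frames[1], on=["participant_id", "age", "sex", "interval_months"])
    return wide.dropna(subset=["t1", "t2"])


def subgroup_reliability(
    paired: pd.DataFrame,
    stratifiers: tuple[str, ...] = ("interval", "age_band", "sex"),
    model: str = "two_way_random",
    min_n: int = MIN_PAIRS,
) -> pd.DataFrame:
    """Per-task ICC table for the whole sample and each requested subgroup.

    ``paired`` is a long sample with two rows (sessions t1, t2) per
    participant. Produces one row per task x subgroup with n, session
    means/SDs, ICC with 95% CI, and the stability class; subgroups with
    fewer than ``min_n`` pairs are reported with ``insufficient_n`` and no
    estimate.
    """
    unknown = set(stratifiers) - {"interval", "age_band", "sex"}
    if unknown:
        raise SchemaError(f"unknown stratifiers: {sorted(unknown)}")
    rows = []
    for task_id in TASK_IDS:
        wide = _pairs_matrix(paired, task_id)
        groups: list[tuple[str, str, pd.DataFrame]] = [("all", "all", wide)]
        if "interval" in stratifiers:
            bands = wide["interval_months"].map(_interval_band)
            for band in ("0-12", "12-24"):
                groups.append(("interval", band, wide[bands == band]))
        if "age_band" in stratifiers:
            bands = wide["age"].map(_age_band)
            for band in ("9-12", "13-18"):
                groups.append(("age_band", band, wide[bands == band]))
        if "sex" in stratifiers:
            for sex in ("male", "female"):
                groups.append(("sex", sex, wide[wide["sex"] == sex]))
        for stratifier, label, g in groups:
            base = dict(
                task_id=task_id,
                stratifier=stratifier,
                subgroup=label,
                n_pairs=int(len(g)),
                mean_t1=float(g["t1"].mean()) if len(g) else np.nan,
                sd_t1=float(g["t1"].std(ddof=1)) if len(g) > 1 else np.nan,
                mean_t2=float(g["t2"].mean()) if len(g) else np.nan,
                sd_t2=float(g["t2"].std(ddof=1)) if len(g) > 1 else np.nan,
            )
            if len(g) < min_n:
                rows.append(
                    ReliabilityResult(
                        **base, icc=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                        classification="insufficient_n",
                    )
                )
                continue
            icc, lo, hi = icc_single(g[["t1", "t2"]].to_numpy(), model=model, min_n=min_n)
            rows.append(
                ReliabilityResult(
                    **base, icc=icc, ci_lower=lo, ci_upper=hi,
                    classification=classify_reliability(icc),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def select_outcome_items(
    results: pd.DataFrame | dict[str, float],
    interval: str = "0-12",
    target_icc: float = STABLE_ABOVE,
) -> tuple[list[str], list[str]]:
    """Partition the six tasks into outcome vs exertion items.

    Outcome items are those whose whole-group ICC in the chosen retest
    interval exceeds ``target_icc`` (default 0.70); the rest remain as
    standalone exertion items. ``results`` is either a
    :func:`subgroup_reliability` table or a plain mapping task_id -> ICC
    for the interval.
    """
    if isinstance(results, pd.DataFrame):
        sel = results[(results["stratifier"] == "interval") & (results["subgroup"] == interval)]
        iccs = dict(zip(sel["task_id"], sel["icc"]))
    else:
        iccs = dict(results)
    missing = [t for t in TASK_IDS if t not in iccs]
    if missing:
        raise SelectionError(f"no ICC for tasks: {missing} in interval {interval}")
    outcome = [t for t in TASK_IDS if iccs[t] > target_icc]
    exertion = [t for t in TASK_IDS if t not in outcome]
    if not outcome:
        import warnings

        warnings.warn(f"no task exceeds ICC {target_icc} in interval {interval}", stacklevel=2)
    return outcome, exertion
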