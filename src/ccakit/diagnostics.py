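"""Item difficulty and distribution-shape diagnostics for scored samples.

In a healthy athlete cohort most items cluster at the top of the scale;
an item whose scores pile up at the maximum (or whose distribution is
strongly negatively skewed) cannot register post-injury decline — the
classic ceiling effect. Conversely, an item whose mean falls below 2.0 on
the legacy 0-3 scale is flagged as too difficult.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ccakit.exceptions import DiagnosticsError

__all__ = [
    "ItemDiagnostics",
    "item_diagnostics",
    "error_prevalence",
    "recommend_error_rule_class",
    "sample_diagnostics",
]

# Defaults for the qualitative ceiling-effect criterion: flag when more
# than 15% of scores sit at the scale maximum or skewness < -0.5.
CEILING_PCT_AT_MAX = 15.0
CEILING_SKEWNESS_BOUND = -0.5
TOO_DIFFICULT_MEAN = 2.0  # applies on the 0-3 scale only
ERROR_PREVALENCE_AUTO_ZERO_PCT = 5.0


@dataclass(frozen=True)
class ItemDiagnostics:
    task_id: str
    n: int
    mean_score: float
    sd_score: float
    skewness: float
    pct_at_max: float
    flags: tuple[str, ...]


def item_diagnostics(
    scores,
    scale_max: int,
    task_id: str = "",
    ceiling_pct: float = CEILING_PCT_AT_MAX,
    skew_bound: float = CEILING_SKEWNESS_BOUND,
) -> ItemDiagnostics:
    """Mean, SD, adjusted Fisher-Pearson skewness, % at max, and flags.

    ``too_difficult`` fires when the mean falls below 2.0 on the 0-3
    scale; ``ceiling_effect`` when the share of perfect scores exceeds
    ``ceiling_pct`` or skewness drops below ``skew_bound``. On one
    evaluation the two flags are mutually exclusive (too_difficult wins,
    being the stronger finding about the same distribution's location).
    """
    vals = np.asarray(scores, dtype=float)
    if vals.size == 0:
        raise DiagnosticsError("empty score set")
    if np.any(vals < 0) or np.any(vals > scale_max):
        raise DiagnosticsError(f"scores outside [0, {scale_max}]")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    skew = float(stats.skew(vals, bias=False)) if vals.size > 2 and sd > 0 else 0.0
    pct_at_max = float(np.mean(vals == scale_max) * 100.0)
    flags = []
    if scale_max == 3 and mean < TOO_DIFFICULT_MEAN:
        flags.append("too_difficult")
    elif pct_at_max > ceiling_pct or skew < skew_bound:
        flags.append("ceiling_effect")
    else:
        flags.append("acceptable")
    return ItemDiagnostics(
        task_id=task_id,
        n=int(vals.size),
        mean_score=mean,
        sd_score=sd,
        skewness=skew,
        pct_at_max=pct_at_max,
        flags=tuple(flags),
    )


def error_prevalence(sample: pd.DataFrame, task_id: str) -> float:
    """Percentage of participants committing at least one error on a task."""
    if sample.empty:
        raise DiagnosticsError("sample is empty")
    return float((sample[f"{task_id}_errors"] >= 1).mean() * 100.0)


def recommend_error_rule_class(prevalence_pct: float, boundary: float = ERROR_PREVALENCE_AUTO_ZERO_PCT) -> str:
    """Recommend ``auto_zero`` (rare errors) vs ``graded_caps`` (common errors)."""
    return "auto_zero" if prevalence_pct < boundary else "graded_caps"


def sample_diagnostics(scored: pd.DataFrame, scale_max: int = 4) -> pd.DataFrame:
    """Item diagnostics for every ``{task}_score`` column of a scored sample."""
    rows = []
    for col in scored.columns:
        if not col.endswith("_score"):
            continue
        task_id = col[: -len("_score")]
        d = item_diagnostics(scored[col].to_numpy(), scale_max, task_id=task_id)
        rows.append(
            {
                "task_id": task_id,
                "n": d.n,
                "mean_score": d.mean_score,
                "sd_score": d.sd_score,
                "skewness": d.skewness,
                "pct_at_max": d.pct_at_max,
                "flags": "|".join(d.flags),
            }
        )
    return pd.DataFrame(rows)
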