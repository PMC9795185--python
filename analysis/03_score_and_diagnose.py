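"""Score the normative cohort and diagnose item difficulty.

Scores every athlete under the stratified quartile forms with the
error-modified 0-4 rules, then runs the item diagnostics (mean, SD,
skewness, % at maximum, ceiling/difficulty flags) and the error-prevalence
check that motivates each task's error-rule class (auto-zero below 5%
prevalence, graded caps above). Writes scores and diagnostics CSVs under
results/.
"""

from pathlib import Path

import pandas as pd

from ccakit import io
from ccakit.diagnostics import error_prevalence, recommend_error_rule_class, sample_diagnostics
from ccakit.instrument import TASK_IDS, score_sample

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    normative = io.read_records(ROOT / "data" / "normative_sample.csv")
    forms = io.read_forms(ROOT / "forms_quartile_stratified.json")

    scored = score_sample(normative, forms)
    scored.to_csv(ROOT / "scores.csv", index=False)

    diag = sample_diagnostics(scored, scale_max=4)
    prevalence = pd.DataFrame(
        {
            "task_id": TASK_IDS,
            "pct_any_error": [error_prevalence(normative, t) for t in TASK_IDS],
        }
    )
    prevalence["recommended_rule_class"] = prevalence["pct_any_error"].map(
        recommend_error_rule_class
    )
    diag = diag.merge(prevalence, on="task_id")
    diag.to_csv(ROOT / "diagnostics.csv", index=False)

    print(f"scored {len(scored)} athletes; outcome summary mean "
          f"{scored.outcome_summary.mean():.2f} (range {scored.outcome_summary.min()}"
          f"-{scored.outcome_summary.max()})")
    print(diag.round(2).to_string(index=False))

    # legacy 4-point (0-3) scoring from the two-cut mean +/- SD form, the
    # configuration whose difficulty profile motivated the 5-point revision
    legacy = score_sample(normative, io.read_forms(ROOT / "forms_mean_sd.json"))
    legacy_diag = sample_diagnostics(legacy, scale_max=3)
    legacy_diag.to_csv(ROOT / "diagnostics_legacy_4pt.csv", index=False)
    print("\nlegacy 0-3 scale diagnostics (mean < 2.0 flags too_difficult):")
    print(legacy_diag.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
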