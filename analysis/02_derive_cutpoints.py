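"""Derive scoring-form cut points from the normative cohort.

Reproduces the development sequence: the legacy two-cut mean +/- SD form
(4-point scale), the pooled quartile form (5-point scale), and the four
age-band x sex quartile forms. Only error-free performances enter the
derivation. Writes the forms (JSON) and a normative summary table (CSV)
under results/.
"""

from pathlib import Path

from ccakit import io
from ccakit.cutpoints import build_scoring_forms, normative_summary

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    normative = io.read_records(ROOT / "data" / "normative_sample.csv")

    mean_sd = build_scoring_forms(normative, method="mean_sd", stratify=False)
    pooled = build_scoring_forms(normative, method="quartile", stratify=False)
    stratified = build_scoring_forms(normative, method="quartile", stratify=True)

    io.write_forms(mean_sd, ROOT / "forms_mean_sd.json")
    io.write_forms(pooled, ROOT / "forms_quartile_pooled.json")
    io.write_forms(stratified, ROOT / "forms_quartile_stratified.json")
    summary = normative_summary(normative, stratify=True)
    summary.to_csv(ROOT / "normative_summary.csv", index=False)

    print(f"derived {len(mean_sd)} mean+/-SD form, {len(pooled)} pooled and "
          f"{len(stratified)} stratified quartile forms")
    for form in stratified:
        n = form.provenance["n_error_free"]
        print(f"  stratum {'/'.join(form.stratum):14s} "
              f"error-free n per task: min {min(n.values())}, max {max(n.values())}")
    print("pooled quartile cut points:")
    for task_id, cuts in pooled[0].thresholds.items():
        print(f"  {task_id:18s} " + ", ".join(f"{c:7.2f}" for c in cuts))


if __name__ == "__main__":
    main()
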