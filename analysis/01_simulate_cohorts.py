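"""Generate the synthetic development cohorts.

Draws the cross-sectional normative cohort (854 athletes, ages 9-18) and
the paired test-retest cohort (67 athletes, intervals 0.5-24 months) under
the default stated world, and writes both as CSV under results/data/.
"""

from pathlib import Path

from ccakit import io
from ccakit.diagnostics import error_prevalence
from ccakit.instrument import TASK_IDS
from ccakit.simulate import SimConfig, generate_normative_sample, generate_retest_sample

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20240901


def main() -> None:
    cfg = SimConfig(seed=SEED)
    normative = generate_normative_sample(cfg)
    paired = generate_retest_sample(cfg)
    io.write_records(normative, OUT / "normative_sample.csv")
    io.write_records(paired, OUT / "retest_sample.csv")

    print(f"normative cohort: {len(normative)} athletes "
          f"({(normative.age >= 13).mean():.0%} adolescents, "
          f"{(normative.sex == 'male').mean():.0%} male)")
    print(f"retest cohort: {paired.participant_id.nunique()} athletes x 2 sessions")
    print("observed error prevalence (%):")
    for task_id in TASK_IDS:
        print(f"  {task_id:18s} {error_prevalence(normative, task_id):5.1f}")


if __name__ == "__main__":
    main()
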