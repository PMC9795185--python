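"""End-to-end development pipeline: simulate -> derive -> score -> diagnose -> reliability.

Each stage is a plain function over DataFrames/forms so the CLI, the
analysis drivers, and the tests share one code path. ``run_pipeline``
executes all stages in order, writes every artifact under an output
directory, and records a manifest (config, seed, package version, artifact
checksums). A failing stage leaves a ``<stage>.failed`` marker beside any
partial artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from ccakit import io
from ccakit.cutpoints import build_scoring_forms, normative_summary
from ccakit.diagnostics import sample_diagnostics
from ccakit.instrument import score_sample
from ccakit.reliability import select_outcome_items, subgroup_reliability
from ccakit.simulate import SimConfig, generate_normative_sample, generate_retest_sample

logger = logging.getLogger("ccakit")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    n_participants: int = 854
    n_retest: int = 67
    method: str = "quartile"
    stratify: bool = False
    min_n: int = 30


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full development pipeline; returns the artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    sim = SimConfig(
        n_participants=config.n_participants, n_retest=config.n_retest, seed=config.seed
    )
    stage = "simulate"
    try:
        normative = generate_normative_sample(sim)
        paired = generate_retest_sample(sim)
        artifacts["normative_sample"] = out / "normative_sample.csv"
        artifacts["retest_sample"] = out / "retest_sample.csv"
        io.write_records(normative, artifacts["normative_sample"])
        io.write_records(paired, artifacts["retest_sample"])
        logger.info("simulate: %d normative rows, %d retest rows", len(normative), len(paired))

        stage = "derive"
        forms = build_scoring_forms(
            normative, method=config.method, stratify=config.stratify, min_n=config.min_n
        )
        artifacts["scoring_forms"] = out / "scoring_forms.json"
        io.write_forms(forms, artifacts["scoring_forms"])
        summary = normative_summary(normative, stratify=config.stratify)
        artifacts["normative_summary"] = out / "normative_summary.csv"
        summary.to_csv(artifacts["normative_summary"], index=False)
        logger.info("derive: %d form(s)", len(forms))

        stage = "score"
        scored = score_sample(normative, forms)
        artifacts["scores"] = out / "scores.csv"
        scored.to_csv(artifacts["scores"], index=False)
        logger.info("score: %d rows", len(scored))

        stage = "diagnose"
        diag = sample_diagnostics(scored, scale_max=4)
        artifacts["diagnostics"] = out / "diagnostics.csv"
        diag.to_csv(artifacts["diagnostics"], index=False)

        stage = "reliability"
        rel = subgroup_reliability(paired)
        artifacts["reliability"] = out / "reliability.csv"
        rel.to_csv(artifacts["reliability"], index=False)
        outcome, exertion = select_outcome_items(rel)
        artifacts["item_partition"] = out / "item_partition.csv"
        artifacts["item_partition"].write_text(
            "task_id,item_class\n"
            + "\n".join(f"{t},outcome" for t in outcome)
            + ("\n" if outcome and exertion else "")
            + "\n".join(f"{t},exertion" for t in exertion)
            + "\n"
        )
        logger.info("reliability: outcome items %s", outcome)
    except Exception:
        (out / f"{stage}.failed").touch()
        logger.exception("pipeline failed at stage %s", stage)
        raise

    manifest_config = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "n_retest": config.n_retest,
        "method": config.method,
        "stratify": config.stratify,
        "min_n": config.min_n,
    }
    io.write_manifest(out / "manifest.json", manifest_config, artifacts)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
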