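"""CSV/JSON input-output and schema validation.

CSV dialect: comma-separated, UTF-8, mandatory header row, dot decimal.
Athlete records are one row per participant-session with the columns
produced by :mod:`ccakit.simulate`; scoring forms are versioned JSON
documents that round-trip thresholds bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ccakit.exceptions import SchemaError
from ccakit.instrument import TASK_IDS, ScoringForm

__all__ = [
    "read_records",
    "write_records",
    "validate_records",
    "read_forms",
    "write_forms",
    "write_manifest",
    "sha256_file",
]

_DEMOGRAPHIC_COLUMNS = ("participant_id", "age", "sex", "session")


def validate_records(records: pd.DataFrame) -> None:
    """Raise SchemaError (with row numbers) on malformed athlete records."""
    missing = [c for c in _DEMOGRAPHIC_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    problems: list[str] = []

    def check(mask: pd.Series, message: str) -> None:
        bad = records.index[mask.fillna(True)].tolist()[:5]
        if bad:
            problems.append(f"rows {bad}: {message}")

    check(~records["sex"].isin(["male", "female"]), "sex must be male|female")
    check(~records["session"].isin(["t1", "t2"]), "session must be t1|t2")
    check(pd.to_numeric(records["age"], errors="coerce") < 0, "age must be non-negative")
    for task_id in TASK_IDS:
        err_col = f"{task_id}_errors"
        if err_col in records.columns:
            check(pd.to_numeric(records[err_col], errors="coerce") < 0,
                  f"{err_col} must be non-negative")
        if task_id == "long_jump":
            for i in (1, 2, 3):
                col = f"long_jump_d{i}"
                if col in records.columns:
                    check(pd.to_numeric(records[col], errors="coerce") < 0,
                          f"{col} must be non-negative")
        else:
            col = f"{task_id}_value"
            if col in records.columns:
                check(pd.to_numeric(records[col], errors="coerce") <= 0,
                      f"{col} must be positive")
    if problems:
        raise SchemaError("; ".join(problems))


def read_records(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path)
    validate_records(records)
    for i in (1, 2, 3):
        col = f"long_jump_valid{i}"
        if col in records.columns:
            records[col] = records[col].astype(bool)
    return records


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def write_forms(forms: list[ScoringForm], path: str | Path) -> None:
    """Serialize scoring forms as one versioned JSON document.

    Floats survive the round trip bit-exactly (repr-based JSON encoding).
    """
    payload = {"schema_version": 1, "forms": [f.to_dict() for f in forms]}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_forms(path: str | Path) -> list[ScoringForm]:
    payload = json.loads(Path(path).read_text())
    return [ScoringForm.from_dict(f) for f in payload["forms"]]


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, artifacts: dict[str, Path]) -> None:
    """Record run configuration and artifact checksums for reproducibility."""
    from ccakit import __version__

    base = Path(path).parent
    manifest = {
        "package_version": __version__,
        "config": config,
        "artifacts": {
            # paths relative to the manifest so seeded runs are byte-identical
            name: {"path": str(Path(p).relative_to(base)), "sha256": sha256_file(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
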