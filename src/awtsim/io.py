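"""File I/O for trial-record tables and run reports.

Trial records travel as UTF-8 CSV with a header row and '.' decimals;
reports as JSON. Reads are schema-checked so a corrupt or truncated file
fails loudly, naming the missing column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TRIAL_RECORD_COLUMNS",
    "write_trial_records",
    "read_trial_records",
    "write_report",
    "read_report",
]

REPORT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A persisted table or report does not match the expected schema."""


#: Required columns of a trial-record table (a session table plus responses).
TRIAL_RECORD_COLUMNS: tuple[str, ...] = (
    "subject",
    "trial_id",
    "meridian",
    "meridian_class",
    "separation_deg",
    "cue_validity",
    "cue_meridian",
    "cue_separation_deg",
    "soa_ms",
    "complexity",
    "stimulus_a",
    "stimulus_b",
    "target_count_a",
    "target_count_b",
    "reported_count_a",
    "reported_count_b",
    "correct",
)

_SESSION_ONLY = TRIAL_RECORD_COLUMNS[1:-3]


def write_trial_records(records: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(records).to_csv(path, index=False, encoding="utf-8")


def read_trial_records(path: str | Path, require_responses: bool = True) -> pd.DataFrame:
    """Read a trial-record (or bare session) CSV, validating the schema."""
    df = pd.read_csv(path, encoding="utf-8")
    required = TRIAL_RECORD_COLUMNS if require_responses else _SESSION_ONLY
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if require_responses:
        df["correct"] = df["correct"].astype(bool)
        bad = df.index[
            df["correct"]
            != (
                (df["reported_count_a"] == df["target_count_a"])
                & (df["reported_count_b"] == df["target_count_b"])
            )
        ]
        if len(bad):
            raise SchemaError(
                f"{path}: row {int(bad[0]) + 2} has a 'correct' flag inconsistent "
                "with the reported counts"
            )
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **_jsonable(report)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_report(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    version = payload.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported report schema version {version!r} "
            f"(expected {REPORT_SCHEMA_VERSION})"
        )
    return payload
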