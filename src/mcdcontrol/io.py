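"""Trial-table and result-file input/output.

The interchange format is a plain CSV with a fixed header::

    subject, trial, condition, vr0_a, vr0_b, vcr0_a, vcr0_b,
    choice, rt_s, confidence, effort, vr1_a, vr1_b, vcr1_a, vcr1_b

Conditions are lowercase strings (``neutral``/``consequential``/
``penalized``).  Post-choice columns may be absent as a block, in which
case the table is flagged pre-only.  Fit results and reports are JSON.
Every written file embeds a schema version; readers reject a different
major version.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import Condition
from .observation import TrialRecord

__all__ = [
    "SCHEMA_VERSION",
    "TrialTableError",
    "read_trials",
    "write_trials",
    "row_to_record",
    "frame_to_records",
    "write_json",
    "read_json",
]

SCHEMA_VERSION = "1.0"

PRE_COLUMNS = ["subject", "trial", "condition", "vr0_a", "vr0_b", "vcr0_a", "vcr0_b"]
POST_COLUMNS = ["choice", "rt_s", "confidence", "effort", "vr1_a", "vr1_b", "vcr1_a", "vcr1_b"]
ALL_COLUMNS = PRE_COLUMNS + POST_COLUMNS

_RATING_COLUMNS = ["vr0_a", "vr0_b", "vcr0_a", "vcr0_b",
                   "confidence", "effort", "vr1_a", "vr1_b", "vcr1_a", "vcr1_b"]
_CONDITIONS = {c.value for c in Condition}


class TrialTableError(ValueError):
    """A trial table failed schema validation."""


def read_trials(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trial table.

    Checks the header, rating ranges, condition labels, choice codes and
    response-time positivity, reporting offending rows by line number
    (header = line 1).  Returns the table with a ``pre_only`` attribute in
    ``DataFrame.attrs`` when the post-choice block is absent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PRE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing required columns {missing}")
    have_post = [c for c in POST_COLUMNS if c in df.columns]
    pre_only = not have_post
    if have_post and len(have_post) != len(POST_COLUMNS):
        raise TrialTableError(
            f"{path}: post-choice columns must be all present or all absent; "
            f"found only {have_post}"
        )

    errors = []

    def _line(i) -> int:
        return int(i) + 2  # header + 1-based

    bad_cond = ~df["condition"].isin(_CONDITIONS)
    for i in df.index[bad_cond]:
        errors.append(f"line {_line(i)}: unknown condition {df.at[i, 'condition']!r}")
    for col in _RATING_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~((vals >= 0) & (vals <= 1)) & vals.notna()
        for i in df.index[bad]:
            errors.append(f"line {_line(i)}: column {col}={df.at[i, col]} outside [0, 1]")
        nan = vals.isna() & df[col].notna()
        for i in df.index[nan]:
            errors.append(f"line {_line(i)}: column {col}={df.at[i, col]!r} not numeric")
    if not pre_only:
        bad = ~df["choice"].isin(["a", "b"])
        for i in df.index[bad]:
            errors.append(f"line {_line(i)}: choice must be 'a' or 'b', got {df.at[i, 'choice']!r}")
        rt = pd.to_numeric(df["rt_s"], errors="coerce")
        bad = ~(rt > 0)
        for i in df.index[bad]:
            errors.append(f"line {_line(i)}: rt_s={df.at[i, 'rt_s']!r} must be positive")
    if errors:
        head = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise TrialTableError(f"{path}: {len(errors)} validation error(s)\n  {head}{more}")

    df["subject"] = df["subject"].astype(str)
    df.attrs["pre_only"] = pre_only
    df.attrs["schema_version"] = SCHEMA_VERSION
    return df


def write_trials(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trial table in the canonical column order."""
    path = Path(path)
    cols = [c for c in ALL_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def row_to_record(row: pd.Series) -> TrialRecord:
    """Convert one trial-table row into a :class:`TrialRecord`."""

    def _opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    return TrialRecord(
        subject=str(row["subject"]),
        trial=int(row["trial"]),
        condition=Condition(row["condition"]),
        vr0_a=float(row["vr0_a"]),
        vr0_b=float(row["vr0_b"]),
        vcr0_a=float(row["vcr0_a"]),
        vcr0_b=float(row["vcr0_b"]),
        choice=_opt("choice"),
        rt=float(row["rt_s"]) if _opt("rt_s") is not None else None,
        confidence_obs=_opt("confidence"),
        effort_obs=_opt("effort"),
        vr1_a=_opt("vr1_a"),
        vr1_b=_opt("vr1_b"),
        vcr1_a=_opt("vcr1_a"),
        vcr1_b=_opt("vcr1_b"),
    )


def frame_to_records(df: pd.DataFrame) -> list:
    """All rows of a trial table as :class:`TrialRecord` objects."""
    return [row_to_record(row) for _, row in df.iterrows()]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj: dict, path: Union[str, Path]) -> None:
    """Write a JSON document with the schema version stamped in."""
    doc = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(doc, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: Union[str, Path]) -> dict:
    """Read a JSON document, rejecting a mismatched major schema version."""
    doc = json.loads(Path(path).read_text())
    ver = str(doc.get("schema_version", "0"))
    if ver.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise TrialTableError(
            f"{path}: schema version {ver} incompatible with {SCHEMA_VERSION}"
        )
    return doc
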