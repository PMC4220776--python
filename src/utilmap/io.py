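"""Cohort file I/O: delimited text with a documented schema.

A cohort file is comma- (or tab-) separated with one row per patient.  The
recognised columns are ``patient_id``, demographics (``age``, ``sex``,
``site``, ``stage``, ``ecog``), the 27 FACT-G item columns ``GP1..GP7,
GS1..GS7, GE1..GE6, GF1..GF7``, domain scores (``pwb, swb, ewb, fwb,
factg``) and utilities (``eq5d``, ``sf6d``).  Missing values are empty cells
("NA" is accepted on read).  Metadata written by this package is embedded as
``# key: value`` comment lines before the header and round-trips through
``DataFrame.attrs``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import ITEM_CODES

__all__ = ["CohortFileSchema", "load_cohort", "write_cohort"]

_NUMERIC_RANGES = {
    "age": (0.0, 130.0),
    "stage": (1, 4),
    "ecog": (0, 3),
    "pwb": (0, 28), "swb": (0, 28), "ewb": (0, 24), "fwb": (0, 28),
    "factg": (0, 108),
    "eq5d": (-1.0, 1.0),
    "sf6d": (-1.0, 1.0),
}
for _code in ITEM_CODES:
    _NUMERIC_RANGES[_code] = (0, 4)

_CATEGORICAL = {
    "sex": {"female", "male"},
    "site": {"breast", "colorectal", "lung"},
}


@dataclass(frozen=True)
class CohortFileSchema:
    """Declared columns of a cohort file; unknown columns are passed through."""

    required: tuple[str, ...] = ("patient_id",)
    missing_tokens: tuple[str, ...] = ("", "NA")
    delimiter: str = ","

    def validate_header(self, columns: Sequence[str]) -> None:
        missing = [c for c in self.required if c not in columns]
        if missing:
            raise ValueError(f"cohort header lacks required columns: {missing}")


def load_cohort(
    path, schema: Optional[CohortFileSchema] = None
) -> tuple[pd.DataFrame, dict]:
    """Read a cohort file; returns (frame, report).

    Rows with out-of-range or unparseable values in a recognised column are
    rejected; the report lists their 1-based line numbers, the per-column
    missing counts and any file metadata.
    """
    schema = schema or CohortFileSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    header_at = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            if ":" in text:
                key, _, value = text.partition(":")
                metadata[key.strip()] = value.strip()
            header_at = i + 1
        else:
            break
    body = "".join(lines[header_at:])
    if not body.strip():
        raise ValueError(f"{path}: no header/data rows")
    df = pd.read_csv(
        _io.StringIO(body),
        sep=schema.delimiter,
        dtype=str,
        keep_default_na=False,
    )
    schema.validate_header(df.columns)

    bad_lines: list[int] = []
    missing_counts: dict[str, int] = {}
    for col in df.columns:
        raw = df[col].astype(str).str.strip()
        is_missing = raw.isin(schema.missing_tokens)
        missing_counts[col] = int(is_missing.sum())
        if col in _NUMERIC_RANGES:
            values = pd.to_numeric(raw.where(~is_missing), errors="coerce")
            lo, hi = _NUMERIC_RANGES[col]
            invalid = (~is_missing) & (values.isna() | (values < lo) | (values > hi))
            df[col] = values.where(~invalid)
            bad_lines.extend(df.index[invalid])
        elif col in _CATEGORICAL:
            norm = raw.str.lower()
            invalid = (~is_missing) & ~norm.isin(_CATEGORICAL[col])
            df[col] = norm.where(~is_missing & ~invalid)
            bad_lines.extend(df.index[invalid])
        else:
            df[col] = raw.where(~is_missing)

    bad_rows = sorted(set(bad_lines))
    if bad_rows:
        df = df.drop(index=bad_rows).reset_index(drop=True)
    # data line numbers: 1-based, counting metadata and header lines
    report = {
        "n_rows": len(df),
        "n_rejected": len(bad_rows),
        "rejected_lines": [header_at + 2 + r for r in bad_rows],
        "missing_counts": missing_counts,
        "metadata": metadata,
    }
    df.attrs.update(metadata)
    return df, report


def write_cohort(
    df: pd.DataFrame, path, metadata: Optional[dict] = None, delimiter: str = ","
) -> None:
    """Write a cohort with ``# key: value`` metadata comment lines."""
    path = Path(path)
    meta = dict(df.attrs)
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=delimiter, index=False, na_rep="")
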