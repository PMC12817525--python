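"""Tabular I/O contracts for cohort tables and score tables.

All files are UTF-8 CSV with a header row; months are decimals, flags are
0/1, percentages live on the 0–100 scale.  Truth-mode cohort tables carry
an integrity checksum in a leading ``#``-comment so that
round-tripping through disk preserves the tamper check.  CIWS values may be
written in the conventional "5+" notation and are parsed back to integers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import pandas as pd

from .scoring import parse_score
from .synthetic import TRUTH_COLUMNS, _truth_checksum

__all__ = ["read_cohort", "write_cohort", "read_drug_assays", "SchemaError"]

PathLike = Union[str, Path]

#: Columns every cohort table must provide.
REQUIRED_COLUMNS = (
    "patient_id",
    "timepoint",
    "dfs_months",
    "dfs_event",
    "os_months",
    "os_event",
)

_FLAG_COLUMNS = (
    "dfs_event",
    "os_event",
    "new_lesions",
    "target_lesions_vanished",
    "viable_after_3wk",
    "growth_sustained",
)

_NONNEGATIVE_COLUMNS = (
    "dfs_months",
    "os_months",
    "baseline_sld_mm",
    "nadir_sld_mm",
    "current_sld_mm",
    "cluster_diameter_um",
)

_KNOWN_PREFIXES = ("cir_treated_", "cir_control", "scir_")
_KNOWN_COLUMNS = set(REQUIRED_COLUMNS) | set(_FLAG_COLUMNS) | set(_NONNEGATIVE_COLUMNS) | {
    "days_to_formation",
    "edu_fraction",
    "recist_nat",
    "recist_at5y",
    "ciws",
    "ofp_grade",
    "growth_group",
} | set(TRUTH_COLUMNS)


class SchemaError(ValueError):
    """A cohort file violates the tabular contract."""


def _check_schema(df: pd.DataFrame, source: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns: {', '.join(missing)}")
    unknown = [
        c
        for c in df.columns
        if c not in _KNOWN_COLUMNS and not any(c.startswith(p) for p in _KNOWN_PREFIXES)
    ]
    if unknown:
        warnings.warn(f"{source}: ignoring unknown columns: {', '.join(unknown)}")
    for col in _NONNEGATIVE_COLUMNS:
        if col in df.columns:
            bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise SchemaError(
                    f"{source}: negative {col} at data row(s) {[int(i) + 2 for i in bad]}"
                )
    for col in _FLAG_COLUMNS:
        if col in df.columns:
            values = set(pd.Series(df[col]).dropna().unique())
            if not values <= {0, 1, True, False}:
                raise SchemaError(f"{source}: flag column {col} must be 0/1")


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Restores the truth-mode attrs (and checksum) written by
    :func:`write_cohort`; parses "5+"-notation CIWS columns to integers.
    """
    path = Path(path)
    checksum = None
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# truth_checksum:"):
        checksum = first.split(":", 1)[1].strip()
        skip = 1
    df = pd.read_csv(path, skiprows=skip)
    _check_schema(df, str(path))
    if "ciws" in df.columns:
        df["ciws"] = df["ciws"].map(parse_score)
    if all(c in df.columns for c in TRUTH_COLUMNS):
        df.attrs["truth_mode"] = True
        df.attrs["truth_checksum"] = checksum if checksum else _truth_checksum(df)
    return df


def write_cohort(df: pd.DataFrame, path: PathLike) -> None:
    """Write a cohort table to CSV, preserving the truth checksum if present."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        checksum = df.attrs.get("truth_checksum")
        if checksum and all(c in df.columns for c in TRUTH_COLUMNS):
            fh.write(f"# truth_checksum: {checksum}\n")
        df.to_csv(fh, index=False)


def read_drug_assays(path: PathLike) -> pd.DataFrame:
    """Read a long-format drug-assay CSV.

    Expected columns: patient_id, timepoint, drug_id, and either
    cir_treated + cir_control or a pre-computed scir column.
    """
    df = pd.read_csv(path)
    needed = {"patient_id", "timepoint", "drug_id"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(needed)}")
    has_raw = {"cir_treated", "cir_control"} <= set(df.columns)
    if not has_raw and "scir" not in df.columns:
        raise SchemaError(f"{path}: need cir_treated+cir_control or scir")
    return df
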