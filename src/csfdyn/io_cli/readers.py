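"""Readers and writers for the plain-text formats the pipeline touches."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._trace import PressureTrace
from ..errors import ContractError, FormatError
from .dialects import TraceFileDialect

__all__ = [
    "read_pressure_trace",
    "write_pressure_trace",
    "read_sample_table",
    "write_sample_table",
    "read_cohort_table",
]

SAMPLE_TABLE_KEY = ("animal_id", "assay", "field", "replicate")


def read_pressure_trace(path, dialect: TraceFileDialect | None = None) -> PressureTrace:
    """Read a delimited pressure log into a :class:`PressureTrace`.

    Times are normalized to seconds from trace start; the sampling rate is
    inferred as the reciprocal of the median successive time delta. Rows
    whose pressure field is non-numeric are flagged in the mask (NaN
    pressure), never dropped; a malformed time field or row is a
    :class:`FormatError` naming the line.
    """
    dialect = dialect or TraceFileDialect()
    times: list[float] = []
    pressures: list[float] = []
    mask: list[bool] = []
    ncol = max(dialect.time_column, dialect.pressure_column) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= dialect.header_rows:
                continue
            line = line.strip()
            if not line:
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) < ncol:
                raise FormatError(f"{path}: line {lineno}: expected >= {ncol} fields, got {len(parts)}")
            try:
                t = dialect.parse_number(parts[dialect.time_column])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: unparseable time field "
                                  f"{parts[dialect.time_column]!r}") from None
            try:
                p = dialect.parse_number(parts[dialect.pressure_column])
                ok = np.isfinite(p)
            except ValueError:
                p, ok = np.nan, False
            times.append(t)
            pressures.append(p)
            mask.append(ok)
    if len(times) < 2:
        raise FormatError(f"{path}: need at least 2 numeric rows, got {len(times)}")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise ContractError(f"{path}: time column is not strictly increasing")
    fs = 1.0 / float(np.median(np.diff(t)))
    # snap to the uniform grid implied by the inferred rate
    t_uniform = np.arange(len(t)) / fs
    if np.max(np.abs((t - t[0]) - t_uniform)) > 0.1 / fs:
        raise ContractError(f"{path}: timestamps deviate grossly from a uniform grid")
    return PressureTrace(t=t_uniform, p=np.asarray(pressures), fs=fs, mask=np.asarray(mask))


def write_pressure_trace(trace: PressureTrace, path, dialect: TraceFileDialect | None = None) -> None:
    """Write a trace in the same delimited layout :func:`read_pressure_trace` reads."""
    dialect = dialect or TraceFileDialect()
    with open(path, "w") as fh:
        for t, p, ok in zip(trace.t, trace.p, trace.mask):
            val = f"{p:.12g}" if ok and np.isfinite(p) else "NaN"
            fh.write(f"{t:.9f}{dialect.delimiter}{val}\n")


def read_sample_table(path) -> pd.DataFrame:
    """Read a long-format sample table (CSV).

    Requires ``animal_id`` and ``group`` columns; unit strings are
    preserved as text. When the full (animal_id, assay, field, replicate)
    key is present, duplicates are an error.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str}, keep_default_na=False)
    for col in ("animal_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["animal_id"].eq("").any():
        raise FormatError(f"{path}: empty animal_id")
    if all(c in df.columns for c in SAMPLE_TABLE_KEY):
        dup = df.duplicated(subset=list(SAMPLE_TABLE_KEY))
        if dup.any():
            raise FormatError(
                f"{path}: duplicate (animal_id, assay, field, replicate) rows at "
                f"{list(df.index[dup])}"
            )
    if "value" in df.columns:
        df["value"] = pd.to_numeric(df["value"])
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort table CSV (animal_id, group, measure, value[, unit])."""
    df = read_sample_table(path)
    for col in ("measure", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if not np.isfinite(df["value"]).all():
        raise FormatError(f"{path}: non-finite values in cohort table")
    return df
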