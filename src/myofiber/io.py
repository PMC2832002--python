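"""Plain-text readers and writers.

Force traces are stored as two-column delimited text (``time_s``,
``force_mN_per_mm2``) preceded by ``#``-prefixed header lines carrying a
JSON metadata block (fiber id, surgery group, protocol, pCa, added Pi/ADP,
sampling rate). Measurement tables are TSV/CSV with explicit units in the
column names (``ca_uM``, ``pi_mM``).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TraceFormatError
from .trace import ForceTrace

__all__ = ["read_trace", "write_trace", "read_measurements"]

_META_PREFIX = "# meta: "
#: relative tolerance on sampling-interval uniformity
_UNIFORMITY_TOL = 0.01

_META_FIELDS = ("fiber_id", "group", "protocol", "pCa", "pi_mM", "adp_mM", "rate_hz")


def write_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a trace as two-column TSV with a JSON metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_META_PREFIX + json.dumps(trace.metadata(), sort_keys=True) + "\n")
        fh.write("time_s\tforce_mN_per_mm2\n")
        for t, f in zip(trace.time_s, trace.force):
            fh.write(f"{t:.6f}\t{f:.9g}\n")
    return path


def read_trace(path: str | Path, check_uniform: bool = True) -> ForceTrace:
    """Parse a trace file, validating columns and sampling uniformity.

    Raises :class:`TraceFormatError` naming the offending line for malformed
    headers or columns, and when the timestamps disagree with the declared
    sampling rate by more than 1%.
    """
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    with path.open() as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            header_lines += 1
            if line.startswith(_META_PREFIX):
                try:
                    meta = json.loads(line[len(_META_PREFIX):])
                except json.JSONDecodeError as exc:
                    raise TraceFormatError(
                        f"{path}: line {header_lines}: bad JSON metadata ({exc})"
                    ) from exc
        else:
            break
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#")
    except Exception as exc:
        raise TraceFormatError(f"{path}: cannot parse table: {exc}") from exc
    for col in ("time_s", "force_mN_per_mm2"):
        if col not in df.columns:
            raise TraceFormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    f = df["force_mN_per_mm2"].to_numpy(dtype=float)
    if t.size < 2:
        raise TraceFormatError(f"{path}: trace needs at least 2 samples")
    extra = {k: v for k, v in meta.items() if k not in _META_FIELDS}
    trace = ForceTrace(
        time_s=t,
        force=f,
        protocol_kind=meta.get("protocol", "CA_JUMP"),
        fiber_id=str(meta.get("fiber_id", path.stem)),
        group=str(meta.get("group", "")),
        pCa=float(meta.get("pCa", 4.5)),
        pi_mM=float(meta.get("pi_mM", 0.0)),
        adp_mM=float(meta.get("adp_mM", 0.0)),
        rate_hz=float(meta.get("rate_hz", 0.0) or _infer_rate(t)),
        extra=extra,
    )
    if check_uniform:
        dt = np.diff(t)
        if dt.size and (np.max(dt) - np.min(dt)) > _UNIFORMITY_TOL * np.mean(dt):
            raise TraceFormatError(f"{path}: sampling is non-uniform beyond 1%")
        declared = trace.rate_hz
        if declared > 0 and abs(1.0 / np.mean(dt) - declared) > _UNIFORMITY_TOL * declared:
            raise TraceFormatError(
                f"{path}: declared rate {declared} Hz disagrees with timestamps"
            )
    return trace


def _infer_rate(t: np.ndarray) -> float:
    dt = float(np.mean(np.diff(t)))
    return 1.0 / dt if dt > 0 else 0.0


def read_measurements(
    path: str | Path, required: Sequence[str] = ()
) -> pd.DataFrame:
    """Read a TSV/CSV measurement table, validating required columns.

    Unknown columns are preserved. Raises :class:`SchemaError` for an empty
    file or missing required columns; rows with non-numeric values in a
    required numeric column are reported by index in the error message.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in required:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.notna().all():
                df[col] = coerced
            elif col not in ("fiber_id", "group", "sample_id", "condition"):
                bad = df.index[coerced.isna()].tolist()
                raise SchemaError(
                    f"{path}: non-numeric values in column {col!r} at rows {bad}"
                )
    if {"fiber_id", "condition"}.issubset(df.columns):
        dup = df.duplicated(subset=["fiber_id", "condition"])
        if dup.any():
            import warnings

            warnings.warn(
                f"{path}: duplicated fiber_id+condition rows: "
                f"{df.index[dup].tolist()}",
                stacklevel=2,
            )
    return df
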