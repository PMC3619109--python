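"""Series and report readers/writers shared by the CLI and the library.

Series interchange is plain CSV (single numeric column, optional header, or a
multi-column CSV with a ``value`` column); structured reports are JSON with
full float precision, or CSV for the tabular parts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .harness import BandSummary, BatteryReport
from .synthesis import Waveform

__all__ = ["read_series", "write_report", "to_jsonable", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


class SeriesParseError(ValueError):
    """Raised when a series file cannot be parsed; names the offending row."""


def read_series(path: str | Path) -> Waveform:
    """Read a waveform from a CSV or whitespace-delimited text file.

    Accepts one numeric value per row; a single header row is allowed.  A
    multi-column CSV must provide a ``value`` column.  Parsing is strict: any
    non-numeric cell raises :class:`SeriesParseError` naming the 1-based row.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    rows = [(i, ln) for i, ln in enumerate(lines, start=1) if ln]
    if not rows:
        raise SeriesParseError(f"{path}: file contains no data")

    def split(line: str) -> list[str]:
        return [f.strip() for f in (line.split(",") if "," in line else line.split())]

    first_fields = split(rows[0][1])
    col = 0
    start = 0
    header_is_numeric = True
    try:
        [float(f) for f in first_fields]
    except ValueError:
        header_is_numeric = False
    if not header_is_numeric:
        start = 1
        if len(first_fields) > 1:
            lowered = [f.lower() for f in first_fields]
            if "value" not in lowered:
                raise SeriesParseError(
                    f"{path}: multi-column file needs a 'value' column, "
                    f"got {first_fields}")
            col = lowered.index("value")
        if start >= len(rows):
            raise SeriesParseError(f"{path}: no data rows after the header")

    samples = np.empty(len(rows) - start)
    for j, (rownum, line) in enumerate(rows[start:]):
        fields = split(line)
        if col >= len(fields):
            raise SeriesParseError(f"{path}: row {rownum} has no column {col + 1}")
        try:
            samples[j] = float(fields[col])
        except ValueError:
            raise SeriesParseError(
                f"{path}: non-numeric value {fields[col]!r} at row {rownum}") from None
    return Waveform(samples, label=path.stem, generator=f"file({path.name})")


def to_jsonable(obj: Any) -> Any:
    """Recursively convert report objects to JSON-serializable structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        out["_type"] = type(obj).__name__
        return out
    if isinstance(obj, pd.DataFrame):
        return [to_jsonable(rec) for rec in obj.to_dict(orient="records")]
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, dict):
        return {_key(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if obj != obj else ("inf" if obj > 0 else "-inf")
    return obj


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return "/".join(str(x) for x in k)
    return str(k)


def write_report(report: Any, path: str | Path, format: str = "json") -> None:
    """Write a report (battery, band summary, or any estimate record).

    JSON keeps full float precision (repr round-trip); CSV writes the tabular
    part with '.' decimals and no thousands separators.
    """
    path = Path(path)
    if format == "json":
        payload = {"schema_version": SCHEMA_VERSION, "report": to_jsonable(report)}
        path.write_text(json.dumps(payload, indent=2, allow_nan=False) + "\n")
    elif format == "csv":
        frame = _as_frame(report)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; use 'json' or 'csv'")


def _as_frame(report: Any) -> pd.DataFrame:
    if isinstance(report, (BatteryReport, BandSummary)):
        return report.table
    if isinstance(report, pd.DataFrame):
        return report
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        flat = to_jsonable(report)
        flat.pop("_type", None)
        scalar = {k: v for k, v in flat.items() if np.isscalar(v) or v is None}
        return pd.DataFrame([scalar])
    raise ValueError(f"cannot render {type(report).__name__} as CSV")
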