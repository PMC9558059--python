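"""Reading and writing right-censored survival tables and run reports.

The on-disk format is a delimited text table with a ``time`` column
(positive reals) and an ``event`` column (1 = observed failure,
0 = right-censored); comma and tab dialects are auto-detected.  Reports are
plain JSON with deterministic key ordering so runs can be diffed.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .likelihood import SurvivalRecords

__all__ = ["read_survival_csv", "write_survival_csv", "write_report"]


class SurvivalParseError(ValueError):
    """Malformed survival table; the message names the offending row."""


def read_survival_csv(path) -> SurvivalRecords:
    """Read a (time, event) table; comma or tab delimited, header required."""
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    if reader.fieldnames is None or not {"time", "event"} <= set(reader.fieldnames):
        raise SurvivalParseError(
            f"{path}: header must contain 'time' and 'event' columns, "
            f"got {reader.fieldnames}"
        )
    times, events = [], []
    for i, row in enumerate(reader, start=2):  # row 1 is the header
        try:
            t = float(row["time"])
        except (TypeError, ValueError):
            raise SurvivalParseError(f"{path}: row {i}: time {row['time']!r} is not a number")
        if not (t > 0.0 and np.isfinite(t)):
            raise SurvivalParseError(f"{path}: row {i}: time must be a positive real, got {t}")
        ev = (row["event"] or "").strip()
        if ev not in ("0", "1"):
            raise SurvivalParseError(f"{path}: row {i}: event must be 0 or 1, got {ev!r}")
        times.append(t)
        events.append(int(ev))
    if not times:
        raise SurvivalParseError(f"{path}: no data rows")
    return SurvivalRecords(np.array(times), np.array(events))


def write_survival_csv(d: SurvivalRecords, path) -> None:
    """Write records as comma-delimited text; round-trips bit-exactly."""
    path = Path(path)
    lines = ["time,event"]
    for t, e in zip(d.times, d.events):
        lines.append(f"{float(t)!r},{int(e)}")
    path.write_text("\n".join(lines) + "\n")


def write_report(payload: dict, path) -> None:
    """JSON report with sorted keys and a trailing newline (diff-friendly)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_coerce) + "\n")


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
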