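"""Reading and writing the wristband CSV dialect and cohort tables.

``EDA.csv``: first row UNIX start time, second row sampling rate (Hz),
then one conductance sample (uS) per row.  ``IBI.csv``: first row UNIX
start time, then rows of ``offset_seconds,interval_seconds``.  Intervals
are converted to milliseconds in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eda import EDATrace
from .errors import PipelineError, ValidationError
from .hrv import IBISeries

__all__ = [
    "read_eda_csv",
    "write_eda_csv",
    "read_ibi_csv",
    "write_ibi_csv",
    "session_dirs",
]


def read_eda_csv(path: str | Path) -> EDATrace:
    path = Path(path)
    if not path.exists():
        raise PipelineError("read", f"missing EDA file: {path}", offending=str(path))
    raw = np.loadtxt(path, delimiter=",", dtype=float, ndmin=1)
    if raw.size < 2:
        raise ValidationError(f"{path}: expected start time, rate and samples")
    return EDATrace(start_time=float(raw[0]), fs=float(raw[1]), values=raw[2:])


def write_eda_csv(trace: EDATrace, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"{trace.start_time:.6f}\r\n{trace.fs:.6f}\r\n")
        fh.writelines(f"{x:.6f}\r\n" for x in trace.values)


def read_ibi_csv(path: str | Path) -> IBISeries:
    path = Path(path)
    if not path.exists():
        raise PipelineError("read", f"missing IBI file: {path}", offending=str(path))
    with open(path) as fh:
        first = fh.readline().strip()
        body = np.loadtxt(fh, delimiter=",", dtype=float, ndmin=2)
    if body.size == 0:
        body = body.reshape(0, 2)
    return IBISeries(
        start_time=float(first.split(",")[0]),
        offsets=body[:, 0],
        intervals=body[:, 1] * 1000.0,
    )


def write_ibi_csv(series: IBISeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"{series.start_time:.6f}\r\n")
        fh.writelines(
            f"{off:.6f},{iv / 1000.0:.6f}\r\n"
            for off, iv in zip(series.offsets, series.intervals)
        )


def session_dirs(root: str | Path) -> list[tuple[str, str, Path]]:
    """Enumerate ``(participant_id, phase, dir)`` under a cohort directory."""
    root = Path(root)
    out = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for phdir in sorted(q for q in pdir.iterdir() if q.is_dir()):
            out.append((pdir.name, phdir.name, phdir))
    return out


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PipelineError("read", f"missing table: {path}", offending=str(path))
    return pd.read_csv(path)
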