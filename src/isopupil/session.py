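"""Session data model and CSV I/O for eye-tracker pupil traces.

A session is a ~90 Hz binocular recording of pupil diameter (mm), eye
openness and gaze position. The canonical on-disk format is a plain CSV
with header ``t_s,left_mm,right_mm,left_open,right_open,gaze_x,gaze_y``;
vendor exports with different column names or millisecond timestamps are
mapped through :class:`ColumnMap`.

Missing values are encoded as empty cells and represented as NaN in
memory. A *zero* diameter is deliberately preserved as the literal value
0.0 rather than converted to missing: the artifact detector's zero-value
rule consumes it downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyTraceError, TraceFormatError

log = logging.getLogger(__name__)

#: Canonical column order of the session CSV format.
CANONICAL_COLUMNS = (
    "t_s",
    "left_mm",
    "right_mm",
    "left_open",
    "right_open",
    "gaze_x",
    "gaze_y",
)

#: Physically plausible pupil diameter ceiling (mm); zero is allowed as the
#: sensor-dropout encoding.
MAX_DIAMETER_MM = 12.0


@dataclass(frozen=True)
class PupilSample:
    """One binocular sample. NaN marks a missing field."""

    t: float
    left_mm: float = np.nan
    right_mm: float = np.nan
    left_open: float = np.nan
    right_open: float = np.nan
    gaze_x: float = np.nan
    gaze_y: float = np.nan


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names onto the column names of a vendor export.

    Parameters
    ----------
    time_unit:
        ``"s"`` or ``"ms"``; timestamps are converted to seconds from the
        first sample on read.
    """

    t: str = "t_s"
    left_mm: str = "left_mm"
    right_mm: str = "right_mm"
    left_open: str = "left_open"
    right_open: str = "right_open"
    gaze_x: str = "gaze_x"
    gaze_y: str = "gaze_y"
    time_unit: str = "s"

    def __post_init__(self) -> None:
        if self.time_unit not in ("s", "ms"):
            raise ConfigError(f"time_unit must be 's' or 'ms', got {self.time_unit!r}")


@dataclass
class SessionTrace:
    """Ordered binocular pupil samples for one recording session.

    ``data`` holds the canonical columns; timestamps are seconds from the
    first sample and strictly increasing.
    """

    data: pd.DataFrame
    session_id: str = "session"
    nominal_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise TraceFormatError(f"trace missing columns: {missing}")
        if len(self.data) < 2:
            raise EmptyTraceError(f"trace has {len(self.data)} samples; need >= 2")
        t = self.data["t_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise TraceFormatError("timestamps must be strictly increasing")
        if t[0] < 0:
            raise TraceFormatError("timestamps must be non-negative")
        for col in ("left_mm", "right_mm"):
            v = self.data[col].to_numpy(float)
            bad = np.isfinite(v) & ((v < 0) | (v >= MAX_DIAMETER_MM))
            if bad.any():
                raise TraceFormatError(
                    f"{col}: {int(bad.sum())} values outside [0, {MAX_DIAMETER_MM}) mm"
                )
        for col in ("left_open", "right_open"):
            v = self.data[col].to_numpy(float)
            bad = np.isfinite(v) & ((v < 0) | (v > 1))
            if bad.any():
                raise TraceFormatError(f"{col}: values outside [0, 1]")
        if self.nominal_rate_hz <= 0:
            self.nominal_rate_hz = float(1.0 / np.median(np.diff(t)))

    @property
    def t(self) -> np.ndarray:
        return self.data["t_s"].to_numpy(float)

    @property
    def duration_s(self) -> float:
        t = self.t
        return float(t[-1] - t[0])

    def __len__(self) -> int:
        return len(self.data)

    def samples(self) -> Iterator[PupilSample]:
        for row in self.data.itertuples(index=False):
            yield PupilSample(*row)


def read_session(
    path: str | Path,
    column_map: ColumnMap | None = None,
    session_id: str | None = None,
) -> SessionTrace:
    """Read a session CSV into a :class:`SessionTrace`.

    Rows whose timestamp does not strictly increase over the previous kept
    row are dropped and counted in a log message. Timestamps are shifted so
    the first sample is at t = 0.

    Raises
    ------
    TraceFormatError
        If a mapped column is absent.
    EmptyTraceError
        If fewer than two usable rows remain.
    """
    path = Path(path)
    cmap = column_map or ColumnMap()
    raw = pd.read_csv(path)
    rename = {}
    for f in fields(cmap):
        if f.name == "time_unit":
            continue
        src = getattr(cmap, f.name)
        if src not in raw.columns:
            raise TraceFormatError(f"column {src!r} not found in {path.name}")
        rename[src] = "t_s" if f.name == "t" else f.name
    df = raw.rename(columns=rename)[list(CANONICAL_COLUMNS)].astype(float)
    if cmap.time_unit == "ms":
        df["t_s"] = df["t_s"] / 1000.0
    t = df["t_s"].to_numpy()
    keep = np.ones(len(df), bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if not np.isfinite(ti) or ti <= last:
            keep[i] = False
        else:
            last = ti
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d rows with non-increasing timestamps", path.name, dropped)
    df = df.loc[keep].reset_index(drop=True)
    if len(df) < 2:
        raise EmptyTraceError(f"{path.name}: only {len(df)} usable rows")
    df["t_s"] = df["t_s"] - df["t_s"].iloc[0]
    return SessionTrace(df, session_id=session_id or path.stem)


def write_session(trace: SessionTrace, path: str | Path) -> None:
    """Write a trace as canonical CSV (6-decimal precision, NaN as empty)."""
    df = trace.data[list(CANONICAL_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def combine_eyes(trace: SessionTrace, mode: str = "mean") -> np.ndarray:
    """Reduce the binocular channels to one diameter series (mm).

    ``mode="mean"`` averages whichever eyes are valid at each sample and is
    NaN only where both are missing; ``"left"``/``"right"`` select one eye.
    """
    if mode == "left":
        return trace.data["left_mm"].to_numpy(float)
    if mode == "right":
        return trace.data["right_mm"].to_numpy(float)
    if mode != "mean":
        raise ConfigError(f"unknown eye-combination mode {mode!r}")
    both = trace.data[["left_mm", "right_mm"]].to_numpy(float)
    n_valid = np.isfinite(both).sum(axis=1)
    total = np.nansum(both, axis=1)
    return np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
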