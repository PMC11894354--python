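"""Reading, writing and artifact-filtering of interbeat-interval (IBI) and step streams.

An IBI stream is a sequence of ``(timestamp_ms, ibi_ms)`` samples: the
timestamp of a detected beat together with the interval since the previous
beat.  Wrist photoplethysmography (PPG) and chest ECG devices both export
this shape.  Step counts arrive as one integer per minute of wear.

Physiologically implausible beats — IBI above 1500 ms or below 300 ms —
are treated as detection artifacts and removed before any windowing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hrvgaps")

#: Artifact bounds, ms.  Values strictly below/above these are removed;
#: the boundary values themselves are kept.
ARTIFACT_LOW_MS = 300.0
ARTIFACT_HIGH_MS = 1500.0

DEVICES = ("ppg", "ecg")


class ParseError(ValueError):
    """A row in an input file could not be parsed."""


class EmptySeriesError(ValueError):
    """An input file contained no samples."""


class ValidationError(ValueError):
    """An input value violated a schema constraint."""


@dataclass
class IBISeries:
    """One participant x device stream of timestamped interbeat intervals.

    Parameters
    ----------
    participant_id : str
        Cohort identifier of the wearer.
    device : {"ppg", "ecg"}
        Sensing modality the stream came from.
    timestamps : ndarray of int64
        Beat times, epoch milliseconds (UTC), strictly increasing.
    ibi : ndarray of float
        Interbeat intervals in ms, one per beat, finite and positive.
    """

    participant_id: str
    device: str
    timestamps: np.ndarray
    ibi: np.ndarray

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValidationError(f"device must be one of {DEVICES}, got {self.device!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.ibi = np.asarray(self.ibi, dtype=float)
        if self.timestamps.shape != self.ibi.shape:
            raise ValidationError("timestamps and ibi must have equal length")
        if self.timestamps.size:
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if np.any(self.timestamps < 0):
                raise ValidationError("timestamps must be non-negative epoch ms")
            if not np.all(np.isfinite(self.ibi)) or np.any(self.ibi <= 0):
                raise ValidationError("ibi values must be finite and > 0")

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class StepSeries:
    """Per-minute step counts for one participant.

    ``minute_start`` values are epoch ms of the minute's start; minutes the
    device was not worn are simply absent (no imputation).
    """

    participant_id: str
    minute_start: np.ndarray
    steps: np.ndarray

    def __post_init__(self) -> None:
        self.minute_start = np.asarray(self.minute_start, dtype=np.int64)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if self.minute_start.shape != self.steps.shape:
            raise ValidationError("minute_start and steps must have equal length")
        if np.any(self.steps < 0):
            raise ValidationError("step counts must be >= 0")
        if self.minute_start.size and np.any(np.diff(self.minute_start) <= 0):
            order = np.argsort(self.minute_start, kind="stable")
            self.minute_start = self.minute_start[order]
            self.steps = self.steps[order]

    def __len__(self) -> int:
        return int(self.minute_start.size)


def _dedupe_sorted(t: np.ndarray, v: np.ndarray, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Sort by timestamp and collapse duplicate timestamps to the first occurrence."""
    order = np.argsort(t, kind="stable")
    if np.any(order != np.arange(t.size)):
        logger.warning("%s: samples out of order; sorting by timestamp", path)
    t, v = t[order], v[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    if not keep.all():
        logger.warning("%s: %d duplicate timestamps collapsed (kept first)", path, int((~keep).sum()))
    return t[keep], v[keep]


def read_ibi(path: str | Path, format: str = "csv", *,
             participant_id: str, device: str) -> IBISeries:
    """Read an IBI stream from a two-column CSV or a JSON array.

    CSV schema: header ``timestamp_ms,ibi_ms``.  JSON schema: an array of
    objects ``{"t": int, "ibi": float}``.  Rows are sorted by timestamp and
    duplicate timestamps collapsed to the first occurrence with a warning.

    Raises
    ------
    ParseError
        If a row is malformed (the message names the offending line).
    EmptySeriesError
        If the file holds no samples.
    """
    path = Path(path)
    if format == "csv":
        t, v = _read_two_col_csv(path, "timestamp_ms", "ibi_ms")
    elif format == "json":
        with open(path) as fh:
            try:
                rows = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        try:
            t = np.array([r["t"] for r in rows], dtype=np.int64)
            v = np.array([r["ibi"] for r in rows], dtype=float)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: JSON rows must be objects with 't' and 'ibi'") from exc
    else:
        raise ValidationError(f"unknown format {format!r} (expected 'csv' or 'json')")
    if t.size == 0:
        raise EmptySeriesError(f"{path}: no IBI samples")
    t, v = _dedupe_sorted(t, v, str(path))
    return IBISeries(participant_id=participant_id, device=device, timestamps=t, ibi=v)


def _read_two_col_csv(path: Path, c1: str, c2: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptySeriesError(f"{path}: empty file") from exc
    for col in (c1, c2):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    # to_numeric(coerce) only locates bad rows; the actual conversion goes
    # through numpy, whose parser is round-trip exact (to_numeric is not)
    bad = (pd.to_numeric(df[c1], errors="coerce").isna()
           | pd.to_numeric(df[c2], errors="coerce").isna())
    if bad.any():
        # +2: header line plus 1-based counting
        line = int(bad.idxmax()) + 2
        raise ParseError(f"{path}: malformed row at line {line}")
    return (df[c1].to_numpy().astype(float).astype(np.int64),
            df[c2].to_numpy().astype(float))


def write_ibi(series: IBISeries, path: str | Path, format: str = "csv") -> None:
    """Write an IBI stream; exact inverse of :func:`read_ibi` for valid series."""
    path = Path(path)
    if format == "csv":
        # %.17g guarantees bit-exact float round trips through the CSV
        pd.DataFrame({"timestamp_ms": series.timestamps,
                      "ibi_ms": series.ibi}).to_csv(path, index=False,
                                                    float_format="%.17g")
    elif format == "json":
        rows = [{"t": int(t), "ibi": float(v)}
                for t, v in zip(series.timestamps, series.ibi)]
        with open(path, "w") as fh:
            json.dump(rows, fh)
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_steps(path: str | Path, *, participant_id: str) -> StepSeries:
    """Read per-minute step counts from a CSV with header ``minute_start_ms,steps``.

    Missing minutes are preserved as gaps; negative counts are rejected.
    """
    path = Path(path)
    t, v = _read_two_col_csv(path, "minute_start_ms", "steps")
    if np.any(v < 0):
        raise ValidationError(f"{path}: negative step count")
    return StepSeries(participant_id=participant_id, minute_start=t,
                      steps=v.astype(np.int64))


def write_steps(series: StepSeries, path: str | Path) -> None:
    pd.DataFrame({"minute_start_ms": series.minute_start,
                  "steps": series.steps}).to_csv(Path(path), index=False)


def filter_artifacts(series: IBISeries) -> tuple[IBISeries, int]:
    """Remove artifact beats (IBI > 1500 ms or IBI < 300 ms).

    The bounds are strict, so beats at exactly 300 or 1500 ms survive.
    Surviving samples are returned bit-identical; the second element is the
    number removed.  Idempotent.
    """
    keep = (series.ibi >= ARTIFACT_LOW_MS) & (series.ibi <= ARTIFACT_HIGH_MS)
    filtered = IBISeries(participant_id=series.participant_id, device=series.device,
                         timestamps=series.timestamps[keep], ibi=series.ibi[keep])
    return filtered, int((~keep).sum())
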