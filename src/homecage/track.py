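"""Tracking-stream container and the plain-text track dialect.

A :class:`TrackStream` holds one animal's centre-of-gravity positions on a
regular grid at the nominal sample rate (15 Hz by default).  Samples where
the tracker lost the animal (in or under the shelter) carry
``detected = False`` and NaN coordinates.

The on-disk dialect is CSV with ``#``-prefixed header metadata::

    # animal_id: B6-001
    # strain: C57BL/6J
    # sample_rate: 15
    t,x,y,detected
    0.000000,12.3456,4.5678,1
    0.066667,,,0

Undetected rows leave x and y empty.  Writing is canonical (fixed float
formats), so write(read(f)) is byte-identical for files produced by
:func:`write_track`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaLayout

__all__ = ["TrackStream", "read_track", "write_track", "TrackFormatError"]


class TrackFormatError(ValueError):
    """Raised for malformed or invalid track files."""


@dataclass
class TrackStream:
    animal_id: str
    strain: str
    t: np.ndarray          # seconds since recording start, regular grid
    x: np.ndarray          # cm; NaN where not detected
    y: np.ndarray
    detected: np.ndarray   # bool
    sample_rate: float = 15.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.detected = np.asarray(self.detected, bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.detected) == n):
            raise ValueError("t, x, y, detected must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise TrackFormatError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Record length in seconds (grid end = last sample + one interval)."""
        return float(self.t[-1] + self.dt - self.t[0]) if len(self) else 0.0

    def validate_bounds(self, layout: ArenaLayout) -> None:
        d = self.detected
        ok = layout.in_bounds(self.x[d], self.y[d])
        if not np.all(ok):
            i = int(np.flatnonzero(~ok)[0])
            t_bad = self.t[d][i]
            raise TrackFormatError(
                f"detected coordinate out of cage bounds at t={t_bad:.3f}s"
            )


def _parse_header(lines: list[str], path) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" not in body:
            raise TrackFormatError(f"{path}: malformed metadata line {ln!r}")
        key, val = body.split(":", 1)
        meta[key.strip()] = val.strip()
    for key in ("animal_id", "strain", "sample_rate"):
        if key not in meta:
            raise TrackFormatError(f"{path}: missing '{key}' metadata")
    return meta


def _locate_bad_row(path, n_skip: int) -> None:
    """Line-by-line diagnostic pass: raises naming the first bad line."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if lineno <= n_skip:
                continue
            parts = raw.rstrip("\n").split(",")
            if len(parts) != 4:
                raise TrackFormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                float(parts[0])
                det = int(parts[3])
                if det:
                    float(parts[1])
                    float(parts[2])
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: {exc}") from None
    raise TrackFormatError(f"{path}: malformed data")


def read_track(path, layout: ArenaLayout | None = None,
               max_gap_s: float = 1.0) -> TrackStream:
    """Read a track CSV, validating monotone time and cage bounds.

    Missing rows while the animal is detected are linearly interpolated up
    to ``max_gap_s``; longer detected gaps raise.  Gaps adjacent to
    undetected samples are filled as undetected (shelter occupancy).
    """
    path = Path(path)
    header: list[str] = []
    n_skip = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            n_skip += 1
            if line.startswith("#"):
                header.append(line)
                continue
            if [c.strip() for c in line.split(",")] != ["t", "x", "y", "detected"]:
                raise TrackFormatError(
                    f"{path}:{n_skip}: expected header 't,x,y,detected'")
            break
        else:
            raise TrackFormatError(f"{path}: no data rows")
    meta = _parse_header(header, path)
    rate = float(meta["sample_rate"])

    try:
        df = pd.read_csv(path, skiprows=n_skip, header=None,
                         names=["t", "x", "y", "detected"],
                         dtype={"t": float, "x": float, "y": float,
                                "detected": np.int64})
    except (ValueError, pd.errors.ParserError):
        _locate_bad_row(path, n_skip)   # raises with the offending line
        raise
    if df["t"].isna().any() or df["detected"].isna().any():
        _locate_bad_row(path, n_skip)
    if not len(df):
        raise TrackFormatError(f"{path}: no data rows")

    rows_d = df["detected"].to_numpy() != 0
    rows_x = np.where(rows_d, df["x"].to_numpy(), np.nan)
    rows_y = np.where(rows_d, df["y"].to_numpy(), np.nan)
    if np.any(rows_d & (~np.isfinite(rows_x) | ~np.isfinite(rows_y))):
        _locate_bad_row(path, n_skip)
    t = df["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        i = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise TrackFormatError(f"{path}: non-monotone t near row {i + 2}")

    # re-grid onto the nominal sampling lattice
    dt = 1.0 / rate
    idx = np.rint((t - t[0]) / dt).astype(int)
    if np.any(np.diff(idx) < 1):
        raise TrackFormatError(f"{path}: samples closer than 1/{rate:g} s")
    n = idx[-1] + 1
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    det = np.zeros(n, bool)
    present = np.zeros(n, bool)
    x[idx] = rows_x
    y[idx] = rows_y
    det[idx] = rows_d
    present[idx] = True

    # fill gaps: detected neighbours on both sides -> interpolate (<= max_gap_s)
    gap_starts = np.flatnonzero(present[:-1] & ~present[1:])
    for gs in gap_starts:
        ge = gs + 1
        while ge < n and not present[ge]:
            ge += 1
        if ge >= n:
            break
        if det[gs] and det[ge]:
            gap = (ge - gs) * dt
            if gap > max_gap_s:
                raise TrackFormatError(
                    f"{path}: {gap:.2f}s gap while detected at t={t[0] + gs * dt:.3f}s "
                    f"exceeds {max_gap_s:g}s"
                )
            frac = np.arange(1, ge - gs) / (ge - gs)
            x[gs + 1:ge] = x[gs] + frac * (x[ge] - x[gs])
            y[gs + 1:ge] = y[gs] + frac * (y[ge] - y[gs])
            det[gs + 1:ge] = True
        # else: gap borders shelter occupancy -> stays undetected

    stream = TrackStream(
        animal_id=meta["animal_id"],
        strain=meta["strain"],
        t=t[0] + np.arange(n) * dt,
        x=x,
        y=y,
        detected=det,
        sample_rate=rate,
    )
    if layout is not None:
        stream.validate_bounds(layout)
    return stream


def write_track(stream: TrackStream, path) -> None:
    """Write the canonical dialect: fixed formats, '#' metadata header."""
    rate = stream.sample_rate
    rate_s = f"{int(rate)}" if float(rate).is_integer() else f"{rate:g}"
    head = (f"# animal_id: {stream.animal_id}\n"
            f"# strain: {stream.strain}\n"
            f"# sample_rate: {rate_s}\n"
            "t,x,y,detected\n")
    body = "\n".join(
        f"{t:.6f},{x:.4f},{y:.4f},1" if d else f"{t:.6f},,,0"
        for t, x, y, d in zip(stream.t, stream.x, stream.y, stream.detected)
    )
    Path(path).write_text(head + body + "\n")
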