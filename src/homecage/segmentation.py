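"""Segmentation of a tracking stream into behavioral elements.

The continuous centre-of-gravity trace is cut into three element types:

* **moves** — gross displacement of the centre of gravity (locomotion,
  turning, rearing against the wall);
* **arrests** — complete inactivity or minute movements (grooming, eating):
  runs of samples that stay within ``epsilon`` of a common position after
  repeated running-median smoothing;
* **shelter visits** — intervals during which the tracker loses the animal
  after it disappears in the 2 cm strip in front of the shelter entrance,
  closed only when the animal is re-detected continuously for at least
  7 samples (0.5 s) to debounce the flickering detection during entry/exit.

Moves and arrests exactly tile every continuous outside-shelter run; visits
and outside intervals together tile the record up to tracking dropouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaLayout
from .track import TrackStream

__all__ = [
    "SmoothingParams",
    "Segment",
    "smooth_track",
    "running_median",
    "segment_moves_arrests",
    "detect_shelter_visits",
    "zone_occupancy",
    "segment_stream",
    "MOVE",
    "ARREST",
    "SHELTER",
]

log = logging.getLogger(__name__)

MOVE = "move"
ARREST = "arrest"
SHELTER = "shelter"

#: consecutive detected samples required to close a shelter visit (0.5 s at 15 Hz)
EXIT_DEBOUNCE_SAMPLES = 7


@dataclass(frozen=True)
class SmoothingParams:
    """Running-median and arrest-detection settings.

    ``half_windows`` are the half-window sizes of the consecutive
    running-median passes (window length ``2h + 1``); ``epsilon`` is the
    radius (cm) within which a sample is considered stationary around the
    arrest's medoid; ``min_arrest_samples`` is the minimal arrest length.
    """

    half_windows: tuple[int, ...] = (3, 2, 1, 1)
    min_arrest_samples: int = 3
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        hw = tuple(int(h) for h in self.half_windows)
        if not hw or any(h <= 0 for h in hw):
            raise ValueError("half_windows must be positive integers")
        if any(a < b for a, b in zip(hw, hw[1:])):
            raise ValueError("half_windows must be nonincreasing")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_arrest_samples < 1:
            raise ValueError("min_arrest_samples must be >= 1")


@dataclass
class Segment:
    """A typed behavioral element of one animal.

    ``t_end`` is exclusive; segments of one animal are ordered and
    non-overlapping.  ``distance`` is the summed inter-sample displacement
    of the smoothed coordinates (moves only), ``max_velocity`` the peak
    per-sample speed (cm/s).  ``class_label`` is assigned later from the
    animal's own thresholds.
    """

    animal_id: str
    kind: str                       # move | arrest | shelter
    t_start: float
    t_end: float
    distance: float = 0.0
    max_velocity: float = np.nan
    class_label: str = ""

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.kind not in (MOVE, ARREST, SHELTER):
            raise ValueError(f"unknown segment kind {self.kind!r}")


def running_median(values: np.ndarray, half_window: int) -> np.ndarray:
    """Running median with window ``2*half_window + 1``, shrinking at edges.

    Each output element is the median of the input over the part of the
    centred window that lies inside the sequence, so output length equals
    input length and edges are handled without padding.
    """
    s = pd.Series(np.asarray(values, float))
    return (
        s.rolling(2 * half_window + 1, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def smooth_track(x: np.ndarray, y: np.ndarray,
                 params: SmoothingParams = SmoothingParams()) -> tuple[np.ndarray, np.ndarray]:
    """Repeated running-median smoothing of one continuous detected run.

    The passes are applied in order of ``params.half_windows`` to x and y
    independently.  Runs shorter than the largest window are returned
    unsmoothed (with a log warning): the median window would never reach
    full width anywhere.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    largest = 2 * max(params.half_windows) + 1
    if len(x) < largest:
        log.warning("run of %d samples shorter than largest window %d; "
                    "passed through unsmoothed", len(x), largest)
        return x.copy(), y.copy()
    for h in params.half_windows:
        x = running_median(x, h)
        y = running_median(y, h)
    return x, y


def _stationary_valid(xs: np.ndarray, ys: np.ndarray, i: int, j: int,
                      eps: float) -> bool:
    """True if samples i..j all lie within eps of the run's medoid.

    The medoid is the run sample nearest the coordinate-wise median — an
    O(k) surrogate for the exact medoid that coincides with it for the
    near-stationary clouds this test is applied to.
    """
    sx = xs[i:j + 1]
    sy = ys[i:j + 1]
    cx = np.median(sx)
    cy = np.median(sy)
    k = int(np.argmin((sx - cx) ** 2 + (sy - cy) ** 2))
    d2 = (sx - sx[k]) ** 2 + (sy - sy[k]) ** 2
    return bool(np.max(d2) <= eps * eps)


def _find_stationary_runs(xs: np.ndarray, ys: np.ndarray,
                          params: SmoothingParams) -> list[tuple[int, int]]:
    """Greedy left-to-right maximal stationary runs (inclusive index pairs)."""
    n = len(xs)
    m = params.min_arrest_samples
    eps = params.epsilon
    runs: list[tuple[int, int]] = []
    i = 0
    while i + m - 1 < n:
        if not _stationary_valid(xs, ys, i, i + m - 1, eps):
            i += 1
            continue
        # grow by doubling, then binary search the last valid end
        j = i + m - 1
        step = m
        while j < n - 1:
            cand = min(n - 1, j + step)
            if _stationary_valid(xs, ys, i, cand, eps):
                j = cand
                step *= 2
            else:
                break
        lo, hi = j, min(n - 1, j + step)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if _stationary_valid(xs, ys, i, mid, eps):
                lo = mid
            else:
                hi = mid - 1
        runs.append((i, lo))
        i = lo + 1
    return runs


def segment_moves_arrests(t: np.ndarray, x_s: np.ndarray, y_s: np.ndarray,
                          dt: float, animal_id: str = "",
                          params: SmoothingParams = SmoothingParams()) -> list[Segment]:
    """Tile one smoothed outside-shelter run with alternating moves/arrests.

    An arrest is a maximal run of at least ``min_arrest_samples`` samples
    each within ``epsilon`` of the run's medoid; the complementary
    intervals are moves.  Each sample spans ``[t_i, t_i + dt)``, so the
    emitted segments exactly tile the run.
    """
    n = len(t)
    if n == 0:
        return []
    x_s = np.asarray(x_s, float)
    y_s = np.asarray(y_s, float)
    arrest_runs = _find_stationary_runs(x_s, y_s, params)

    step = np.hypot(np.diff(x_s), np.diff(y_s))
    speed = step / dt

    segments: list[Segment] = []

    def emit(kind: str, i: int, j: int) -> None:
        # displacement between consecutive samples i..j belongs to the segment
        dist = float(step[i:j].sum()) if kind == MOVE else 0.0
        vmax = float(speed[i:j].max()) if (kind == MOVE and j > i) else 0.0
        segments.append(Segment(
            animal_id=animal_id, kind=kind,
            t_start=float(t[i]), t_end=float(t[j]) + dt,
            distance=dist, max_velocity=vmax if kind == MOVE else np.nan,
        ))

    pos = 0
    for (a, b) in arrest_runs:
        if a > pos:
            emit(MOVE, pos, a - 1)
        emit(ARREST, a, b)
        pos = b + 1
    if pos < n:
        emit(MOVE, pos, n - 1)
    return segments


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean array as (start, stop_exclusive, value)."""
    n = len(mask)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    edges = np.concatenate(([0], change, [n]))
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(edges[:-1], edges[1:])]


def detect_shelter_visits(stream: TrackStream, layout: ArenaLayout,
                          debounce: int = EXIT_DEBOUNCE_SAMPLES) -> list[Segment]:
    """Shelter visits from detection gaps anchored at the entrance zone.

    A visit opens when detection is lost while the last detected position
    lies in the entrance strip, and closes at the first sample of a run of
    ``debounce`` consecutive detected samples; shorter re-detections during
    entry/exit flicker do not close the visit.  Detection losses elsewhere
    in the cage are tracking dropouts, not visits.  A record that begins
    undetected opens a visit at t = 0 (the animal started inside).
    """
    runs = _bool_runs(stream.detected)
    entrance = layout.zone_mask("entrance_zone", stream.x, stream.y)
    dt = stream.dt
    visits: list[Segment] = []
    open_start: float | None = None
    n_dropouts = 0
    for (a, b, det) in runs:
        if det:
            if open_start is not None and (b - a) >= debounce:
                visits.append(Segment(stream.animal_id, SHELTER,
                                      open_start, float(stream.t[a])))
                open_start = None
        else:
            if open_start is not None:
                continue  # flicker inside an open visit
            if a == 0 or entrance[a - 1]:
                open_start = float(stream.t[a])
            else:
                n_dropouts += 1
    if open_start is not None:
        # record ends inside the shelter
        visits.append(Segment(stream.animal_id, SHELTER,
                              open_start, float(stream.t[-1]) + dt))
    if n_dropouts:
        log.warning("%s: %d detection losses outside the entrance zone "
                    "treated as tracking dropouts", stream.animal_id, n_dropouts)
    return visits


def zone_occupancy(stream: TrackStream, layout: ArenaLayout,
                   zones: tuple[str, ...] = ("feeding_zone", "spout_zone",
                                             "onshelter_zone")) -> dict[str, list[tuple[float, float]]]:
    """Per-zone maximal occupancy intervals of the detected samples.

    Membership is closed (boundary samples count as inside).  The number of
    OnShelter intervals is the animal's count of jumps onto the shelter.
    """
    dt = stream.dt
    out: dict[str, list[tuple[float, float]]] = {}
    for zone in zones:
        mask = layout.zone_mask(zone, stream.x, stream.y) & stream.detected
        out[zone] = [
            (float(stream.t[a]), float(stream.t[b - 1]) + dt)
            for (a, b, val) in _bool_runs(mask) if val
        ]
    return out


def _outside_intervals(stream: TrackStream, visits: list[Segment]) -> list[tuple[int, int]]:
    """Index ranges (inclusive) of detected samples not inside any visit."""
    n = len(stream)
    in_visit = np.zeros(n, bool)
    t0 = stream.t[0]
    dt = stream.dt
    for v in visits:
        a = int(np.ceil(round((v.t_start - t0) / dt, 9)))
        b = int(np.ceil(round((v.t_end - t0) / dt, 9)))  # exclusive
        in_visit[a:min(b, n)] = True
    usable = stream.detected & ~in_visit
    return [(a, b - 1) for (a, b, val) in _bool_runs(usable) if val]


def segment_stream(stream: TrackStream, layout: ArenaLayout,
                   params: SmoothingParams = SmoothingParams()) -> dict:
    """Full segmentation of one animal.

    Returns a dict with ``segments`` (time-ordered moves, arrests and
    shelter visits), ``zones`` (occupancy intervals) and the smoothed
    coordinates (NaN where not smoothed).
    """
    visits = detect_shelter_visits(stream, layout)
    x_s = np.full(len(stream), np.nan)
    y_s = np.full(len(stream), np.nan)
    segments: list[Segment] = list(visits)
    for (a, b) in _outside_intervals(stream, visits):
        xs, ys = smooth_track(stream.x[a:b + 1], stream.y[a:b + 1], params)
        x_s[a:b + 1] = xs
        y_s[a:b + 1] = ys
        segments.extend(segment_moves_arrests(
            stream.t[a:b + 1], xs, ys, stream.dt, stream.animal_id, params))
    segments.sort(key=lambda s: s.t_start)
    zones = zone_occupancy(stream, layout)
    return {"segments": segments, "zones": zones, "x_s": x_s, "y_s": y_s}


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Segment table in the on-disk layout."""
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "kind": s.kind,
                "class": s.class_label,
                "t_start": s.t_start,
                "t_end": s.t_end,
                "duration": s.duration,
                "distance": s.distance,
                "max_velocity": s.max_velocity,
            }
            for s in segments
        ]
    )


def frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    out = []
    for row in df.to_dict("records"):
        label = row.get("class", "")
        out.append(Segment(
            animal_id=row["animal_id"], kind=row["kind"],
            t_start=float(row["t_start"]), t_end=float(row["t_end"]),
            distance=float(row["distance"]),
            max_velocity=float(row["max_velocity"]),
            class_label="" if (label is None or (isinstance(label, float) and np.isnan(label))) else str(label),
        ))
    return out
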