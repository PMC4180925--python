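"""Arena geometry and light-schedule arithmetic.

The observation cage is a 30 x 30 cm (35 cm high) box with a triangular
shelter in one corner, a feeding station and a water spout on two adjacent
walls, and an analysis zone on top of the shelter.  All coordinates are
continuous centimetres with the origin at a cage corner; the tracker reports
the animal's centre of gravity.

Recording starts at the onset of the first dark phase, so ``t = 0`` seconds
is always a dark onset and phases alternate from there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

__all__ = [
    "ArenaLayout",
    "LightSchedule",
    "Phase",
    "default_layout",
    "default_schedule",
]

DARK = "dark"
LIGHT = "light"

Phase = str  # "dark" | "light"


def _as_polygon(points: Sequence[tuple[float, float]]) -> Polygon:
    poly = Polygon(points)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"invalid polygon: {list(points)}")
    return poly


@dataclass(frozen=True)
class ArenaLayout:
    """Cage geometry: bounds, shelter footprint, entrance strip and zones.

    Polygons are closed: a sample lying exactly on a boundary counts as
    inside (deterministic tie-break).
    """

    cage_width: float = 30.0
    cage_height: float = 30.0
    shelter_polygon: tuple[tuple[float, float], ...] = ()
    entrance_zone: tuple[tuple[float, float], ...] = ()
    feeding_zone: tuple[tuple[float, float], ...] = ()
    spout_zone: tuple[tuple[float, float], ...] = ()
    onshelter_zone: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.cage_width <= 0 or self.cage_height <= 0:
            raise ValueError("cage dimensions must be positive")
        cage = Polygon(
            [
                (0.0, 0.0),
                (self.cage_width, 0.0),
                (self.cage_width, self.cage_height),
                (0.0, self.cage_height),
            ]
        )
        for name in ("shelter_polygon", "entrance_zone", "feeding_zone",
                     "spout_zone", "onshelter_zone"):
            pts = getattr(self, name)
            if not pts:
                raise ValueError(f"{name} must be given")
            poly = _as_polygon(pts)
            if not cage.buffer(1e-9).contains(poly):
                raise ValueError(f"{name} extends outside the cage bounds")
        if not self.polygon("entrance_zone").buffer(1e-9).intersects(
            self.polygon("shelter_polygon")
        ):
            raise ValueError("entrance_zone must abut the shelter")

    def polygon(self, name: str) -> Polygon:
        return _as_polygon(getattr(self, name))

    def in_bounds(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= 0) & (x <= self.cage_width) & (y >= 0) & (y <= self.cage_height)

    def zone_mask(self, name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Closed point-in-polygon membership for every (x, y) sample."""
        poly = self.polygon(name)
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        out = np.zeros(x.shape, dtype=bool)
        ok = np.isfinite(x) & np.isfinite(y)
        # intersects counts boundary points as hits -> closed polygons
        out[ok] = shapely.intersects_xy(poly, x[ok], y[ok])
        return out

    def to_dict(self) -> dict:
        return {
            "cage_width": float(self.cage_width),
            "cage_height": float(self.cage_height),
            "shelter_polygon": [[float(a), float(b)] for a, b in self.shelter_polygon],
            "entrance_zone": [[float(a), float(b)] for a, b in self.entrance_zone],
            "feeding_zone": [[float(a), float(b)] for a, b in self.feeding_zone],
            "spout_zone": [[float(a), float(b)] for a, b in self.spout_zone],
            "onshelter_zone": [[float(a), float(b)] for a, b in self.onshelter_zone],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaLayout":
        kw = dict(d)
        for name in ("shelter_polygon", "entrance_zone", "feeding_zone",
                     "spout_zone", "onshelter_zone"):
            kw[name] = tuple(tuple(map(float, p)) for p in kw[name])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ArenaLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh)["arena"])


def default_layout() -> ArenaLayout:
    """The standard cage: triangular shelter in the top-left corner, a 2 cm
    entrance strip along its diagonal face, feeding and spout zones on the
    two opposite walls, and the on-shelter zone over the shelter footprint."""
    shelter = ((0.0, 18.0), (12.0, 30.0), (0.0, 30.0))
    # 2 cm strip offset outward (perpendicular to the diagonal face)
    dx = 2.0 / math.sqrt(2.0)
    entrance = (
        (0.0, 18.0),
        (12.0, 30.0),
        (12.0 + dx, 30.0 - dx),
        (0.0 + dx, 18.0 - dx),
    )
    return ArenaLayout(
        cage_width=30.0,
        cage_height=30.0,
        shelter_polygon=shelter,
        entrance_zone=entrance,
        feeding_zone=((10.0, 0.0), (20.0, 0.0), (20.0, 4.0), (10.0, 4.0)),
        spout_zone=((26.0, 10.0), (30.0, 10.0), (30.0, 16.0), (26.0, 16.0)),
        onshelter_zone=shelter,
    )


def _parse_clock(s: str) -> float:
    """'HH:MM' -> hours since midnight."""
    hh, mm = s.split(":")
    h = int(hh) + int(mm) / 60.0
    if not 0 <= h < 24:
        raise ValueError(f"clock time out of range: {s}")
    return h


@dataclass(frozen=True)
class LightSchedule:
    """Lights-on / lights-off clock times; recording starts at a dark onset.

    The default is the 7:00 / 19:00 regime: 12 h dark, 12 h light, with
    ``t = 0`` at 19:00 of the first day.
    """

    lights_on: str = "07:00"
    lights_off: str = "19:00"
    recording_start: str = "19:00"

    def __post_init__(self) -> None:
        if _parse_clock(self.recording_start) != _parse_clock(self.lights_off):
            raise ValueError("recording must start at a dark onset (lights off)")

    @property
    def dark_hours(self) -> float:
        d = (_parse_clock(self.lights_on) - _parse_clock(self.lights_off)) % 24.0
        return d if d > 0 else 24.0

    @property
    def light_hours(self) -> float:
        return 24.0 - self.dark_hours

    def phase_of(self, t) -> tuple:
        """Phase label and 1-based day index for time(s) ``t`` in seconds.

        Intervals are half-open: a phase transition instant belongs to the
        phase it begins.  Vectorized over array input.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be non-negative")
        day_s = 86400.0
        dark_s = self.dark_hours * 3600.0
        day = (t_arr // day_s).astype(int) + 1
        within = t_arr % day_s
        phase = np.where(within < dark_s, DARK, LIGHT)
        if np.isscalar(t) or t_arr.ndim == 0:
            return str(phase), int(day)
        return phase, day

    def phase_bins(self, n_days: int = 3) -> list[tuple[str, int, float, float]]:
        """(phase, day, t_start, t_end) for each 12 h bin of an n-day record."""
        dark_s = self.dark_hours * 3600.0
        light_s = self.light_hours * 3600.0
        out = []
        t = 0.0
        for day in range(1, n_days + 1):
            out.append((DARK, day, t, t + dark_s))
            t += dark_s
            out.append((LIGHT, day, t, t + light_s))
            t += light_s
        return out

    def transitions(self, n_days: int = 3) -> list[tuple[str, float]]:
        """Phase-onset times (seconds) within the record, excluding t=0.

        Labels name the phase that begins: 'light' at lights-on, 'dark' at
        lights-off.
        """
        out = []
        for phase, _day, t0, _t1 in self.phase_bins(n_days):
            if t0 > 0:
                out.append((phase, t0))
        return out


def default_schedule() -> LightSchedule:
    return LightSchedule()
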