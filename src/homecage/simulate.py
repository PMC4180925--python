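"""Strain-structured synthetic home-cage cohorts with known ground truth.

One simulated animal is an alternating renewal process over a 3-day
recording that starts at dark onset:

* a **shelter visit** whose duration is drawn from a 3-component mixture of
  log2-normal classes (seconds-long passing-through visits, intermediate
  visits, hours-long resting visits), with phase-dependent class weights
  (resting visits concentrate in the light phase);
* an **outside excursion** composed of alternating move and arrest
  segments (move distances from a bimodal log2-normal mixture, arrest
  durations log2-normal), whose expected duration is set so that the
  long-run fraction of time outside matches the phase's activity level.

Circadian structure comes from phase-dependent activity fractions
(dark >> light), multi-day habituation from a per-day multiplier on the
activity fraction, and anticipation of phase transitions from a linear
ramp on the activity fraction over the two hours preceding a transition.

Generation is event-level first (exact ground-truth segments, cheap enough
for hundreds of animals); rendering to a 15 Hz coordinate stream with
detection loss during shelter occupancy is a separate, optional step used
by track-level tests.  Strain panels draw per-strain and per-animal effects
on selected profile fields so that realized between/within variance
fractions match requested narrow-sense heritability targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from shapely.geometry import Point

from .arena import ArenaLayout, LightSchedule, default_layout, default_schedule
from .segmentation import ARREST, MOVE, SHELTER, Segment
from .track import TrackStream

__all__ = [
    "StrainProfile",
    "TrueSegment",
    "GroundTruth",
    "simulate_animal",
    "render_track",
    "simulate_cohort",
    "iter_cohort",
    "simulate_strain_values",
    "sample_log2_mixture",
    "analytic_intersection",
    "paper_panel",
    "PAPER_STRAIN_N",
    "HERITABLE_FIELDS",
]

log = logging.getLogger(__name__)

#: group sizes of the 11-strain reference panel
PAPER_STRAIN_N = {
    "129S1/SvImJ": 61,
    "A/J": 49,
    "BALB/cJ": 47,
    "C3H/HeJ": 29,
    "C57BL/6J": 112,
    "DBA/2J": 40,
    "FVB/NJ": 49,
    "NOD/ShiLtJ": 46,
    "WSB/EiJ": 14,
    "PWK/PhJ": 15,
    "CAST/EiJ": 14,
}

_WALL_MARGIN = 0.3   # cm kept clear of the walls when placing positions
_MIN_MOVE_CM = 0.4   # smallest realized move displacement (4x the arrest radius)


@dataclass(frozen=True)
class StrainProfile:
    """Generating parameters of one strain.

    Move distances and arrest/shelter durations are log2-normal; activity
    fractions are the expected share of time spent outside the shelter per
    phase; ``habituation`` multiplies the activity fraction per elapsed
    day; anticipation slopes (fraction per hour) ramp activity over the
    two hours preceding the named phase transition.
    """

    name: str = "SIM"
    n_animals: int = 1
    # kinematics (log2 cm / cm/s)
    short_move_log2_mean: float = 0.0
    short_move_log2_sd: float = 0.5
    long_move_log2_mean: float = 3.0
    long_move_log2_sd: float = 0.7
    p_long_move: float = 0.35
    long_move_velocity: float = 12.0
    long_move_velocity_sd: float = 2.5
    short_move_velocity: float = 2.5
    # arrests (log2 s)
    arrest_log2_mean: float = 3.3
    arrest_log2_sd: float = 1.1
    # shelter visit classes (log2 s)
    shelter_means: tuple[float, float, float] = (3.0, 9.5, 12.0)
    shelter_sds: tuple[float, float, float] = (0.8, 0.5, 0.6)
    shelter_weights_dark: tuple[float, float, float] = (0.75, 0.20, 0.05)
    shelter_weights_light: tuple[float, float, float] = (0.35, 0.20, 0.45)
    # circadian / longitudinal structure
    dark_activity: float = 0.60
    light_activity: float = 0.10
    habituation: float = 0.90
    anticipate_dark_slope: float = 0.0
    anticipate_light_slope: float = 0.0
    # zone routing (per long move)
    p_feed: float = 0.10
    p_spout: float = 0.05
    p_jump: float = 0.06
    # outside-sleeper behavior: share of light-phase rest taken outside
    outside_rest_fraction: float = 0.0
    # recording
    sample_rate: float = 15.0
    duration_h: float = 72.0

    def __post_init__(self) -> None:
        for w in (self.shelter_weights_dark, self.shelter_weights_light):
            if abs(sum(w) - 1.0) > 1e-9 or any(v < 0 for v in w):
                raise ValueError("shelter class weights must be >=0 and sum to 1")
            if all(v == 0 for v in w):
                raise ValueError("degenerate profile: all shelter classes zero weight")
        if not (self.shelter_means[0] < self.shelter_means[1] < self.shelter_means[2]):
            raise ValueError("shelter class means must be ordered")
        for p in (self.dark_activity, self.light_activity, self.p_long_move,
                  self.p_feed, self.p_spout, self.p_jump,
                  self.outside_rest_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.habituation <= 0:
            raise ValueError("habituation multiplier must be positive")


@dataclass(slots=True)
class TrueSegment:
    """A generated behavioral element with its generating class."""

    kind: str          # move | arrest | shelter
    i_start: int       # sample index, inclusive
    i_end: int         # sample index, exclusive
    distance: float = 0.0
    velocity: float = np.nan       # nominal speed of a move (cm/s)
    gen_class: str = ""            # generating class label
    zone: str = ""                 # zone an arrest is located in
    waypoints: tuple = ()          # move path ((x, y), ...) for rendering
    pos: tuple = ()                # arrest position

    def t_start(self, rate: float) -> float:
        return self.i_start / rate

    def t_end(self, rate: float) -> float:
        return self.i_end / rate


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated animal."""

    animal_id: str
    strain: str
    sample_rate: float
    n_samples: int
    segments: list[TrueSegment]
    thresholds: dict            # true generating thresholds (natural units)
    profile: StrainProfile      # realized (per-animal) profile
    seed: object = None

    def to_segments(self) -> list[Segment]:
        """Ground-truth segments as pipeline :class:`Segment` objects, with
        shelter visits separated by less than the exit debounce merged the
        way the detector would see them."""
        rate = self.sample_rate
        out = []
        for s in self.segments:
            seg = Segment(
                animal_id=self.animal_id, kind=s.kind,
                t_start=s.i_start / rate, t_end=s.i_end / rate,
                distance=s.distance,
                max_velocity=s.velocity if s.kind == MOVE else np.nan,
                class_label=s.gen_class,
            )
            out.append(seg)
        return out

    def jump_times(self) -> np.ndarray:
        """Times (s) of jumps onto the shelter (on-shelter arrests)."""
        return np.array([s.i_start / self.sample_rate for s in self.segments
                         if s.kind == ARREST and s.zone == "onshelter_zone"])

    def zone_intervals(self, zone: str) -> list[tuple[float, float]]:
        rate = self.sample_rate
        return [(s.i_start / rate, s.i_end / rate) for s in self.segments
                if s.kind == ARREST and s.zone == zone]


# ---------------------------------------------------------------------------
# mixture helpers (also used by threshold-recovery suites)

def sample_log2_mixture(means, sds, weights, n, rng) -> np.ndarray:
    """n draws of 2**X where X comes from a Gaussian mixture in log2 units."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    w = np.asarray(weights, float)
    w = w / w.sum()
    comp = rng.choice(len(w), size=n, p=w)
    return 2.0 ** rng.normal(means[comp], sds[comp])


def analytic_intersection(m1, s1, w1, m2, s2, w2) -> float | None:
    """Crossing point of two weighted Gaussian densities between their means.

    Solves w1 N(x; m1, s1) = w2 N(x; m2, s2) in closed form (quadratic in
    x) and returns the root inside (m1, m2), or None when the densities do
    not cross there.  This is the generating-parameter oracle for the
    histogram-fit thresholds: least-squares curve amplitudes are the
    densities scaled by one common factor, so the crossing is identical.
    """
    if w1 <= 0 or w2 <= 0:
        return None
    lo, hi = sorted((m1, m2))
    # quadratic a x^2 + b x + c = 0 from equating log densities
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    c = (m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2)
         + math.log(w1 / s1) - math.log(w2 / s2))
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return None
        roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            return None
        r = math.sqrt(disc)
        roots = [(-b - r) / (2 * a), (-b + r) / (2 * a)]
    inside = [x for x in roots if lo < x < hi]
    if not inside:
        return None
    mid = 0.5 * (lo + hi)
    return min(inside, key=lambda x: abs(x - mid))


def _true_thresholds(profile: StrainProfile, arrest_durations: np.ndarray) -> dict:
    """Generating thresholds: analytic mixture crossings plus the empirical
    90th percentile of the animal's true arrest durations (the arrest
    threshold is defined empirically, so its truth is exact)."""
    move_x = analytic_intersection(
        profile.short_move_log2_mean, profile.short_move_log2_sd, 1 - profile.p_long_move,
        profile.long_move_log2_mean, profile.long_move_log2_sd, profile.p_long_move,
    )
    # pooled shelter weights: average of phase weights (equal phase shares)
    w = 0.5 * np.asarray(profile.shelter_weights_dark) + \
        0.5 * np.asarray(profile.shelter_weights_light)
    m, s = profile.shelter_means, profile.shelter_sds
    long_x = analytic_intersection(m[1], s[1], w[1], m[2], s[2], w[2])
    z90 = 1.2815515655446004
    return {
        "long_move_threshold": 2.0 ** move_x if move_x is not None else np.nan,
        "long_arrest_threshold": (float(np.percentile(arrest_durations, 90.0))
                                  if len(arrest_durations) else np.nan),
        "short_shelter_threshold": 2.0 ** (m[0] + z90 * s[0]),
        "long_shelter_threshold": 2.0 ** long_x if long_x is not None else np.nan,
    }


# ---------------------------------------------------------------------------
# geometry

def _entrance_point(layout: ArenaLayout) -> np.ndarray:
    c = layout.polygon("entrance_zone").centroid
    return np.array([c.x, c.y])


def _zone_point(layout: ArenaLayout, zone: str, rng) -> np.ndarray:
    poly = layout.polygon(zone)
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(50):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if poly.contains(Point(p)):
            return p
    c = poly.centroid
    return np.array([c.x, c.y])


def _billiard_path(pos: np.ndarray, length: float, rng,
                   w: float, h: float) -> tuple[tuple, float]:
    """Straight path of the given length reflecting off the walls."""
    lo = np.array([_WALL_MARGIN, _WALL_MARGIN])
    hi = np.array([w - _WALL_MARGIN, h - _WALL_MARGIN])
    p = np.clip(np.asarray(pos, float), lo, hi)
    ang = rng.uniform(0, 2 * np.pi)
    u = np.array([np.cos(ang), np.sin(ang)])
    pts = [tuple(p)]
    remaining = length
    guard = 0
    while remaining > 1e-9 and guard < 200:
        guard += 1
        dists = []
        for k in range(2):
            if u[k] > 1e-12:
                dists.append((hi[k] - p[k]) / u[k])
            elif u[k] < -1e-12:
                dists.append((lo[k] - p[k]) / u[k])
            else:
                dists.append(np.inf)
        d_wall = max(min(dists), 0.0)
        step = min(remaining, d_wall)
        p = p + step * u
        remaining -= step
        pts.append(tuple(p))
        if remaining > 1e-9:
            k = int(np.argmin(dists))
            u[k] = -u[k]
    return tuple(pts), length - remaining


def _two_leg_path(a: np.ndarray, b: np.ndarray, length: float, rng,
                  w: float, h: float) -> tuple[tuple, float]:
    """Path from a to b of total length ~``length`` via one waypoint on the
    ellipse with foci a, b (falls back to the direct segment)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = float(np.hypot(*(b - a)))
    if length <= d * 1.001 or d < 1e-9:
        return (tuple(a), tuple(b)), max(d, 1e-6)
    for _ in range(20):
        ang = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(ang), np.sin(ang)])
        c = b - a
        denom = 2 * (length - float(u @ c))
        if denom <= 1e-9:
            continue
        r = (length ** 2 - float(c @ c)) / denom
        if r <= 0 or r >= length:
            continue
        wpt = a + r * u
        if (_WALL_MARGIN <= wpt[0] <= w - _WALL_MARGIN
                and _WALL_MARGIN <= wpt[1] <= h - _WALL_MARGIN):
            return (tuple(a), tuple(wpt), tuple(b)), length
    return (tuple(a), tuple(b)), max(d, 1e-6)


# ---------------------------------------------------------------------------
# single-animal generation

def _phase_weights(profile: StrainProfile, dark: bool) -> np.ndarray:
    w = profile.shelter_weights_dark if dark else profile.shelter_weights_light
    return np.asarray(w, float)


def _expected_shelter_s(profile: StrainProfile, dark: bool) -> float:
    w = _phase_weights(profile, dark)
    m = np.asarray(profile.shelter_means)
    s = np.asarray(profile.shelter_sds)
    return float(np.sum(w * 2.0 ** m * np.exp(0.5 * (s * np.log(2)) ** 2)))


def _activity_fraction(profile: StrainProfile, t_s: float) -> float:
    """Target outside fraction at time t: phase base x habituation, plus the
    anticipation ramp over the last 2 h of the current phase."""
    day = int(t_s // 86400.0) + 1
    t_in_day = t_s % 86400.0
    dark = t_in_day < 43200.0
    base = profile.dark_activity if dark else profile.light_activity
    f = base * profile.habituation ** (day - 1)
    to_end = (43200.0 - t_in_day) if dark else (86400.0 - t_in_day)
    slope = profile.anticipate_light_slope if dark else profile.anticipate_dark_slope
    if to_end < 7200.0:
        f += slope * (7200.0 - to_end) / 3600.0
    return float(np.clip(f, 0.0, 0.95))


def simulate_animal(profile: StrainProfile, seed, animal_id: str | None = None,
                    layout: ArenaLayout | None = None,
                    render: bool = True) -> tuple[TrackStream | None, GroundTruth]:
    """Generate one animal; returns (stream, truth).

    ``render=False`` skips coordinate emission (stream is None) and is the
    fast path for large cohorts; the ground truth is identical either way
    because all randomness lives in event generation.
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    rate = profile.sample_rate
    n_total = int(round(profile.duration_h * 3600 * rate))
    if animal_id is None:
        animal_id = f"{profile.name}-{seed}"

    entrance = _entrance_point(layout)
    wcage, hcage = layout.cage_width, layout.cage_height
    segments: list[TrueSegment] = []
    i = 0
    pos = entrance.copy()

    def clip_end(n: int) -> int:
        return min(i + n, n_total)

    while i < n_total:
        # ---- shelter visit ----------------------------------------------
        t_s = i / rate
        dark = (t_s % 86400.0) < 43200.0
        wts = _phase_weights(profile, dark)
        k = int(rng.choice(3, p=wts / wts.sum()))
        dur = 2.0 ** rng.normal(profile.shelter_means[k], profile.shelter_sds[k])
        n = max(int(round(dur * rate)), 8)
        j = clip_end(n)
        cls = ("short", "intermediate", "long")[k]
        if segments and segments[-1].kind == SHELTER:
            # no detected samples in between -> the detector would see one visit
            segments[-1].i_end = j
        else:
            segments.append(TrueSegment(SHELTER, i, j, gen_class=cls))
        i = j
        if i >= n_total:
            break

        # ---- outside excursion ------------------------------------------
        f = _activity_fraction(profile, i / rate)
        if f <= 1e-3:
            continue
        tau_sh = _expected_shelter_s(profile, dark)
        tau_out = tau_sh * f / (1.0 - f)
        # lognormal with mean tau_out (sigma 0.5)
        sig = 0.5
        target = tau_out * np.exp(rng.normal(-0.5 * sig * sig, sig))
        if target * rate < 10:
            continue
        i = _emit_excursion(profile, layout, rng, segments, i, n_total,
                            pos, entrance, target, rate, wcage, hcage, dark)
        pos = entrance.copy()

    arrest_durs = np.array([(s.i_end - s.i_start) / rate for s in segments
                            if s.kind == ARREST])
    truth = GroundTruth(
        animal_id=animal_id, strain=profile.name, sample_rate=rate,
        n_samples=n_total, segments=segments,
        thresholds=_true_thresholds(profile, arrest_durs),
        profile=profile, seed=seed,
    )
    _label_true_moves_arrests(truth)
    stream = render_track(truth, layout, rng_seed=rng.integers(2 ** 31)) if render else None
    return stream, truth


def _emit_excursion(profile, layout, rng, segments, i, n_total, pos, entrance,
                    target_s, rate, wcage, hcage, dark) -> int:
    """Append move/arrest segments for one excursion; returns the new index."""
    elapsed = 0.0
    pos = np.asarray(pos, float).copy()
    first = True
    while elapsed < target_s and i < n_total:
        # ---- move -------------------------------------------------------
        is_first = first
        long_move = first or (rng.random() < profile.p_long_move)
        first = False
        if long_move:
            dist = 2.0 ** rng.normal(profile.long_move_log2_mean,
                                     profile.long_move_log2_sd)
            v = float(np.clip(rng.normal(profile.long_move_velocity,
                                         profile.long_move_velocity_sd), 3.0, 40.0))
            zone = ""
            u = rng.random()
            if u < profile.p_jump:
                zone = "onshelter_zone"
            elif u < profile.p_jump + profile.p_feed:
                zone = "feeding_zone"
            elif u < profile.p_jump + profile.p_feed + profile.p_spout:
                zone = "spout_zone"
        else:
            dist = 2.0 ** rng.normal(profile.short_move_log2_mean,
                                     profile.short_move_log2_sd)
            v = profile.short_move_velocity
            zone = ""
        dist = max(dist, _MIN_MOVE_CM)
        dist = min(dist, 80.0)
        if zone:
            tgt = _zone_point(layout, zone, rng)
            wpts, dist = _two_leg_path(pos, tgt, dist, rng, wcage, hcage)
        else:
            wpts, dist = _billiard_path(pos, dist, rng, wcage, hcage)
        # first move of an excursion must outlast the exit debounce so the
        # preceding shelter visit is closed by sustained re-detection
        n_mv = max(int(round(dist / v * rate)), 8 if is_first else 3)
        j = min(i + n_mv, n_total)
        segments.append(TrueSegment(MOVE, i, j, distance=dist,
                                    velocity=dist / ((j - i) / rate),
                                    waypoints=wpts))
        pos[:] = wpts[-1]
        elapsed += (j - i) / rate
        i = j
        if i >= n_total or elapsed >= target_s:
            break

        # ---- arrest -----------------------------------------------------
        if (not dark and profile.outside_rest_fraction > 0
                and rng.random() < profile.outside_rest_fraction):
            dur = rng.uniform(1800.0, 5400.0)      # outside nesting rest
        else:
            dur = 2.0 ** rng.normal(profile.arrest_log2_mean,
                                    profile.arrest_log2_sd)
        n_ar = max(int(round(dur * rate)), 4)
        j = min(i + n_ar, n_total)
        segments.append(TrueSegment(ARREST, i, j, zone=zone, pos=tuple(pos)))
        elapsed += (j - i) / rate
        i = j

    # ---- return to the entrance strip -----------------------------------
    if i < n_total:
        d = float(np.hypot(*(entrance - pos)))
        if d > 1e-6:
            v = float(np.clip(rng.normal(profile.long_move_velocity,
                                         profile.long_move_velocity_sd), 3.0, 40.0))
            n_mv = max(int(round(d / v * rate)), 3)
            j = min(i + n_mv, n_total)
            segments.append(TrueSegment(MOVE, i, j, distance=d,
                                        velocity=d / ((j - i) / rate),
                                        waypoints=(tuple(pos), tuple(entrance))))
            i = j
    return i


def _label_true_moves_arrests(truth: GroundTruth) -> None:
    """Class labels for true moves/arrests from the true thresholds
    (shelter labels already carry the generating class)."""
    thr_mv = truth.thresholds["long_move_threshold"]
    thr_ar = truth.thresholds["long_arrest_threshold"]
    rate = truth.sample_rate
    for s in truth.segments:
        if s.kind == MOVE:
            s.gen_class = "long" if s.distance >= thr_mv else "short"
        elif s.kind == ARREST:
            dur = (s.i_end - s.i_start) / rate
            s.gen_class = "long" if dur >= thr_ar else "short"


def render_track(truth: GroundTruth, layout: ArenaLayout | None = None,
                 jitter_cm: float = 0.02, rng_seed=0) -> TrackStream:
    """Emit the 15 Hz coordinate stream for a generated animal.

    Moves traverse their waypoint polyline at constant speed; arrests sit
    at their position; both get small isotropic jitter (clipped well below
    the arrest radius).  Shelter samples are undetected with NaN
    coordinates.
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(rng_seed)
    n = truth.n_samples
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    det = np.zeros(n, bool)
    for s in truth.segments:
        m = s.i_end - s.i_start
        if m <= 0:
            continue
        if s.kind == SHELTER:
            continue
        det[s.i_start:s.i_end] = True
        if s.kind == ARREST:
            x[s.i_start:s.i_end] = s.pos[0]
            y[s.i_start:s.i_end] = s.pos[1]
        else:
            pts = np.asarray(s.waypoints, float)
            seglen = np.hypot(*np.diff(pts, axis=0).T)
            cum = np.concatenate(([0.0], np.cumsum(seglen)))
            total = cum[-1] if cum[-1] > 0 else 1e-9
            arc = (np.arange(1, m + 1) / m) * total
            x[s.i_start:s.i_end] = np.interp(arc, cum, pts[:, 0])
            y[s.i_start:s.i_end] = np.interp(arc, cum, pts[:, 1])
    if jitter_cm > 0:
        jx = np.clip(rng.normal(0, jitter_cm, n), -0.045, 0.045)
        jy = np.clip(rng.normal(0, jitter_cm, n), -0.045, 0.045)
        x[det] += jx[det]
        y[det] += jy[det]
    np.clip(x, 0.01, layout.cage_width - 0.01, out=x)
    np.clip(y, 0.01, layout.cage_height - 0.01, out=y)
    x[~det] = np.nan
    y[~det] = np.nan
    rate = truth.sample_rate
    return TrackStream(
        animal_id=truth.animal_id, strain=truth.strain,
        t=np.arange(n) / rate, x=x, y=y, detected=det, sample_rate=rate,
    )


# ---------------------------------------------------------------------------
# strain panels and heritable variation

def paper_panel(**overrides) -> list[StrainProfile]:
    """The 11-strain reference panel with its unequal group sizes and
    hand-set strain flavor (nocturnality, anticipation, shelter-jumping)."""
    flavor = {
        "129S1/SvImJ": dict(p_jump=0.002, dark_activity=0.50),
        "A/J": dict(p_jump=0.002, dark_activity=0.65, light_activity=0.055),
        "BALB/cJ": dict(dark_activity=0.55),
        "C3H/HeJ": dict(p_jump=0.004, light_activity=0.18),
        "C57BL/6J": dict(anticipate_light_slope=0.12, dark_activity=0.62),
        "DBA/2J": dict(p_jump=0.10),
        "FVB/NJ": dict(anticipate_dark_slope=0.10, light_activity=0.20),
        "WSB/EiJ": dict(long_move_velocity=15.0),
        "PWK/PhJ": dict(dark_activity=0.70),
        "CAST/EiJ": dict(anticipate_dark_slope=0.15, dark_activity=0.72),
        "NOD/ShiLtJ": dict(),
    }
    out = []
    for strain, n in PAPER_STRAIN_N.items():
        kw = dict(name=strain, n_animals=n)
        kw.update(flavor.get(strain, {}))
        kw.update(overrides)
        out.append(StrainProfile(**kw))
    return out


def _logit(p):
    return math.log(p / (1 - p))


def _expit(z):
    return 1.0 / (1.0 + math.exp(-z))


#: profile fields that vary between strains and animals:
#: field -> (transform, inverse, total SD on the transformed scale)
HERITABLE_FIELDS: dict[str, tuple] = {
    "long_move_log2_mean": (lambda v: v, lambda z: z, 0.30),
    "short_move_log2_mean": (lambda v: v, lambda z: z, 0.20),
    "long_move_velocity": (math.log, math.exp, 0.12),
    "arrest_log2_mean": (lambda v: v, lambda z: z, 0.25),
    "dark_activity": (_logit, _expit, 0.30),
    "light_activity": (_logit, _expit, 0.35),
    "habituation": (math.log, math.exp, 0.08),
    "anticipate_dark_slope": (lambda v: v, lambda z: z, 0.03),
    "p_jump": (lambda v: max(v, 1e-4), lambda z: min(max(z, 0.0), 0.5), 0.02),
}


def _between_fraction(h2: float) -> float:
    """Share of total latent variance placed between strains so that the
    inbred-panel estimator h2 = 0.5 Vb / (0.5 Vb + Vw) targets ``h2``."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("heritability target must lie in [0, 1)")
    return 2.0 * h2 / (1.0 + h2)


def draw_cohort_fields(profiles: list[StrainProfile],
                       heritability_targets: dict[str, float],
                       rng) -> tuple[list[list[StrainProfile]], dict]:
    """Per-animal realized profiles plus the latent draws.

    For each targeted field the per-strain values are re-centred on the
    panel mean (transformed scale), a strain effect with variance
    q * sd^2 (q = 2 h2 / (1 + h2)) is drawn, and each animal adds an
    independent effect with variance (1 - q) * sd^2.  A target of 0 makes
    all strain-level profiles identical for that field.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 strains")
    if all(p.n_animals < 2 for p in profiles):
        raise ValueError("within-strain variance inestimable: all strains have n=1")
    latents: dict[str, dict] = {}
    per_strain_fields: list[dict] = [dict() for _ in profiles]
    per_animal: list[list[dict]] = [[dict() for _ in range(p.n_animals)]
                                    for p in profiles]
    for fname, h2 in heritability_targets.items():
        fwd, inv, sd = HERITABLE_FIELDS[fname]
        q = _between_fraction(h2)
        base = float(np.mean([fwd(getattr(p, fname)) for p in profiles]))
        strain_z = rng.normal(0.0, math.sqrt(q) * sd, len(profiles))
        lat = {"base": base, "strain_z": strain_z, "animal_z": []}
        for si, p in enumerate(profiles):
            az = rng.normal(0.0, math.sqrt(1.0 - q) * sd, p.n_animals)
            lat["animal_z"].append(az)
            per_strain_fields[si][fname] = inv(base + strain_z[si])
            for ai in range(p.n_animals):
                per_animal[si][ai][fname] = inv(base + strain_z[si] + az[ai])
        latents[fname] = lat
    realized: list[list[StrainProfile]] = []
    for si, p in enumerate(profiles):
        animals = []
        for ai in range(p.n_animals):
            animals.append(replace(p, **per_animal[si][ai]))
        realized.append(animals)
    return realized, latents


def iter_cohort(profiles: list[StrainProfile],
                heritability_targets: dict[str, float] | None = None,
                seed: int = 0, render: bool = False,
                layout: ArenaLayout | None = None,
                tweak=None) -> Iterator[tuple[TrackStream | None, GroundTruth]]:
    """Generate a cohort lazily, one animal at a time.

    One master seed; per-animal substreams are derived from
    ``(seed, strain index, animal index)`` so any animal is reproducible
    independently of generation order.  ``tweak(strain_idx, animal_idx,
    profile) -> profile`` can override individual animals (e.g. to plant
    outside sleepers).
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    if heritability_targets:
        realized, _ = draw_cohort_fields(profiles, heritability_targets, rng)
    else:
        if len(profiles) < 2:
            raise ValueError("need at least 2 strains")
        realized = [[p] * p.n_animals for p in profiles]
    for si, animals in enumerate(realized):
        for ai, prof in enumerate(animals):
            if tweak is not None:
                prof = tweak(si, ai, prof)
            sub = np.random.default_rng([int(seed), si, ai])
            aid = f"{prof.name.replace('/', '_')}-{ai + 1:03d}"
            yield simulate_animal(prof, sub, animal_id=aid,
                                  layout=layout, render=render)


def simulate_cohort(profiles, heritability_targets=None, seed=0,
                    render: bool = False, layout=None,
                    tweak=None) -> list[tuple[TrackStream | None, GroundTruth]]:
    """Eager version of :func:`iter_cohort` (small cohorts only)."""
    return list(iter_cohort(profiles, heritability_targets, seed, render,
                            layout, tweak))


def simulate_strain_values(group_sizes: dict[str, int], h2: float, seed,
                           mean: float = 0.0, sd: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Value-level cohort: one phenotype per animal with strain structure.

    Draws strain effects and residuals so that the inbred-panel estimator
    targets ``h2`` in expectation; returns (values, strain labels).  This
    is the fast oracle cohort for estimator-recovery and null simulations.
    """
    rng = np.random.default_rng(seed)
    q = _between_fraction(h2)
    strains = list(group_sizes)
    vals = []
    labels = []
    for sname in strains:
        n = group_sizes[sname]
        b = rng.normal(0.0, math.sqrt(q) * sd)
        vals.append(mean + b + rng.normal(0.0, math.sqrt(1.0 - q) * sd, n))
        labels += [sname] * n
    return np.concatenate(vals), np.array(labels)
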