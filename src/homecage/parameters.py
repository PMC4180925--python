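"""Multi-timescale behavioral parameters and the parameter registry.

From one animal's classified segments this module derives:

* **activity bouts** — runs of behavior that start with a long movement and
  end at the first long arrest or at a shelter visit longer than the
  animal's brief-visit threshold;
* **12 h bins** — every measure aggregated per dark/light phase per day
  (durations clipped at bin edges, events assigned by start time);
* a **habituation index** per measure (day-3 over day-1 value of the
  matched phase; < 1 means decline with familiarity);
* a **DarkLight index** per measure (dark / (dark + light) on day 3;
  0.5 = phase-indifferent, 1 = fully nocturnal);
* **transition slopes** — OLS slopes of the proportion of time spent in
  activity bouts per 10-min bin over the 2 h before (anticipation) and
  after (response) each phase transition, excluding the 10-min bin
  adjacent to the transition (units: proportion per hour);

plus the outside-sleeper exclusion: animals that spend < 60 % of the
light phases of days 2-3 in the shelter while being dead-still (< 2 cm
cumulative movement per 5-min bin) for > 25 % of their outside time in
those phases rest outside the shelter and are dropped, because zone- and
arrest-based measures are confounded for them.

The registry is declarative and extensible; the default covers the 20 key
measures plus systematic per-bin family expansions, 115 parameters in all,
each tagged with one of the six categories (kinematics, sheltering,
activity bouts, habituation, darklight, pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .arena import LightSchedule, default_schedule
from .segmentation import ARREST, MOVE, SHELTER, Segment
from .thresholds import ThresholdSet

__all__ = [
    "AnimalRecord",
    "ActivityBout",
    "ParameterSpec",
    "ParameterMatrix",
    "assemble_bouts",
    "flag_outside_sleepers",
    "bin_cumulative_duration",
    "bin_event_counts",
    "bin_mean_duration",
    "habituation_index",
    "darklight_index",
    "transition_slopes",
    "activity_proportion",
    "default_registry",
    "build_parameter_matrix",
    "CATEGORIES",
]

log = logging.getLogger(__name__)

CATEGORIES = ("kinematics", "sheltering", "activity bouts",
              "habituation", "darklight", "pattern")

SEGMENT_CLASSES = (
    ("move", "short"), ("move", "long"),
    ("arrest", "short"), ("arrest", "long"),
    ("shelter", "short"), ("shelter", "intermediate"), ("shelter", "long"),
)


@dataclass
class ActivityBout:
    """A run of activity: opened by a long move, closed by a long arrest, a
    more-than-brief shelter visit, or the end of the recording.  The
    terminating event is excluded from the bout interval."""

    t_start: float
    t_end: float
    n_long_moves: int = 0
    n_jumps_onshelter: int = 0
    terminator: str = "recording end"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class AnimalRecord:
    """One animal's fully derived artifacts, the unit the registry reads.

    Built either from a tracked-and-segmented stream or directly from a
    simulator ground truth; both paths produce the same structure.
    """

    animal_id: str
    strain: str
    segments: list[Segment]                 # classified, time-ordered
    thresholds: ThresholdSet
    jump_times: np.ndarray                  # onshelter entries (s)
    zone_intervals: dict[str, list[tuple[float, float]]]
    duration_s: float = 72 * 3600.0
    schedule: LightSchedule = field(default_factory=default_schedule)
    excluded: bool = False

    def __post_init__(self) -> None:
        self._df: pd.DataFrame | None = None
        self._bouts: list[ActivityBout] | None = None

    @property
    def df(self) -> pd.DataFrame:
        if self._df is None:
            self._df = pd.DataFrame({
                "kind": [s.kind for s in self.segments],
                "cls": [s.class_label for s in self.segments],
                "t_start": [s.t_start for s in self.segments],
                "t_end": [s.t_end for s in self.segments],
                "duration": [s.duration for s in self.segments],
                "distance": [s.distance for s in self.segments],
                "max_velocity": [s.max_velocity for s in self.segments],
            })
        return self._df

    @property
    def bouts(self) -> list[ActivityBout]:
        if self._bouts is None:
            self._bouts = assemble_bouts(self.segments, self.thresholds,
                                         self.jump_times, self.duration_s)
        return self._bouts

    def select(self, kind: str, cls: str | None = None) -> pd.DataFrame:
        d = self.df
        m = d["kind"] == kind
        if cls is not None:
            m &= d["cls"] == cls
        return d[m]


def assemble_bouts(segments: Sequence[Segment], thresholds: ThresholdSet,
                   jump_times: np.ndarray | None = None,
                   duration_s: float | None = None) -> list[ActivityBout]:
    """Scan classified segments in time order and apply the bout rule.

    A bout opens at a long move not already inside a bout and closes at
    the first long arrest or shelter visit exceeding the brief-visit
    threshold; the terminating event is not part of the bout.  Short
    arrests, short moves and brief (passing-through) shelter visits do not
    interrupt a bout.
    """
    jump_times = np.asarray(jump_times if jump_times is not None else [], float)
    bouts: list[ActivityBout] = []
    cur: ActivityBout | None = None

    def close(t_end: float, terminator: str) -> None:
        nonlocal cur
        if cur is None:
            return
        cur.t_end = t_end
        cur.terminator = terminator
        cur.n_jumps_onshelter = int(np.sum(
            (jump_times >= cur.t_start) & (jump_times < cur.t_end)))
        bouts.append(cur)
        cur = None

    for s in segments:
        terminating = (
            (s.kind == ARREST and s.class_label == "long")
            or (s.kind == SHELTER
                and s.duration > thresholds.short_shelter_threshold)
        )
        if terminating:
            close(s.t_start, "long arrest" if s.kind == ARREST else "shelter visit")
            continue
        if s.kind == MOVE and s.class_label == "long":
            if cur is None:
                cur = ActivityBout(t_start=s.t_start, t_end=s.t_end)
            cur.n_long_moves += 1
        if cur is not None:
            cur.t_end = s.t_end
    if cur is not None:
        close(cur.t_end if duration_s is None else min(cur.t_end, duration_s),
              "recording end")
    return bouts


# ---------------------------------------------------------------------------
# interval arithmetic over the six 12 h bins

def _overlap(t0: np.ndarray, t1: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.clip(np.minimum(t1, b) - np.maximum(t0, a), 0.0, None)


def _bin_index(schedule: LightSchedule, n_days: int = 3) -> list[tuple[str, int]]:
    return [(ph, day) for (ph, day, _a, _b) in schedule.phase_bins(n_days)]


def bin_cumulative_duration(intervals: Iterable[tuple[float, float]],
                            schedule: LightSchedule, n_days: int = 3) -> pd.Series:
    """Total duration (s) per 12 h bin, intervals clipped at bin edges, so
    the six bins conserve the 3-day total."""
    iv = np.array(list(intervals), float).reshape(-1, 2)
    vals = [float(_overlap(iv[:, 0], iv[:, 1], a, b).sum()) if len(iv) else 0.0
            for (_p, _d, a, b) in schedule.phase_bins(n_days)]
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(
        _bin_index(schedule, n_days), names=("phase", "day")))


def bin_event_counts(times: Iterable[float], schedule: LightSchedule,
                     n_days: int = 3) -> pd.Series:
    """Number of events per 12 h bin, assigned by start time."""
    t = np.asarray(list(times), float)
    vals = [float(np.sum((t >= a) & (t < b)))
            for (_p, _d, a, b) in schedule.phase_bins(n_days)]
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(
        _bin_index(schedule, n_days), names=("phase", "day")))


def bin_mean_duration(intervals: Iterable[tuple[float, float]],
                      schedule: LightSchedule, n_days: int = 3) -> pd.Series:
    """Mean event duration per 12 h bin (events assigned by start time;
    NaN for bins without events)."""
    iv = np.array(list(intervals), float).reshape(-1, 2)
    vals = []
    for (_p, _d, a, b) in schedule.phase_bins(n_days):
        if len(iv):
            sel = (iv[:, 0] >= a) & (iv[:, 0] < b)
            vals.append(float(np.mean(iv[sel, 1] - iv[sel, 0])) if sel.any() else np.nan)
        else:
            vals.append(np.nan)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(
        _bin_index(schedule, n_days), names=("phase", "day")))


def habituation_index(binned: pd.Series, phase: str) -> float:
    """Day-3 over day-1 value of the given phase; NaN when day 1 is zero
    or either value is missing."""
    try:
        v1 = float(binned[(phase, 1)])
        v3 = float(binned[(phase, 3)])
    except KeyError:
        return np.nan
    if not np.isfinite(v1) or not np.isfinite(v3) or v1 == 0:
        if v1 == 0:
            log.debug("habituation index undefined: day-1 value is zero")
        return np.nan
    return v3 / v1


def darklight_index(dark_value: float, light_value: float) -> float:
    """dark / (dark + light); NaN when both are zero or either missing."""
    if not np.isfinite(dark_value) or not np.isfinite(light_value):
        return np.nan
    tot = dark_value + light_value
    if tot == 0:
        return np.nan
    return dark_value / tot


def darklight_from_binned(binned: pd.Series, day: int = 3) -> float:
    try:
        return darklight_index(float(binned[("dark", day)]),
                               float(binned[("light", day)]))
    except KeyError:
        return np.nan


# ---------------------------------------------------------------------------
# activity proportion and transition-pattern slopes

def activity_proportion(bout_intervals: Sequence[tuple[float, float]],
                        t_edges: np.ndarray) -> np.ndarray:
    """Fraction of each time bin spent inside activity bouts."""
    iv = np.array(list(bout_intervals), float).reshape(-1, 2)
    out = np.zeros(len(t_edges) - 1)
    for i, (a, b) in enumerate(zip(t_edges[:-1], t_edges[1:])):
        if len(iv):
            out[i] = _overlap(iv[:, 0], iv[:, 1], a, b).sum() / (b - a)
    return out


def _window_slope(bout_iv, t_from: float, t_to: float, bin_s: float,
                  duration_s: float) -> float:
    """OLS slope (proportion per hour) of per-bin activity proportion."""
    if t_from < 0 or t_to > duration_s or t_to <= t_from:
        return np.nan
    edges = np.arange(t_from, t_to + bin_s / 2, bin_s)
    if len(edges) < 3:
        return np.nan
    prop = activity_proportion(bout_iv, edges)
    centers_h = (edges[:-1] + bin_s / 2) / 3600.0
    return float(np.polyfit(centers_h, prop, 1)[0])


def transition_slopes(bout_intervals: Sequence[tuple[float, float]],
                      schedule: LightSchedule, day: int = 3,
                      window_h: float = 2.0, bin_min: float = 10.0,
                      duration_s: float = 72 * 3600.0) -> dict[str, float]:
    """Anticipation and response slopes around the day's two transitions.

    Anticipation windows cover the ``window_h`` hours before the named
    phase begins, response windows the same span after; the 10-min bin
    adjacent to the transition is excluded on both sides.
    """
    dark_s = schedule.dark_hours * 3600.0
    t_dark_on = (day - 1) * 86400.0
    t_light_on = t_dark_on + dark_s
    w = window_h * 3600.0
    g = bin_min * 60.0
    bout_iv = list(bout_intervals)
    return {
        "anticipate_dark": _window_slope(bout_iv, t_dark_on - w, t_dark_on - g, g, duration_s),
        "respond_dark": _window_slope(bout_iv, t_dark_on + g, t_dark_on + w, g, duration_s),
        "anticipate_light": _window_slope(bout_iv, t_light_on - w, t_light_on - g, g, duration_s),
        "respond_light": _window_slope(bout_iv, t_light_on + g, t_light_on + w, g, duration_s),
    }


# ---------------------------------------------------------------------------
# outside-sleeper exclusion

def _light_bins_days23(schedule: LightSchedule):
    return [(a, b) for (ph, day, a, b) in schedule.phase_bins(3)
            if ph == "light" and day in (2, 3)]


def flag_outside_sleepers(record: AnimalRecord,
                          shelter_frac_limit: float = 0.60,
                          still_cm: float = 2.0,
                          still_bin_s: float = 300.0,
                          still_frac_limit: float = 0.25) -> dict:
    """Joint low-shelter-occupancy / low-outside-mobility exclusion test.

    Over the pooled light phases of days 2 and 3: the animal is flagged
    when its shelter-time fraction is below ``shelter_frac_limit`` AND the
    fraction of its outside 5-min bins (bins at least half outside the
    shelter) with cumulative movement below ``still_cm`` exceeds
    ``still_frac_limit``.  Returns both criteria separately plus the flag;
    ``evaluable`` is False for records not covering days 2-3.
    """
    windows = _light_bins_days23(record.schedule)
    if record.duration_s + 1e-6 < windows[-1][1]:
        return {"flag": False, "evaluable": False,
                "shelter_fraction": np.nan, "still_fraction": np.nan}
    d = record.df
    sh = d[d["kind"] == SHELTER]
    sh_t0 = sh["t_start"].to_numpy()
    sh_t1 = sh["t_end"].to_numpy()
    mv = d[d["kind"] == MOVE]
    mv_t0 = mv["t_start"].to_numpy()
    mv_t1 = mv["t_end"].to_numpy()
    mv_dist = mv["distance"].to_numpy()
    mv_dur = np.maximum(mv_t1 - mv_t0, 1e-9)

    total = sum(b - a for (a, b) in windows)
    shelter_time = sum(float(_overlap(sh_t0, sh_t1, a, b).sum()) if len(sh) else 0.0
                       for (a, b) in windows)
    shelter_fraction = shelter_time / total

    n_outside = 0
    n_still = 0
    for (a, b) in windows:
        edges = np.arange(a, b + 1e-6, still_bin_s)
        for lo, hi in zip(edges[:-1], edges[1:]):
            sh_in = float(_overlap(sh_t0, sh_t1, lo, hi).sum()) if len(sh) else 0.0
            if sh_in > 0.5 * (hi - lo):
                continue
            n_outside += 1
            if len(mv):
                frac = _overlap(mv_t0, mv_t1, lo, hi) / mv_dur
                dist = float(np.sum(mv_dist * frac))
            else:
                dist = 0.0
            if dist < still_cm:
                n_still += 1
    still_fraction = (n_still / n_outside) if n_outside else 0.0
    flag = (shelter_fraction < shelter_frac_limit) and (still_fraction > still_frac_limit)
    return {"flag": bool(flag), "evaluable": True,
            "shelter_fraction": shelter_fraction,
            "still_fraction": still_fraction}


# ---------------------------------------------------------------------------
# the parameter registry

@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    func: Callable[[AnimalRecord], float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _intervals(df: pd.DataFrame) -> list[tuple[float, float]]:
    return list(zip(df["t_start"], df["t_end"]))


def _class_category(kind: str) -> str:
    return "sheltering" if kind == SHELTER else "kinematics"


def _bin_label(phase: str, day: int) -> str:
    return f"{phase}{day}"


def _nanmax(a) -> float:
    a = np.asarray(a, float)
    a = a[np.isfinite(a)]
    return float(a.max()) if len(a) else np.nan


def _make_singletons() -> list[ParameterSpec]:
    return [
        ParameterSpec("long_move_threshold_cm", "kinematics",
                      lambda r: r.thresholds.long_move_threshold),
        ParameterSpec("long_arrest_threshold_s", "kinematics",
                      lambda r: r.thresholds.long_arrest_threshold),
        ParameterSpec("short_shelter_threshold_s", "sheltering",
                      lambda r: r.thresholds.short_shelter_threshold),
        ParameterSpec("long_shelter_threshold_s", "sheltering",
                      lambda r: r.thresholds.long_shelter_threshold),
        ParameterSpec("long_move_max_velocity", "kinematics",
                      lambda r: _nanmax(r.select(MOVE, "long")["max_velocity"])),
        ParameterSpec("mean_long_arrest_duration", "kinematics",
                      lambda r: float(r.select(ARREST, "long")["duration"].mean())),
        ParameterSpec("total_distance_per_24h", "kinematics",
                      lambda r: float(r.select(MOVE)["distance"].sum())
                      / (r.duration_s / 86400.0)),
        ParameterSpec("cum_long_shelter_per_24h", "sheltering",
                      lambda r: float(r.select(SHELTER, "long")["duration"].sum())
                      / (r.duration_s / 86400.0)),
        ParameterSpec("mean_long_shelter_duration", "sheltering",
                      lambda r: float(r.select(SHELTER, "long")["duration"].mean())),
        ParameterSpec("long_shelter_fraction", "sheltering",
                      lambda r: (len(r.select(SHELTER, "long"))
                                 / max(len(r.select(SHELTER)), 1))),
        ParameterSpec("feeding_zone_fraction", "sheltering",
                      lambda r: sum(b - a for a, b in
                                    r.zone_intervals.get("feeding_zone", []))
                      / r.duration_s),
        ParameterSpec("spout_zone_fraction", "sheltering",
                      lambda r: sum(b - a for a, b in
                                    r.zone_intervals.get("spout_zone", []))
                      / r.duration_s),
        ParameterSpec("onshelter_jumps_total", "activity bouts",
                      lambda r: float(len(r.jump_times))),
        ParameterSpec("activity_fraction_total", "activity bouts",
                      lambda r: sum(b.duration for b in r.bouts) / r.duration_s),
    ]


def _class_freq_param(kind: str, cls: str, phase: str, day: int) -> ParameterSpec:
    name = f"{cls}_{kind}_freq_{_bin_label(phase, day)}"

    def func(r: AnimalRecord, kind=kind, cls=cls, phase=phase, day=day) -> float:
        times = r.select(kind, cls)["t_start"]
        return float(bin_event_counts(times, r.schedule)[(phase, day)])

    return ParameterSpec(name, _class_category(kind), func)


def _class_cumdur_param(kind: str, cls: str, phase: str, day: int) -> ParameterSpec:
    name = f"{cls}_{kind}_cumdur_{_bin_label(phase, day)}"

    def func(r: AnimalRecord, kind=kind, cls=cls, phase=phase, day=day) -> float:
        iv = _intervals(r.select(kind, cls))
        return float(bin_cumulative_duration(iv, r.schedule)[(phase, day)])

    return ParameterSpec(name, _class_category(kind), func)


def _bout_param(measure: str, phase: str, day: int) -> ParameterSpec:
    name = f"bout_{measure}_{_bin_label(phase, day)}"

    def func(r: AnimalRecord, measure=measure, phase=phase, day=day) -> float:
        iv = [(b.t_start, b.t_end) for b in r.bouts]
        if measure == "count":
            return float(bin_event_counts([a for a, _ in iv], r.schedule)[(phase, day)])
        if measure == "cumdur":
            return float(bin_cumulative_duration(iv, r.schedule)[(phase, day)])
        return float(bin_mean_duration(iv, r.schedule)[(phase, day)])

    return ParameterSpec(name, "activity bouts", func)


_HAB_SOURCES = {
    "activity": lambda r: bin_cumulative_duration(
        [(b.t_start, b.t_end) for b in r.bouts], r.schedule),
    "bout_count": lambda r: bin_event_counts(
        [b.t_start for b in r.bouts], r.schedule),
    "shelter_time": lambda r: bin_cumulative_duration(
        _intervals(r.select(SHELTER)), r.schedule),
    "move_freq": lambda r: bin_event_counts(
        r.select(MOVE, "long")["t_start"], r.schedule),
}

_DL_SOURCES = dict(_HAB_SOURCES)
_DL_SOURCES["jumps"] = lambda r: bin_event_counts(r.jump_times, r.schedule)


def _hab_param(source: str, phase: str) -> ParameterSpec:
    name = f"habituation_{source}_{phase}"

    def func(r: AnimalRecord, source=source, phase=phase) -> float:
        return habituation_index(_HAB_SOURCES[source](r), phase)

    return ParameterSpec(name, "habituation", func)


def _dl_param(source: str) -> ParameterSpec:
    name = f"darklight_{source}"

    def func(r: AnimalRecord, source=source) -> float:
        return darklight_from_binned(_DL_SOURCES[source](r))

    return ParameterSpec(name, "darklight", func)


def _slope_param(which: str) -> ParameterSpec:
    def func(r: AnimalRecord, which=which) -> float:
        iv = [(b.t_start, b.t_end) for b in r.bouts]
        return transition_slopes(iv, r.schedule,
                                 duration_s=r.duration_s)[which]

    return ParameterSpec(f"slope_{which}", "pattern", func)


def default_registry() -> list[ParameterSpec]:
    """The shipped 115-parameter registry.

    14 singleton measures (thresholds, peak velocity, headline sheltering
    and zone measures), per-12 h-bin frequency for all seven segment
    classes (42), per-bin cumulative duration for the four resting classes
    (24), per-bin bout count / cumulative / mean duration (18), habituation
    indices for four measures x two phases (8), DarkLight indices for five
    measures (5) and the four transition slopes (4).
    """
    specs = _make_singletons()
    bins = [(ph, day) for day in (1, 2, 3) for ph in ("dark", "light")]
    for kind, cls in SEGMENT_CLASSES:
        for ph, day in bins:
            specs.append(_class_freq_param(kind, cls, ph, day))
    for kind, cls in (("arrest", "long"), ("shelter", "short"),
                      ("shelter", "intermediate"), ("shelter", "long")):
        for ph, day in bins:
            specs.append(_class_cumdur_param(kind, cls, ph, day))
    for measure in ("count", "cumdur", "meandur"):
        for ph, day in bins:
            specs.append(_bout_param(measure, ph, day))
    for source in _HAB_SOURCES:
        for ph in ("dark", "light"):
            specs.append(_hab_param(source, ph))
    for source in _DL_SOURCES:
        specs.append(_dl_param(source))
    for which in ("anticipate_dark", "respond_dark",
                  "anticipate_light", "respond_light"):
        specs.append(_slope_param(which))
    names = [s.name for s in specs]
    assert len(names) == len(set(names)), "duplicate parameter names"
    return specs


@dataclass
class ParameterMatrix:
    """Animals x parameters with strain labels and category tags."""

    values: pd.DataFrame            # index: animal_id
    strains: pd.Series              # index: animal_id
    categories: dict[str, str]      # parameter -> category

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    def category_of(self, name: str) -> str:
        return self.categories[name]


def build_parameter_matrix(records: Iterable[AnimalRecord],
                           registry: list[ParameterSpec] | None = None,
                           drop_excluded: bool = True) -> ParameterMatrix:
    """Evaluate every registered parameter for every (non-excluded) animal.

    Missing values are explicit NaN; an empty registry is a configuration
    error.
    """
    registry = default_registry() if registry is None else registry
    if not registry:
        raise ValueError("empty parameter registry")
    rows = {}
    strains = {}
    for rec in records:
        if drop_excluded and rec.excluded:
            continue
        rows[rec.animal_id] = [spec.func(rec) for spec in registry]
        strains[rec.animal_id] = rec.strain
    if not rows:
        raise ValueError("no animals to tabulate")
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[s.name for s in registry]).astype(float)
    return ParameterMatrix(
        values=df,
        strains=pd.Series(strains, name="strain"),
        categories={s.name: s.category for s in registry},
    )


# ---------------------------------------------------------------------------
# building records from the two upstream paths

def record_from_truth(truth, thresholds: ThresholdSet | None = None,
                      schedule: LightSchedule | None = None,
                      use_pipeline_thresholds: bool = True) -> AnimalRecord:
    """AnimalRecord from a simulator ground truth (event-level path).

    By default thresholds are re-estimated from the true segments with the
    pipeline's own estimator, so the whole downstream method is exercised;
    pass ``use_pipeline_thresholds=False`` to classify with the generating
    thresholds instead.
    """
    from .thresholds import classify_segments, compute_thresholds

    schedule = schedule or default_schedule()
    segs = truth.to_segments()
    if thresholds is None:
        if use_pipeline_thresholds:
            thresholds = compute_thresholds(segs)
        else:
            thresholds = ThresholdSet(**truth.thresholds)
    classify_segments(segs, thresholds)
    return AnimalRecord(
        animal_id=truth.animal_id, strain=truth.strain,
        segments=segs, thresholds=thresholds,
        jump_times=truth.jump_times(),
        zone_intervals={
            "feeding_zone": truth.zone_intervals("feeding_zone"),
            "spout_zone": truth.zone_intervals("spout_zone"),
        },
        duration_s=truth.n_samples / truth.sample_rate,
        schedule=schedule,
    )


def record_from_stream(stream, layout, thresholds: ThresholdSet | None = None,
                       schedule: LightSchedule | None = None,
                       smoothing=None) -> AnimalRecord:
    """AnimalRecord from a raw tracking stream (full pipeline path)."""
    from .segmentation import SmoothingParams, segment_stream
    from .thresholds import classify_segments, compute_thresholds

    schedule = schedule or default_schedule()
    smoothing = smoothing or SmoothingParams()
    arts = segment_stream(stream, layout, smoothing)
    segs = arts["segments"]
    if thresholds is None:
        thresholds = compute_thresholds(segs)
    classify_segments(segs, thresholds)
    zones = arts["zones"]
    jump_times = np.array([a for (a, _b) in zones.get("onshelter_zone", [])])
    return AnimalRecord(
        animal_id=stream.animal_id, strain=stream.strain,
        segments=segs, thresholds=thresholds,
        jump_times=jump_times,
        zone_intervals={k: v for k, v in zones.items() if k != "onshelter_zone"},
        duration_s=stream.duration,
        schedule=schedule,
    )
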