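"""Mouse-determined thresholds for classifying behavioral elements.

Rather than imposing fixed cutoffs, each animal's own event-size
distributions define its class boundaries:

* move distances (log2 cm) are bimodal; two Gaussian curves are fitted to
  the binned histogram by constrained least squares and the **long-move
  threshold** is the abscissa where the curves intersect between their
  means;
* the **long-arrest threshold** is the empirical 90th percentile of the
  animal's arrest durations over the whole record;
* shelter-visit durations (log2 s) form three classes; a 3-component fit
  yields the **long-visit threshold** (intersection of components 2 and 3)
  and the **short-visit threshold** (90th percentile of fitted component 1,
  i.e. mean1 + z0.9 * sd1).

Fits use bounded nonlinear least squares on histogram bin counts
(bin width 0.5 log2 units) with the component means box-constrained to
[-6, 1] and [1, 6] log2 cm for moves and [0, 10], [9, 10], [10, 15]
log2 s for shelter visits, started from five deterministic initializations
spread across the mean boxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .segmentation import ARREST, MOVE, SHELTER, Segment

__all__ = [
    "Log2Histogram",
    "GaussianComponent",
    "MixtureFit",
    "ThresholdSet",
    "fit_move_mixture",
    "arrest_threshold",
    "fit_shelter_mixture",
    "classify_segments",
    "compute_thresholds",
    "cohort_thresholds",
    "gaussian_intersection",
]

log = logging.getLogger(__name__)

BIN_WIDTH = 0.5                  # log2 units
MOVE_MEAN_BOXES = ((-6.0, 1.0), (1.0, 6.0))          # log2 cm
SHELTER_MEAN_BOXES = ((0.0, 10.0), (9.0, 10.0), (10.0, 15.0))  # log2 s
Z90 = float(norm.ppf(0.9))       # 1.2816...

MIN_MOVES = 50
MIN_SHELTER_VISITS = 50
MIN_ARRESTS = 10


@dataclass(frozen=True)
class Log2Histogram:
    """Histogram of log2-transformed event sizes with 0.5-unit bins."""

    edges: np.ndarray
    counts: np.ndarray
    variable: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @classmethod
    def from_values(cls, values: np.ndarray, variable: str = "",
                    bin_width: float = BIN_WIDTH, phase: float = 0.0) -> "Log2Histogram":
        """Bin log2(values) into contiguous ``bin_width`` bins.

        Edges sit on multiples of ``bin_width`` shifted by ``phase``
        (``phase`` exists to probe bin-alignment sensitivity).
        """
        v = np.asarray(values, float)
        if np.any(v <= 0):
            raise ValueError("values must be positive for a log2 histogram")
        lv = np.log2(v)
        lo = np.floor((lv.min() - phase) / bin_width) * bin_width + phase
        hi = np.ceil((lv.max() - phase) / bin_width + 1e-9) * bin_width + phase
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, _ = np.histogram(lv, bins=edges)
        return cls(edges=edges, counts=counts.astype(float), variable=variable)


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted Gaussian curve: amplitude * exp(-(x-mean)^2 / (2 sd^2)).

    The weight is on the count scale of the histogram (curve amplitude),
    matching a least-squares fit to bin counts.
    """

    mean: float
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    def curve(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.weight * np.exp(-((x - self.mean) ** 2) / (2 * self.sd ** 2))


@dataclass
class MixtureFit:
    components: tuple[GaussianComponent, ...]
    residual: float
    ok: bool
    message: str = ""


def _mixture_model(params: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(x)
    for i in range(k):
        m, s, w = params[3 * i:3 * i + 3]
        out += w * np.exp(-((x - m) ** 2) / (2 * s ** 2))
    return out


def fit_mixture(hist: Log2Histogram, mean_boxes) -> MixtureFit:
    """Bounded least-squares fit of ``len(mean_boxes)`` Gaussian curves to
    the bin counts, multi-started from five deterministic initializations.
    """
    k = len(mean_boxes)
    x = hist.centers
    yobs = hist.counts
    span = float(hist.edges[-1] - hist.edges[0])
    amp = max(yobs.max(), 1.0)

    lb, ub = [], []
    for (mlo, mhi) in mean_boxes:
        lb += [mlo, 0.05, 0.0]
        ub += [mhi, max(span, 2.0), 10.0 * amp]
    lb = np.array(lb)
    ub = np.array(ub)

    best: optimize.OptimizeResult | None = None
    for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
        p0 = []
        for (mlo, mhi) in mean_boxes:
            p0 += [mlo + frac * (mhi - mlo), 1.0, amp]
        p0 = np.clip(np.array(p0), lb + 1e-9, ub - 1e-9)
        try:
            res = optimize.least_squares(
                lambda p: _mixture_model(p, x, k) - yobs,
                p0, bounds=(lb, ub), method="trf", max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - optimizer blow-up
            log.warning("mixture fit start failed: %s", exc)
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return MixtureFit(components=(), residual=np.inf, ok=False,
                          message="optimizer failure")
    comps = tuple(
        GaussianComponent(mean=float(best.x[3 * i]),
                          sd=float(best.x[3 * i + 1]),
                          weight=float(best.x[3 * i + 2]))
        for i in range(k)
    )
    comps = tuple(sorted(comps, key=lambda c: c.mean))
    return MixtureFit(components=comps, residual=float(best.cost), ok=True)


def gaussian_intersection(c1: GaussianComponent, c2: GaussianComponent) -> float | None:
    """Abscissa where the two curves cross, restricted to (mean1, mean2).

    Roots are located by sign changes of the curve difference on a fine
    grid followed by bisection refinement; with several roots the one
    nearest the midpoint of the means is returned (deterministic
    tie-break).  ``None`` when the curves do not cross between the means.
    """
    lo, hi = sorted((c1.mean, c2.mean))
    if hi - lo < 1e-9:
        return None
    grid = np.linspace(lo, hi, 512)
    diff = c1.curve(grid) - c2.curve(grid)
    sign = np.sign(diff)
    idx = np.flatnonzero(np.diff(sign) != 0)
    roots = []
    f = lambda x: c1.curve(np.array([x]))[0] - c2.curve(np.array([x]))[0]
    for i in idx:
        a, b = grid[i], grid[i + 1]
        if sign[i] == 0:
            roots.append(float(a))
            continue
        try:
            roots.append(float(optimize.brentq(f, a, b, xtol=1e-10)))
        except ValueError:
            continue
    if not roots:
        return None
    mid = 0.5 * (lo + hi)
    return min(roots, key=lambda r: abs(r - mid))


@dataclass
class ThresholdSet:
    """Per-animal cutoffs separating element classes (natural units)."""

    long_move_threshold: float       # cm
    long_arrest_threshold: float     # s
    short_shelter_threshold: float   # s
    long_shelter_threshold: float    # s
    flags: dict = field(default_factory=dict)  # quantity -> fallback reason

    def __post_init__(self) -> None:
        vals = (self.long_move_threshold, self.long_arrest_threshold,
                self.short_shelter_threshold, self.long_shelter_threshold)
        if any(np.isfinite(v) and v <= 0 for v in vals):
            raise ValueError("thresholds must be positive")
        if (np.isfinite(self.short_shelter_threshold)
                and np.isfinite(self.long_shelter_threshold)
                and self.short_shelter_threshold >= self.long_shelter_threshold):
            raise ValueError("short shelter threshold must be below long")


def fit_move_mixture(move_distances_cm: np.ndarray,
                     phase: float = 0.0) -> tuple[MixtureFit, float | None]:
    """Two-component fit to the log2 move-distance histogram.

    Returns the fit and the long-move threshold in cm (``None`` when the
    fit fails or the curves do not intersect between their means; the
    caller substitutes a cohort median and flags the animal).
    """
    d = np.asarray(move_distances_cm, float)
    d = d[d > 0]
    if len(d) < MIN_MOVES:
        raise ValueError(f"need >= {MIN_MOVES} move segments, got {len(d)}")
    hist = Log2Histogram.from_values(d, "move distance (cm)", phase=phase)
    fit = fit_mixture(hist, MOVE_MEAN_BOXES)
    if not fit.ok:
        return fit, None
    xing = gaussian_intersection(fit.components[0], fit.components[1])
    if xing is None:
        fit.ok = False
        fit.message = "no intersection between component means"
        return fit, None
    return fit, float(2.0 ** xing)


def arrest_threshold(arrest_durations_s: np.ndarray) -> float:
    """Empirical 90th percentile of arrest durations (linear interpolation
    between order statistics)."""
    d = np.asarray(arrest_durations_s, float)
    if len(d) < MIN_ARRESTS:
        raise ValueError(f"need >= {MIN_ARRESTS} arrests, got {len(d)}")
    return float(np.percentile(d, 90.0, method="linear"))


def fit_shelter_mixture(visit_durations_s: np.ndarray,
                        phase: float = 0.0) -> tuple[MixtureFit, float | None, float | None]:
    """Three-component fit to the log2 shelter-visit duration histogram.

    Returns (fit, short_threshold_s, long_threshold_s): the short cutoff is
    the 90th percentile of fitted component 1 (mean1 + 1.2816 sd1 in log2
    units), the long cutoff the intersection of components 2 and 3.
    """
    d = np.asarray(visit_durations_s, float)
    d = d[d > 0]
    if len(d) < MIN_SHELTER_VISITS:
        raise ValueError(f"need >= {MIN_SHELTER_VISITS} shelter visits, got {len(d)}")
    hist = Log2Histogram.from_values(d, "shelter visit duration (s)", phase=phase)
    fit = fit_mixture(hist, SHELTER_MEAN_BOXES)
    if not fit.ok:
        return fit, None, None
    c1, c2, c3 = fit.components
    short = float(2.0 ** (c1.mean + Z90 * c1.sd))
    xing = gaussian_intersection(c2, c3)
    if xing is None:
        fit.ok = False
        fit.message = "no intersection between components 2 and 3"
        return fit, short, None
    long_thr = float(2.0 ** xing)
    if long_thr <= short:
        fit.ok = False
        fit.message = "long threshold not above short threshold"
        return fit, short, None
    return fit, short, long_thr


def compute_thresholds(segments: list[Segment]) -> ThresholdSet:
    """All four thresholds for one animal from its 3-day segment list.

    Unfittable quantities come back NaN with a reason in ``flags``;
    :func:`cohort_thresholds` substitutes cohort medians for those.
    """
    moves = np.array([s.distance for s in segments if s.kind == MOVE])
    arrests = np.array([s.duration for s in segments if s.kind == ARREST])
    visits = np.array([s.duration for s in segments if s.kind == SHELTER])
    flags: dict[str, str] = {}

    try:
        _, move_thr = fit_move_mixture(moves)
        if move_thr is None:
            flags["long_move_threshold"] = "fit failure"
            move_thr = np.nan
    except ValueError as exc:
        flags["long_move_threshold"] = str(exc)
        move_thr = np.nan

    try:
        arr_thr = arrest_threshold(arrests)
    except ValueError as exc:
        flags["long_arrest_threshold"] = str(exc)
        arr_thr = np.nan

    try:
        _, short_thr, long_thr = fit_shelter_mixture(visits)
        if short_thr is None or long_thr is None:
            flags["shelter_thresholds"] = "fit failure"
            short_thr = np.nan if short_thr is None else short_thr
            long_thr = np.nan
    except ValueError as exc:
        flags["shelter_thresholds"] = str(exc)
        short_thr = long_thr = np.nan

    return ThresholdSet(
        long_move_threshold=float(move_thr),
        long_arrest_threshold=float(arr_thr),
        short_shelter_threshold=float(short_thr),
        long_shelter_threshold=float(long_thr),
        flags=flags,
    )


def cohort_thresholds(per_animal_segments: dict[str, list[Segment]]) -> dict[str, ThresholdSet]:
    """Thresholds for every animal, with cohort-median fallback.

    Animals whose fit failed (flagged) receive the cohort median of the
    corresponding threshold; the flag is retained for the QC report.
    """
    sets = {aid: compute_thresholds(segs)
            for aid, segs in per_animal_segments.items()}
    fields = ("long_move_threshold", "long_arrest_threshold",
              "short_shelter_threshold", "long_shelter_threshold")
    medians = {}
    for f in fields:
        vals = np.array([getattr(ts, f) for ts in sets.values()])
        vals = vals[np.isfinite(vals)]
        medians[f] = float(np.median(vals)) if len(vals) else np.nan
    for aid, ts in sets.items():
        for f in fields:
            if not np.isfinite(getattr(ts, f)):
                setattr(ts, f, medians[f])
                ts.flags.setdefault(f, "cohort-median fallback")
                log.warning("%s: %s fell back to cohort median %.3g",
                            aid, f, medians[f])
    return sets


def classify_segments(segments: list[Segment], thresholds: ThresholdSet) -> list[Segment]:
    """Assign class labels in place (and return the list).

    Moves and arrests at exactly the threshold are classified long (the
    upper class is closed); shelter visits are short strictly below the
    short cutoff, long strictly above the long cutoff, intermediate
    between (cutoff values inclusive).
    """
    for s in segments:
        if s.kind == MOVE:
            s.class_label = "long" if s.distance >= thresholds.long_move_threshold else "short"
        elif s.kind == ARREST:
            s.class_label = "long" if s.duration >= thresholds.long_arrest_threshold else "short"
        else:
            if s.duration < thresholds.short_shelter_threshold:
                s.class_label = "short"
            elif s.duration > thresholds.long_shelter_threshold:
                s.class_label = "long"
            else:
                s.class_label = "intermediate"
    return segments
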