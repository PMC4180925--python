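"""In-memory cohort workflow: simulate -> thresholds -> exclusion -> matrix.

The disk-based stage runner lives in :mod:`homecage.cli`; this module
drives the same steps in memory, streaming one animal at a time so that
cohorts of hundreds of 3-day animals stay within a laptop's memory.
Animals whose mixture fits fail are re-processed at the end with
cohort-median thresholds (the standard fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import LightSchedule, default_schedule
from .parameters import (AnimalRecord, ParameterMatrix, ParameterSpec,
                         build_parameter_matrix, default_registry,
                         flag_outside_sleepers, record_from_truth)
from .simulate import GroundTruth, StrainProfile, iter_cohort
from .thresholds import ThresholdSet, classify_segments, compute_thresholds

__all__ = ["CohortResult", "tabulate_event_cohort"]

log = logging.getLogger(__name__)

_THRESHOLD_FIELDS = ("long_move_threshold", "long_arrest_threshold",
                     "short_shelter_threshold", "long_shelter_threshold")


@dataclass
class CohortResult:
    matrix: ParameterMatrix             # excluded animals already dropped
    exclusions: pd.DataFrame            # per-animal flag + diagnostics
    thresholds: pd.DataFrame            # per-animal threshold table
    n_animals: int
    n_excluded: int


def _make_record(truth: GroundTruth, ts: ThresholdSet,
                 schedule: LightSchedule) -> AnimalRecord:
    segs = truth.to_segments()
    classify_segments(segs, ts)
    return AnimalRecord(
        animal_id=truth.animal_id, strain=truth.strain,
        segments=segs, thresholds=ts,
        jump_times=truth.jump_times(),
        zone_intervals={
            "feeding_zone": truth.zone_intervals("feeding_zone"),
            "spout_zone": truth.zone_intervals("spout_zone"),
        },
        duration_s=truth.n_samples / truth.sample_rate,
        schedule=schedule,
    )


def tabulate_event_cohort(profiles: list[StrainProfile],
                          seed: int = 0,
                          heritability_targets: dict[str, float] | None = None,
                          tweak=None,
                          registry: list[ParameterSpec] | None = None,
                          schedule: LightSchedule | None = None) -> CohortResult:
    """Run the event-level cohort workflow end to end.

    Per animal: estimate the four mouse-determined thresholds, classify
    segments, apply the outside-sleeper exclusion, and evaluate the
    parameter registry.  Unfittable animals fall back to the cohort median
    threshold and are re-evaluated after the first pass.
    """
    registry = default_registry() if registry is None else registry
    schedule = schedule or default_schedule()
    rows: dict[str, list[float]] = {}
    strains: dict[str, str] = {}
    thr_rows = []
    excl_rows = []
    deferred: list[tuple[GroundTruth, ThresholdSet]] = []

    def tabulate(truth: GroundTruth, ts: ThresholdSet) -> None:
        rec = _make_record(truth, ts, schedule)
        diag = flag_outside_sleepers(rec)
        rec.excluded = bool(diag["flag"])
        excl_rows.append({"animal_id": rec.animal_id, "strain": rec.strain,
                          **diag})
        if not rec.excluded:
            rows[rec.animal_id] = [spec.func(rec) for spec in registry]
            strains[rec.animal_id] = rec.strain

    for _stream, truth in iter_cohort(profiles, heritability_targets,
                                      seed=seed, render=False, tweak=tweak):
        ts = compute_thresholds(truth.to_segments())
        thr_rows.append({"animal_id": truth.animal_id,
                         **{f: getattr(ts, f) for f in _THRESHOLD_FIELDS},
                         "flags": ";".join(ts.flags)})
        if all(np.isfinite(getattr(ts, f)) for f in _THRESHOLD_FIELDS):
            tabulate(truth, ts)
        else:
            deferred.append((truth, ts))

    if deferred:
        thr_df = pd.DataFrame(thr_rows)
        medians = {f: float(np.nanmedian(thr_df[f])) for f in _THRESHOLD_FIELDS}
        log.warning("%d animals fell back to cohort-median thresholds",
                    len(deferred))
        for truth, ts in deferred:
            for f in _THRESHOLD_FIELDS:
                if not np.isfinite(getattr(ts, f)):
                    setattr(ts, f, medians[f])
                    ts.flags.setdefault(f, "cohort-median fallback")
            tabulate(truth, ts)

    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[s.name for s in registry]).astype(float)
    df = df.sort_index()
    matrix = ParameterMatrix(
        values=df,
        strains=pd.Series(strains, name="strain").loc[df.index],
        categories={s.name: s.category for s in registry},
    )
    excl = pd.DataFrame(excl_rows).set_index("animal_id").sort_index()
    return CohortResult(
        matrix=matrix,
        exclusions=excl,
        thresholds=pd.DataFrame(thr_rows).set_index("animal_id").sort_index(),
        n_animals=len(excl),
        n_excluded=int(excl["flag"].sum()),
    )
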