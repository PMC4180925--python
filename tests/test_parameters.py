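import numpy as np
import pytest

from homecage.arena import default_schedule
from homecage.parameters import (
    AnimalRecord,
    CATEGORIES,
    assemble_bouts,
    bin_cumulative_duration,
    bin_event_counts,
    build_parameter_matrix,
    darklight_index,
    default_registry,
    flag_outside_sleepers,
    habituation_index,
    record_from_truth,
    transition_slopes,
)
from homecage.segmentation import Segment
from homecage.thresholds import ThresholdSet

H12 = 12 * 3600.0
DAY = 24 * 3600.0


def _seg(kind, t0, dur, dist=0.0, cls=""):
    return Segment("a", kind, t0, t0 + dur, distance=dist, class_label=cls)


def _thr():
    return ThresholdSet(long_move_threshold=4.0, long_arrest_threshold=10.0,
                        short_shelter_threshold=20.0,
                        long_shelter_threshold=1000.0)


class TestBouts:
    def test_bout_spans_through_internal_short_arrest(self):
        """[long move, short arrest, long move, long arrest] -> one bout
        that excludes the terminating long arrest."""
        segs = [
            _seg("move", 0, 2, dist=8, cls="long"),
            _seg("arrest", 2, 3, cls="short"),
            _seg("move", 5, 2, dist=9, cls="long"),
            _seg("arrest", 7, 30, cls="long"),
        ]
        bouts = assemble_bouts(segs, _thr())
        assert len(bouts) == 1
        assert bouts[0].t_start == 0 and bouts[0].t_end == 7
        assert bouts[0].n_long_moves == 2
        assert bouts[0].terminator == "long arrest"

    def test_no_long_move_no_bout(self):
        segs = [_seg("move", 0, 1, dist=1, cls="short"),
                _seg("arrest", 1, 2, cls="short")]
        assert assemble_bouts(segs, _thr()) == []

    def test_brief_shelter_visit_does_not_terminate(self):
        segs = [
            _seg("move", 0, 2, dist=8, cls="long"),
            _seg("shelter", 2, 5, cls="short"),          # 5 s < 20 s cutoff
            _seg("move", 7, 2, dist=9, cls="long"),
            _seg("shelter", 9, 500, cls="intermediate"),  # terminates
        ]
        bouts = assemble_bouts(segs, _thr())
        assert len(bouts) == 1
        assert bouts[0].t_end == 9
        assert bouts[0].terminator == "shelter visit"

    def test_bout_count_close_to_ground_truth(self, full_animal, full_record):
        """The bout rule applied to recovered artifacts lands within 5 % of
        its application to the generating segments."""
        from homecage.thresholds import classify_segments
        true_segs = full_animal.to_segments()
        tru = full_animal.thresholds
        ts = ThresholdSet(tru["long_move_threshold"],
                          tru["long_arrest_threshold"],
                          tru["short_shelter_threshold"],
                          tru["long_shelter_threshold"])
        true_bouts = assemble_bouts(classify_segments(true_segs, ts), ts)
        rec_bouts = full_record.bouts
        assert abs(len(rec_bouts) - len(true_bouts)) / len(true_bouts) < 0.05

    def test_bouts_never_overlap(self, full_record):
        b = full_record.bouts
        assert all(x.t_end <= y.t_start + 1e-9 for x, y in zip(b, b[1:]))
        total_bout = sum(x.duration for x in b)
        outside = sum(s.duration for s in full_record.segments
                      if s.kind != "shelter")
        assert total_bout <= outside + 1e-6


class TestBinning:
    def test_event_straddling_bin_edge_is_split(self, schedule):
        """A 2 h interval starting 1 h before an edge contributes 1 h to
        each neighbouring bin."""
        iv = [(H12 - 3600.0, H12 + 3600.0)]
        binned = bin_cumulative_duration(iv, schedule)
        assert binned[("dark", 1)] == pytest.approx(3600.0)
        assert binned[("light", 1)] == pytest.approx(3600.0)

    def test_uniform_event_rate_gives_equal_counts(self, schedule):
        times = np.arange(0, 72 * 3600, 600.0)
        counts = bin_event_counts(times, schedule)
        assert (counts == counts.iloc[0]).all()

    def test_clipping_conserves_total(self, schedule):
        rng = np.random.default_rng(0)
        t0 = np.sort(rng.uniform(0, 71 * 3600, 200))
        iv = [(a, a + d) for a, d in zip(t0, rng.uniform(1, 3600, 200))]
        binned = bin_cumulative_duration(iv, schedule)
        assert binned.sum() == pytest.approx(sum(b - a for a, b in iv))


class TestIndices:
    def test_habituation_identity_and_doubling(self, schedule):
        import pandas as pd
        idx = pd.MultiIndex.from_product([["dark", "light"], [1, 2, 3]],
                                         names=("phase", "day"))
        flat = pd.Series(5.0, index=idx)
        assert habituation_index(flat, "dark") == pytest.approx(1.0)
        doubled = flat.copy()
        doubled[("dark", 3)] = 10.0
        assert habituation_index(doubled, "dark") == pytest.approx(2.0)
        zero = flat.copy()
        zero[("light", 1)] = 0.0
        assert np.isnan(habituation_index(zero, "light"))

    def test_darklight_identities(self):
        assert darklight_index(3.0, 3.0) == pytest.approx(0.5)
        assert darklight_index(3.0, 0.0) == pytest.approx(1.0)
        assert np.isnan(darklight_index(0.0, 0.0))

    @pytest.fixture(scope="class")
    def index_sample(self):
        """Dark-phase habituation and DarkLight indices of eight animals
        from one generating profile (rare hours-long shelter visits make
        single-animal indices noisy, so the generator arithmetic is
        checked on the mean)."""
        from homecage.simulate import StrainProfile, simulate_animal
        from homecage.parameters import darklight_from_binned, record_from_truth
        profile = StrainProfile(dark_activity=0.60, light_activity=0.10,
                                habituation=0.85)
        habs, dls = [], []
        for seed in range(310, 318):
            _, truth = simulate_animal(profile, seed=seed, render=False)
            rec = record_from_truth(truth)
            iv = [(b.t_start, b.t_end) for b in rec.bouts]
            binned = bin_cumulative_duration(iv, rec.schedule)
            habs.append(habituation_index(binned, "dark"))
            dls.append(darklight_from_binned(binned))
        return np.array(habs), np.array(dls)

    def test_simulated_habituation_index(self, index_sample):
        """Generating multiplier 0.85/day -> mean day3/day1 activity ratio
        near 0.85^2 = 0.72."""
        habs, _ = index_sample
        assert np.mean(habs) == pytest.approx(0.85 ** 2, abs=0.15)

    def test_simulated_darklight_index(self, index_sample):
        """Generating dark share 0.60/(0.60+0.10) = 0.857."""
        _, dls = index_sample
        assert np.mean(dls) == pytest.approx(0.857, abs=0.04)


class TestTransitionSlopes:
    def test_constant_activity_gives_zero_slopes(self, schedule):
        # bouts everywhere: activity proportion is 1 in every bin
        iv = [(0.0, 72 * 3600.0)]
        slopes = transition_slopes(iv, schedule)
        for v in slopes.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_recovers_slope(self, schedule):
        """Activity ramping 0 -> 0.5 over the 2 h before dark onset on day 3
        gives an anticipation slope of 0.25 per hour."""
        t_tr = 2 * DAY
        rng_edges = np.arange(t_tr - 7200.0, t_tr, 60.0)
        iv = []
        for a in rng_edges:
            frac = 0.5 * (a - (t_tr - 7200.0)) / 7200.0
            if frac > 0:
                iv.append((a, a + 60.0 * frac))
        slopes = transition_slopes(iv, schedule, day=3)
        assert slopes["anticipate_dark"] == pytest.approx(0.25, rel=0.05)

    def test_out_of_record_window_is_missing(self, schedule):
        slopes = transition_slopes([(0.0, 3600.0)], schedule, day=1)
        assert np.isnan(slopes["anticipate_dark"])   # window before t=0


class TestOutsideSleepers:
    def _record(self, segments, duration=72 * 3600.0):
        return AnimalRecord("a", "s", segments, _thr(), np.array([]), {},
                            duration_s=duration)

    def test_full_shelter_occupancy_not_flagged(self):
        segs = [_seg("shelter", 0, 72 * 3600.0, cls="long")]
        diag = flag_outside_sleepers(self._record(segs))
        assert not diag["flag"]
        assert diag["shelter_fraction"] == pytest.approx(1.0)

    def test_outside_nester_flagged(self):
        """40 % shelter during light of days 2-3, dead still outside."""
        segs = []
        for day in (1, 2, 3):
            t0 = (day - 1) * DAY
            segs.append(_seg("shelter", t0, H12, cls="long"))          # dark inside
            segs.append(_seg("shelter", t0 + H12, 0.4 * H12, cls="long"))
            segs.append(_seg("arrest", t0 + H12 + 0.4 * H12, 0.6 * H12,
                             cls="long"))                               # still outside
        diag = flag_outside_sleepers(self._record(segs))
        assert diag["flag"]
        assert diag["shelter_fraction"] == pytest.approx(0.4)
        assert diag["still_fraction"] > 0.25

    def test_mobile_animal_with_low_shelter_not_flagged(self):
        """Same 40 % shelter but constantly moving outside."""
        segs = []
        for day in (1, 2, 3):
            t0 = (day - 1) * DAY
            segs.append(_seg("shelter", t0, H12, cls="long"))
            segs.append(_seg("shelter", t0 + H12, 0.4 * H12, cls="long"))
            t = t0 + H12 + 0.4 * H12
            while t < t0 + DAY:
                segs.append(_seg("move", t, 60.0, dist=50.0, cls="long"))
                t += 60.0
        diag = flag_outside_sleepers(self._record(segs))
        assert not diag["flag"]
        assert diag["still_fraction"] == pytest.approx(0.0)

    def test_incomplete_record_unevaluable(self):
        segs = [_seg("shelter", 0, DAY, cls="long")]
        diag = flag_outside_sleepers(self._record(segs, duration=DAY))
        assert not diag["evaluable"]


class TestRegistry:
    def test_default_registry_has_115_unique_tagged_parameters(self):
        reg = default_registry()
        assert len(reg) == 115
        names = [s.name for s in reg]
        assert len(set(names)) == 115
        assert {s.category for s in reg} == set(CATEGORIES)

    def test_empty_registry_is_an_error(self, full_record):
        with pytest.raises(ValueError, match="empty"):
            build_parameter_matrix([full_record], [])

    def test_matrix_shape_and_explicit_missing(self, full_record):
        pm = build_parameter_matrix([full_record])
        assert pm.values.shape == (1, 115)
        assert pm.strains.loc[full_record.animal_id] == full_record.strain
        # missing values are explicit NaN floats, never silent drops
        assert pm.values.dtypes.unique().tolist() == [np.dtype(float)]

    def test_darklight_column_is_compositional(self, full_record):
        """The registry's darklight_activity equals the index applied to the
        animal's binned bout durations."""
        from homecage.parameters import darklight_from_binned
        pm = build_parameter_matrix([full_record])
        iv = [(b.t_start, b.t_end) for b in full_record.bouts]
        expect = darklight_from_binned(
            bin_cumulative_duration(iv, full_record.schedule))
        assert pm.values.loc[full_record.animal_id, "darklight_activity"] == \
            pytest.approx(expect)
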