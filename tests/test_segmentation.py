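import numpy as np
import pytest

from homecage.segmentation import (
    ARREST,
    MOVE,
    SHELTER,
    SmoothingParams,
    detect_shelter_visits,
    running_median,
    segment_moves_arrests,
    segment_stream,
    smooth_track,
    zone_occupancy,
)
from homecage.track import TrackStream

RATE = 15.0
DT = 1.0 / RATE


def brute_median(values, h):
    """Independent oracle: median over each (2h+1)-neighbourhood, window
    shrunk at the edges."""
    n = len(values)
    return np.array([np.median(values[max(0, i - h):min(n, i + h + 1)])
                     for i in range(n)])


def make_stream(x, y, detected=None, animal="t", strain="s"):
    x = np.asarray(x, float)
    n = len(x)
    det = np.ones(n, bool) if detected is None else np.asarray(detected, bool)
    return TrackStream(animal, strain, np.arange(n) * DT, x, np.asarray(y, float),
                       det, RATE)


class TestRunningMedian:
    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("h", [1, 2, 3])
    def test_matches_brute_force_neighbourhood_median(self, seed, h):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2 * h + 1, 100))
        v = rng.normal(size=n)
        np.testing.assert_allclose(running_median(v, h), brute_median(v, h))

    def test_constant_input_unchanged(self):
        v = np.full(50, 3.7)
        xs, ys = smooth_track(v, v)
        np.testing.assert_array_equal(xs, v)
        np.testing.assert_array_equal(ys, v)

    def test_single_sample_impulse_removed(self):
        """A 5 cm one-sample spike vanishes under the first (window-7) pass."""
        x = np.full(60, 10.0)
        x[30] += 5.0
        xs, _ = smooth_track(x, np.zeros_like(x))
        np.testing.assert_array_equal(xs, np.full(60, 10.0))

    def test_short_run_passed_through(self, caplog):
        v = np.arange(4.0)
        with caplog.at_level("WARNING"):
            xs, _ = smooth_track(v, v)
        np.testing.assert_array_equal(xs, v)
        assert "unsmoothed" in caplog.text


class TestMovesArrests:
    def test_all_stationary_is_one_arrest(self):
        t = np.arange(10) * DT
        x = np.full(10, 5.0)
        segs = segment_moves_arrests(t, x, x, DT)
        assert len(segs) == 1
        assert segs[0].kind == ARREST
        assert segs[0].duration == pytest.approx(10 * DT)

    def test_two_sample_pause_absorbed_into_move(self):
        """A stationary stretch shorter than the 3-sample minimum does not
        become an arrest."""
        x = np.concatenate([np.arange(10) * 0.5,          # move, ends at 4.5
                            np.full(2, 4.75),             # 2-sample pause
                            5.25 + np.arange(10) * 0.5])  # move
        t = np.arange(len(x)) * DT
        segs = segment_moves_arrests(t, x, np.zeros_like(x), DT)
        assert [s.kind for s in segs] == [MOVE]

    def test_constructed_move_stop_move(self):
        """20 cm move, 5 s stop, 10 cm move -> move/arrest/move with the
        stated distances and durations (within one sample)."""
        n1, na, n2 = 30, 75, 15
        x = np.concatenate([
            np.linspace(0, 20, n1, endpoint=False) + 20 / n1,
            np.full(na, 20.0),
            np.linspace(20, 30, n2, endpoint=False) + 10 / n2,
        ])
        t = np.arange(len(x)) * DT
        segs = segment_moves_arrests(t, x, np.zeros_like(x), DT)
        kinds = [s.kind for s in segs]
        assert kinds == [MOVE, ARREST, MOVE]
        # boundary steps on either side of a segment belong to neither
        # neighbour, so distances agree within two per-sample steps
        assert segs[0].distance == pytest.approx(20.0, abs=2 * 20 / n1 + 1e-9)
        assert segs[1].duration == pytest.approx(na * DT, abs=2 * DT)
        assert segs[2].distance == pytest.approx(10.0, abs=2 * 10 / n2 + 1e-9)

    def test_exact_tiling(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.choice([0.0, 0.4], size=200, p=[0.7, 0.3]))
        t = np.arange(len(x)) * DT
        segs = segment_moves_arrests(t, x, np.zeros_like(x), DT)
        assert segs[0].t_start == 0.0
        for a, b in zip(segs, segs[1:]):
            assert a.t_end == pytest.approx(b.t_start)
        assert segs[-1].t_end == pytest.approx(len(x) * DT)

    def test_empty_run(self):
        assert segment_moves_arrests(np.array([]), np.array([]), np.array([]), DT) == []


class TestShelterVisits:
    def entrance_xy(self, layout):
        c = layout.polygon("entrance_zone").centroid
        return c.x, c.y

    def build(self, layout, pattern):
        """pattern: list of (n_samples, 'in'|'out'|'lost') blocks; 'in' sits
        in the entrance strip, 'out' in open cage, 'lost' undetected."""
        ex, ey = self.entrance_xy(layout)
        xs, ys, det = [], [], []
        for n, what in pattern:
            if what == "lost":
                xs += [np.nan] * n
                ys += [np.nan] * n
                det += [False] * n
            elif what == "in":
                xs += [ex] * n
                ys += [ey] * n
                det += [True] * n
            else:
                xs += [20.0] * n
                ys += [5.0] * n
                det += [True] * n
        return make_stream(xs, ys, det)

    def test_flicker_does_not_close_visit(self, layout):
        """Loss in the entrance strip, a 3-sample re-detection, loss again,
        then 20 detected samples -> ONE visit ending at the sustained
        re-detection."""
        stream = self.build(layout, [(30, "out"), (10, "in"), (40, "lost"),
                                     (3, "in"), (50, "lost"), (20, "in")])
        visits = detect_shelter_visits(stream, layout)
        assert len(visits) == 1
        assert visits[0].t_start == pytest.approx(40 * DT)
        assert visits[0].t_end == pytest.approx((40 + 40 + 3 + 50) * DT)

    def test_never_lost_stream_has_no_visits(self, layout):
        stream = self.build(layout, [(100, "out")])
        assert detect_shelter_visits(stream, layout) == []

    def test_loss_outside_entrance_is_dropout_not_visit(self, layout, caplog):
        stream = self.build(layout, [(30, "out"), (40, "lost"), (30, "out")])
        with caplog.at_level("WARNING"):
            visits = detect_shelter_visits(stream, layout)
        assert visits == []
        assert "dropout" in caplog.text

    def test_simulated_visit_schedule_recovered(self, layout, short_animal):
        """Visit count and durations recovered within the 7-sample debounce."""
        stream, truth = short_animal
        visits = detect_shelter_visits(stream, layout)
        true_visits = [s for s in truth.segments if s.kind == SHELTER]
        assert len(visits) == len(true_visits)
        for rec, tru in zip(visits, true_visits):
            assert abs(rec.t_start - tru.i_start / RATE) <= 7 * DT + 1e-9
            assert abs(rec.duration - (tru.i_end - tru.i_start) / RATE) <= 7 * DT + 1e-9


class TestZones:
    def test_never_entering_feeding_zone(self, layout):
        stream = make_stream(np.full(50, 25.0), np.full(50, 25.0))
        occ = zone_occupancy(stream, layout)
        assert occ["feeding_zone"] == []

    def test_three_crossings_three_intervals(self, layout):
        # feeding zone is x in [10,20], y in [0,4]
        blocks = []
        for _ in range(3):
            blocks += [(15.0, 2.0)] * 5 + [(25.0, 15.0)] * 5
        x, y = zip(*blocks)
        occ = zone_occupancy(make_stream(x, y), layout)
        assert len(occ["feeding_zone"]) == 3


class TestEndToEnd:
    def test_tiling_and_boundary_recovery(self, layout, short_animal):
        """Visits + outside segments tile the record; >= 95 % of true
        boundaries are recovered within 3 samples."""
        stream, truth = short_animal
        arts = segment_stream(stream, layout)
        segs = sorted(arts["segments"], key=lambda s: s.t_start)
        assert segs[0].t_start == pytest.approx(0.0)
        for a, b in zip(segs, segs[1:]):
            assert a.t_end == pytest.approx(b.t_start, abs=1e-6)
        assert segs[-1].t_end == pytest.approx(len(stream) * DT)

        true_b = sorted({s.i_start for s in truth.segments})
        rec_b = np.array(sorted({round(s.t_start * RATE) for s in segs}))
        hits = 0
        for b in true_b:
            j = np.searchsorted(rec_b, b)
            nearest = min(abs(rec_b[k] - b)
                          for k in (max(j - 1, 0), min(j, len(rec_b) - 1)))
            hits += nearest <= 3
        assert hits / len(true_b) >= 0.95


class TestSmoothingParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SmoothingParams(half_windows=(1, 2))      # increasing
        with pytest.raises(ValueError):
            SmoothingParams(epsilon=0.0)
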