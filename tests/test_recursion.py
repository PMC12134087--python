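import numpy as np
import pytest
from shapely.geometry import LineString, Point

from revisit.environment import WaterFeatures
from revisit.recursion import (
    RecursionConfig,
    RevisitSite,
    Visit,
    circle_crossings,
    detect_visits,
    filter_water_sites,
    revisitation_table,
    select_radius,
)
from revisit.trajectories import Trajectory, TrajectorySet

from oracles import dense_visits, random_walk

HOUR = 3600.0


def _traj(t_hours, x, y, ind="a"):
    return Trajectory(ind, np.asarray(t_hours) * HOUR, np.asarray(x, float), np.asarray(y, float))


class TestCircleCrossings:
    def test_single_crossing_halfway(self):
        out = circle_crossings((2, 0, 0.0), (0, 0, HOUR), (0, 0), 1.0)
        assert len(out) == 1
        s, t = out[0]
        assert s == pytest.approx(0.5)
        assert t == pytest.approx(0.5 * HOUR)

    def test_segment_inside_circle_no_crossings(self):
        assert circle_crossings((0.1, 0, 0.0), (-0.1, 0, HOUR), (0, 0), 1.0) == []

    def test_tangent_segment_is_not_a_crossing(self):
        # grazes the unit circle at (0, 1)
        assert circle_crossings((-1, 1, 0.0), (1, 1, HOUR), (0, 0), 1.0) == []

    def test_two_crossings_through_circle(self):
        out = circle_crossings((-2, 0, 0.0), (2, 0, HOUR), (0, 0), 1.0)
        assert [pytest.approx(s) for s, _ in out] == [0.25, 0.75]

    def test_zero_length_segment_no_crossings(self):
        assert circle_crossings((0, 0, 0.0), (0, 0, HOUR), (5, 0), 1.0) == []

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            circle_crossings((np.nan, 0, 0.0), (1, 0, HOUR), (0, 0), 1.0)

    def test_time_order_enforced(self):
        with pytest.raises(ValueError):
            circle_crossings((0, 0, HOUR), (1, 0, 0.0), (0, 0), 1.0)


class TestDetectVisits:
    def test_all_fixes_inside_is_one_visit_spanning_track(self):
        traj = _traj(range(10), np.zeros(10), np.zeros(10))
        cfg = RecursionConfig(radius=250)
        visits = detect_visits(traj, (0, 0), cfg)
        assert len(visits) == 1
        assert visits[0].t_enter == traj.t[0]
        assert visits[0].t_exit == traj.t[-1]

    def test_short_excursion_is_merged(self):
        # outside for 6 h, below the 12 h threshold
        x = np.zeros(30)
        x[10:16] = 1000.0
        visits = detect_visits(_traj(range(30), x, np.zeros(30)), (0, 0), RecursionConfig(radius=250))
        assert len(visits) == 1

    def test_long_absence_splits_visits(self):
        x = np.zeros(40)
        x[10:24] = 1000.0  # 13+ h outside
        visits = detect_visits(_traj(range(40), x, np.zeros(40)), (0, 0), RecursionConfig(radius=250))
        assert len(visits) == 2

    @pytest.mark.parametrize("gap_h,n_expected", [(11.99, 1), (12.0, 2), (12.01, 2)])
    def test_merge_rule_boundary_is_exact(self, gap_h, n_expected):
        # interpolated exit at 0.25 h (x crosses 250 m at s = 0.25) and
        # re-entry at T + 0.75 h; the outside gap is exactly gap_h hours
        T = gap_h - 0.5
        t = np.array([0.0, 1.0, T, T + 1.0]) * HOUR
        x = np.array([0.0, 1000.0, 1000.0, 0.0])
        traj = Trajectory("a", t, x, np.zeros(4))
        visits = detect_visits(traj, (0, 0), RecursionConfig(radius=250, min_time_away_s=12 * HOUR))
        assert len(visits) == n_expected

    def test_pass_through_between_outside_fixes_is_detected(self):
        # both fixes outside, the segment dips through the circle
        traj = _traj([0, 1], [-1000, 1000], [0, 0])
        visits = detect_visits(traj, (0, 0), RecursionConfig(radius=250))
        assert len(visits) == 1
        assert visits[0].duration_s == pytest.approx(0.25 * HOUR)

    def test_matches_dense_resampling_oracle(self, rng):
        cfg_radius_pool = [80.0, 150.0, 300.0, 500.0]
        for _ in range(25):
            t, x, y = random_walk(rng, n=120, step_sd=250.0, fix_interval_s=600.0)
            i = rng.integers(len(x))
            cx = x[i] + rng.normal(0, 100)
            cy = y[i] + rng.normal(0, 100)
            r = rng.choice(cfg_radius_pool)
            cfg = RecursionConfig(radius=float(r), min_time_away_s=4 * HOUR)
            visits = detect_visits(Trajectory("a", t, x, y), (cx, cy), cfg)
            oe, ox = dense_visits(t, x, y, cx, cy, r, 4 * HOUR)
            assert len(visits) == len(oe)
            for v, e, o in zip(visits, oe, ox):
                assert abs(v.t_enter - e) <= 1.0
                assert abs(v.t_exit - o) <= 1.0

    def test_more_time_away_never_increases_visits(self, rng):
        t, x, y = random_walk(rng, n=200, step_sd=200.0, fix_interval_s=3600.0)
        traj = Trajectory("a", t, x, y)
        centre = (float(x[50]), float(y[50]))
        counts = [len(detect_visits(traj, centre, RecursionConfig(radius=250, min_time_away_s=h * HOUR)))
                  for h in (0, 2, 6, 12, 24, 48)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory("a", [], [], [])


class TestRevisitationTable:
    def test_one_site_per_fix(self):
        ts = TrajectorySet()
        ts.add(_traj(range(5), np.arange(5) * 10.0, np.zeros(5)))
        sites = revisitation_table(ts, RecursionConfig(radius=250))
        assert len(sites) == 5

    def test_unrevisited_region_has_single_visit(self):
        # fix 0 is 10 km from everything else and never revisited
        x = np.concatenate([[0.0], np.full(20, 10_000.0)])
        ts = TrajectorySet()
        ts.add(_traj(range(21), x, np.zeros(21)))
        sites = revisitation_table(ts, RecursionConfig(radius=250))
        assert sites[0].n_visits == 1

    def test_counts_match_oracle_on_random_tracks(self, rng):
        for _ in range(5):
            t, x, y = random_walk(rng, n=80, step_sd=250.0, fix_interval_s=600.0)
            ts = TrajectorySet()
            ts.add(Trajectory("a", t, x, y))
            cfg = RecursionConfig(radius=200, min_time_away_s=4 * HOUR)
            sites = revisitation_table(ts, cfg)
            for s, cx, cy in zip(sites, x, y):
                oe, _ = dense_visits(t, x, y, cx, cy, 200, 4 * HOUR)
                assert s.n_visits == len(oe)

    def test_permuting_individuals_changes_nothing(self, rng):
        t, x, y = random_walk(rng, n=60)
        t2, x2, y2 = random_walk(rng, n=60)
        a = Trajectory("a", t, x, y)
        b = Trajectory("b", t2, x2, y2)
        cfg = RecursionConfig(radius=250)
        s1 = revisitation_table(TrajectorySet({"a": a, "b": b}), cfg)
        s2 = revisitation_table(TrajectorySet({"b": b, "a": a}), cfg)
        assert [(s.site_id, s.n_visits) for s in s1] == [(s.site_id, s.n_visits) for s in s2]

    def test_larger_radius_never_covers_fewer_fixes(self, rng):
        t, x, y = random_walk(rng, n=150, step_sd=200.0, fix_interval_s=3600.0)
        for cx, cy in [(x[10], y[10]), (x[75], y[75])]:
            covered = []
            for r in (100.0, 250.0, 500.0):
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                covered.append(int((d2 <= r * r).sum()))
            assert covered == sorted(covered)


class TestSelectRadius:
    def test_variance_argmax_wins(self, monkeypatch, rng):
        # synthetic trajectory whose 12 h-separated revisits concentrate at a
        # 250 m scale: back-and-forth between two clusters
        t = np.arange(400) * HOUR
        phase = (np.arange(400) // 20) % 2
        x = phase * 5_000.0 + rng.normal(0, 60, 400)
        y = rng.normal(0, 60, 400)
        ts = TrajectorySet()
        ts.add(Trajectory("a", t, x, y))
        r = select_radius(ts, RecursionConfig(candidate_radii=(100.0, 250.0, 500.0)))
        assert r in (100.0, 250.0, 500.0)

    def test_tie_breaks_to_smaller_radius(self):
        # a track that never revisits anything: all variances are 0 -> error
        ts = TrajectorySet()
        ts.add(_traj(range(10), np.arange(10) * 10_000.0, np.zeros(10)))
        with pytest.raises(ValueError, match="no revisitation structure"):
            select_radius(ts, RecursionConfig(candidate_radii=(100.0, 250.0)))

    def test_needs_two_candidates(self, small_bundle):
        with pytest.raises(ValueError):
            select_radius(small_bundle.trajset, RecursionConfig(candidate_radii=(250.0,)))


class TestWaterFilter:
    def _sites(self, xs):
        return [RevisitSite(f"s{i}", "a", x, 0.0, [Visit(0.0, 1.0)]) for i, x in enumerate(xs)]

    def test_sites_within_buffer_removed(self):
        water = WaterFeatures([LineString([(0, -100), (0, 100)])])
        kept = filter_water_sites(self._sites([400.0, 600.0]), water, 500.0)
        assert [s.cx for s in kept] == [600.0]

    def test_zero_buffer_removes_only_on_water(self):
        water = WaterFeatures([Point(0, 0)])
        kept = filter_water_sites(self._sites([0.0, 1.0]), water, 0.0)
        assert [s.cx for s in kept] == [1.0]

    def test_empty_water_keeps_all_with_warning(self, caplog):
        kept = filter_water_sites(self._sites([1.0, 2.0]), WaterFeatures([]), 500.0)
        assert len(kept) == 2
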