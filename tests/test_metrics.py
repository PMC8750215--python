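import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tipcollide import (
    AnalysisConfig,
    analyze_cell,
    classify_collision,
    collision_kinetics,
    near_collision_speed,
    spot_max_displacement,
    step_speeds,
    straightness_change,
    summarize_cell,
    track_metrics,
    track_metrics_table,
)
from tipcollide.errors import (
    DegenerateTrackError,
    InsufficientWindowError,
    ValidationError,
)

from conftest import make_spots, make_tracks, straight_track


def track_df(points, track_id=1):
    return pd.DataFrame(
        [(track_id, f, x, y) for f, x, y in points],
        columns=["track_id", "frame", "x", "y"],
    )


def track_from_speeds(speeds, interval=1.0):
    """Straight track along x whose per-step speeds are as given."""
    x = np.concatenate([[0.0], np.cumsum(np.asarray(speeds) * interval)])
    return track_df([(f, xi, 0.0) for f, xi in enumerate(x)])


class TestStepSpeeds:
    def test_single_step(self):
        t = track_df([(0, 0, 0), (1, 0.2, 0)])
        assert step_speeds(t, 1.0) == pytest.approx([0.2])

    def test_stationary_track_all_zero(self):
        t = track_df([(f, 1.0, 1.0) for f in range(5)])
        assert np.all(step_speeds(t, 1.0) == 0.0)

    def test_frame_gaps_divide_by_elapsed_time(self):
        t = track_df([(0, 0, 0), (2, 0.4, 0)])
        assert step_speeds(t, 1.0) == pytest.approx([0.2])

    def test_random_track_matches_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, size=(20, 2))
        t = track_df([(f, p[0], p[1]) for f, p in enumerate(pts)])
        expected = [
            math.dist(pts[i], pts[i + 1]) / 0.5 for i in range(19)
        ]
        assert step_speeds(t, 0.5) == pytest.approx(expected)

    def test_duplicate_frames_rejected(self):
        t = track_df([(0, 0, 0), (0, 1, 0), (1, 2, 0)])
        with pytest.raises(ValidationError):
            step_speeds(t, 1.0)


class TestTrackMetrics:
    def test_collinear_track_straightness_one(self):
        m = track_metrics(track_df([(0, 0, 0), (1, 1, 0), (2, 2, 0)]), 1.0)
        assert m.straightness == 1.0

    def test_right_angle_path(self):
        m = track_metrics(track_df([(0, 0, 0), (1, 1, 0), (2, 1, 1)]), 1.0)
        assert m.displacement_um == pytest.approx(math.sqrt(2), abs=1e-12)
        assert m.length_um == pytest.approx(2.0, abs=1e-12)
        assert m.straightness == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    def test_closed_loop_straightness_zero(self):
        m = track_metrics(
            track_df([(0, 0, 0), (1, 1, 0), (2, 1, 1), (3, 0, 1), (4, 0, 0)]), 1.0
        )
        assert m.straightness == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            track_metrics(track_df([(0, 0, 0)]), 1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=2,
            max_size=20,
        ),
        st.floats(0.1, 10.0),
    )
    def test_straightness_bounds_and_scale_invariance(self, pts, scale):
        t = track_df([(f, x, y) for f, (x, y) in enumerate(pts)])
        m = track_metrics(t, 1.0)
        assert 0.0 <= m.straightness <= 1.0 + 1e-12
        assert m.displacement_um <= m.length_um + 1e-9
        t2 = t.copy()
        t2[["x", "y"]] *= scale
        m2 = track_metrics(t2, 1.0)
        assert m2.length_um == pytest.approx(scale * m.length_um, rel=1e-9)
        assert m2.mean_speed_um_s == pytest.approx(scale * m.mean_speed_um_s, rel=1e-9)
        if m.length_um > 1e-6:
            assert m2.straightness == pytest.approx(m.straightness, rel=1e-6)


def episode(anchor, track_id=1, spot_id=1, min_bd=-0.1):
    return {
        "track_id": track_id,
        "spot_id": spot_id,
        "frame_start": anchor,
        "frame_end": anchor,
        "frame_at_min": anchor,
        "min_border_distance": min_bd,
    }


class TestNearCollisionSpeed:
    def test_constant_speed_track(self, config):
        t = track_from_speeds([0.25] * 10)
        v = near_collision_speed(t, episode(5), config, 1.0)
        assert v == pytest.approx(0.25)

    def test_hand_computed_window(self, config):
        # steps 0.3,0.3,0.1,0.1,0.1,0.3; deceleration starts at the step
        # leaving frame 2 -> window frames [1, 5] holds steps 1..4
        t = track_from_speeds([0.3, 0.3, 0.1, 0.1, 0.1, 0.3])
        v = near_collision_speed(t, episode(2), config, 1.0)
        assert v == pytest.approx((0.3 + 0.1 + 0.1 + 0.1) / 4)

    def test_window_clipped_at_track_end(self, config):
        t = track_from_speeds([0.1, 0.2, 0.4])
        v = near_collision_speed(t, episode(2), config, 1.0)
        assert v == pytest.approx((0.2 + 0.4) / 2)

    def test_no_steps_in_window_is_error(self, config):
        t = track_from_speeds([0.1, 0.1])
        with pytest.raises(InsufficientWindowError):
            near_collision_speed(t, episode(9), config, 1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "near,whole,expected",
        [
            (0.10, 0.20, "decelerated"),
            (0.20, 0.20, "unaffected"),
            (0.21, 0.20, "unaffected"),  # boundary: |Δ|/whole == tol
            (0.30, 0.20, "accelerated"),
        ],
    )
    def test_classes(self, near, whole, expected, config):
        assert classify_collision(near, whole, config) == expected

    def test_zero_whole_speed_rejected(self, config):
        with pytest.raises(DegenerateTrackError):
            classify_collision(0.1, 0.0, config)


class TestStraightnessChange:
    def test_straight_then_right_angle(self):
        t = track_df([(0, 0, 0), (1, 1, 0), (2, 2, 0), (3, 2, 1), (4, 2, 2)])
        before, after, decreased = straightness_change(t, episode(2))
        assert before == 1.0
        assert after == 1.0
        assert decreased is False  # whole track is bent, both halves straight

    def test_zigzag_injected_after_collision(self):
        pts = [(f, 0.25 * f, 0.0) for f in range(6)]
        zig = [(6 + i, 1.25 + 0.1 * (i + 1), 0.25 * ((-1) ** i)) for i in range(6)]
        t = track_df(pts + zig)
        before, after, _ = straightness_change(t, episode(5))
        assert after < before

    def test_collision_at_final_point_flags_after_side(self):
        t = track_from_speeds([0.2, 0.2, 0.2])
        before, after, decreased = straightness_change(t, episode(3))
        assert before == 1.0
        assert after is None
        assert decreased is None


class TestSpotDisplacement:
    def test_static_spot_is_zero(self):
        s = pd.DataFrame({"frame": range(50), "x": 2.0, "y": 3.0})
        assert spot_max_displacement(s) == 0.0

    def test_scripted_step_is_exact(self):
        s = pd.DataFrame(
            {"frame": [0, 1, 2], "x": [0.0, 0.1, 0.05], "y": [0.0, 0.0, 0.0]}
        )
        assert spot_max_displacement(s) == 0.1

    def test_random_walk_matches_scan(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 0.05, size=(40, 2)), axis=0)
        s = pd.DataFrame({"frame": range(40), "x": pos[:, 0], "y": pos[:, 1]})
        expected = max(math.dist(pos[0], p) for p in pos)
        assert spot_max_displacement(s) == pytest.approx(expected)


class TestCellSummary:
    def make_kinetics(self, classes, min_bd=None):
        n = len(classes)
        return pd.DataFrame(
            {
                "track_id": list(range(n)),
                "spot_id": [100 + i for i in range(n)],
                "frame_at_min": [5] * n,
                "min_border_distance": min_bd or [-0.1] * n,
                "whole_track_speed": [0.2] * n,
                "near_speed": [0.1] * n,
                "speed_class": classes,
                "straightness_before": [1.0] * n,
                "straightness_after": [1.0] * n,
                "straightness_decreased": [False] * n,
                "valid": [True] * n,
            }
        )

    def base_tables(self, n_tracks=10, n_spots=10):
        tracks = make_tracks(
            sum(
                (straight_track(track_id=i, start=(0, 3.0 * i)) for i in range(n_tracks)),
                [],
            )
        )
        spots = make_spots(
            [(100 + i, 0, 50.0, 3.0 * i, 0.5) for i in range(n_spots)]
        )
        return tracks, spots

    def test_class_percentages_over_colliding_tracks(self, config):
        tracks, spots = self.base_tables()
        kin = self.make_kinetics(["accelerated"] + ["decelerated"] * 3)
        tm = track_metrics_table(tracks)
        s = summarize_cell(tm, kin, tracks, spots, config)
        assert s.pct_tracks_colliding == 40.0
        assert s.pct_acc == 25.0
        assert s.pct_dec == 75.0
        assert s.pct_unaffected == 0.0
        assert s.pct_acc + s.pct_dec + s.pct_unaffected == pytest.approx(100.0)

    def test_all_unaffected(self, config):
        tracks, spots = self.base_tables()
        kin = self.make_kinetics(["unaffected"] * 5)
        s = summarize_cell(track_metrics_table(tracks), kin, tracks, spots, config)
        assert s.pct_unaffected == 100.0

    def test_no_collisions_flagged(self, config):
        tracks, spots = self.base_tables()
        kin = self.make_kinetics([])
        s = summarize_cell(track_metrics_table(tracks), kin, tracks, spots, config)
        assert s.no_colliding_tracks
        assert s.pct_tracks_colliding == 0.0

    def test_majority_tie_breaks_to_closest_approach(self, config):
        tracks, spots = self.base_tables(n_tracks=2)
        kin = pd.DataFrame(
            {
                "track_id": [0, 0],
                "spot_id": [100, 101],
                "frame_at_min": [2, 6],
                "min_border_distance": [-0.05, -0.2],
                "whole_track_speed": [0.2, 0.2],
                "near_speed": [0.3, 0.1],
                "speed_class": ["accelerated", "decelerated"],
                "straightness_before": [1.0, 1.0],
                "straightness_after": [1.0, 1.0],
                "straightness_decreased": [False, False],
                "valid": [True, True],
            }
        )
        s = summarize_cell(track_metrics_table(tracks), kin, tracks, spots, config)
        # tie between acc and dec -> the closer approach (-0.2) wins
        assert s.pct_dec == 100.0


class TestAnalyzeCell:
    def test_min_length_filter_excludes_short_tracks(self):
        long_pts = straight_track(track_id=1, n=40, step=0.25)  # ~9.75 um
        short_pts = straight_track(track_id=2, n=5, step=0.25, start=(0, 5.0))
        tracks = make_tracks(long_pts + short_pts)
        spots = make_spots([(1, 0, 100.0, 100.0, 0.5)])
        res = analyze_cell(tracks, spots, AnalysisConfig())
        assert list(res.track_metrics["track_id"]) == [1]

    def test_collision_counts_propagate(self, config):
        tracks = make_tracks(straight_track(track_id=1, n=30, step=0.25))
        # spot sitting on the path at frame ~10
        spots = make_spots([(7, f, 2.5, 0.0, 0.4) for f in range(30)])
        res = analyze_cell(tracks, spots, config)
        assert res.track_metrics["n_collisions"].iloc[0] >= 1
        assert res.spot_metrics["n_collisions"].iloc[0] >= 1
        assert res.summary.pct_tracks_colliding == 100.0
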