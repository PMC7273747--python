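import numpy as np
import pytest

from posturokit.behavior_biomarkers import (
    CirclingConfig,
    UndefinedResult,
    abdomen_time,
    circling,
    count_laps,
    lateral_weight_distribution,
    stance_steps,
    step_angle_series,
)

from conftest import make_track, quadruped_tracks

RATE = 30.0


class TestLaterality:
    def test_equal_weights_give_fifty_fifty(self):
        n = 60
        tracks = quadruped_tracks(n, w=100.0)
        mask = np.ones(n, dtype=bool)
        r = lateral_weight_distribution(tracks, mask, "STATIC")
        assert r.left_pct == pytest.approx(50.0)
        assert r.right_pct == pytest.approx(50.0)
        assert r.n_frames == n

    def test_130_70_split_gives_65_35(self):
        n = 30
        tracks = quadruped_tracks(n)
        for tr in tracks:
            tr.w = np.full(n, {"FL": 70.0, "RL": 60.0, "FR": 40.0, "RR": 30.0}[tr.label])
        mask = np.zeros(n, dtype=bool)
        r = lateral_weight_distribution(tracks, mask, "DYNAMIC")
        assert r.left_pct == pytest.approx(65.0)
        assert r.right_pct == pytest.approx(35.0)

    def test_mirror_swaps_sides(self):
        n = 30
        tracks = quadruped_tracks(n)
        for tr in tracks:
            tr.w = np.full(n, {"FL": 80.0, "RL": 50.0, "FR": 40.0, "RR": 30.0}[tr.label])
        mask = np.ones(n, dtype=bool)
        r = lateral_weight_distribution(tracks, mask, "STATIC")
        swap = {"FL": "FR", "FR": "FL", "RL": "RR", "RR": "RL"}
        for tr in tracks:
            tr.label = swap[tr.label]
        m = lateral_weight_distribution(tracks, mask, "STATIC")
        assert m.left_pct == pytest.approx(r.right_pct)
        assert m.right_pct == pytest.approx(r.left_pct)

    def test_percentages_sum_to_100(self):
        n = 30
        tracks = quadruped_tracks(n)
        rng = np.random.default_rng(0)
        for tr in tracks:
            tr.w = rng.uniform(10, 200, n)
        r = lateral_weight_distribution(tracks, np.ones(n, dtype=bool), "STATIC")
        assert r.left_pct + r.right_pct == pytest.approx(100.0)

    def test_no_qualifying_frame_is_undefined(self):
        n = 30
        tracks = quadruped_tracks(n)
        with pytest.raises(UndefinedResult):
            lateral_weight_distribution(tracks, np.ones(n, dtype=bool), "DYNAMIC")


class TestAbdomenTime:
    def test_no_other_zone_gives_zero(self):
        n = 60
        tracks = quadruped_tracks(n)
        r = abdomen_time(tracks, np.ones(n, dtype=bool), RATE)
        assert (r.static_s, r.dynamic_s) == (0.0, 0.0)

    def test_between_paws_static_45_frames(self):
        n = 60
        tracks = quadruped_tracks(n)
        fi = np.arange(45)
        tracks.append(make_track(9, fi, np.tile([12.5, 12.5], (45, 1)), w=np.full(45, 40.0), label="OTHER"))
        r = abdomen_time(tracks, np.ones(n, dtype=bool), RATE)
        assert r.static_s == pytest.approx(1.5)  # 45 / 30
        assert r.dynamic_s == 0.0

    def test_outside_hull_not_counted(self):
        n = 60
        tracks = quadruped_tracks(n)  # hull around (12.5, 12.5)
        fi = np.arange(45)
        tracks.append(make_track(9, fi, np.tile([20.0, 20.0], (45, 1)), w=np.full(45, 40.0), label="OTHER"))
        r = abdomen_time(tracks, np.ones(n, dtype=bool), RATE)
        assert (r.static_s, r.dynamic_s) == (0.0, 0.0)

    def test_frames_without_four_paws_skipped(self):
        n = 60
        tracks = quadruped_tracks(n)[:3]  # only 3 paws
        fi = np.arange(n)
        tracks.append(make_track(9, fi, np.tile([12.5, 12.5], (n, 1)), label="OTHER"))
        r = abdomen_time(tracks, np.ones(n, dtype=bool), RATE)
        assert (r.static_s, r.dynamic_s) == (0.0, 0.0)

    def test_split_by_state(self):
        n = 60
        tracks = quadruped_tracks(n)
        fi = np.arange(n)
        tracks.append(make_track(9, fi, np.tile([12.5, 12.5], (n, 1)), label="OTHER"))
        mask = np.zeros(n, dtype=bool)
        mask[:20] = True
        r = abdomen_time(tracks, mask, RATE)
        assert r.static_s == pytest.approx(20 / 30)
        assert r.dynamic_s == pytest.approx(40 / 30)


def steps_at_angles(angles_deg, radius=3.0, stance_s=0.25, origin=(0.0, 0.0)):
    """Step list at given polar angles about origin, fixed stance duration."""
    out = []
    for k, a in enumerate(angles_deg):
        x = origin[0] + radius * np.cos(np.radians(a))
        y = origin[1] + radius * np.sin(np.radians(a))
        out.append((k * 0.35, stance_s, x, y))
    return out


class TestStepAngles:
    CFG = CirclingConfig()

    def test_quarter_turns(self):
        runs = step_angle_series(steps_at_angles([0, 90, 180, 270, 360]), self.CFG, (0, 0))
        assert len(runs) == 1
        assert runs[0] == pytest.approx([90, 90, 90, 90])

    def test_wrap_convention(self):
        runs = step_angle_series(steps_at_angles([-179, 179]), self.CFG, (0, 0))
        assert runs[0] == pytest.approx([-2.0])

    def test_long_stance_breaks_series(self):
        steps = steps_at_angles([0, 90, 180, 270, 360])
        steps[2] = (steps[2][0], 0.6, steps[2][2], steps[2][3])  # 600 ms stance
        runs = step_angle_series(steps, self.CFG, (0, 0))
        assert [len(r) for r in runs] == [1, 1]  # 0->90 and 270->360

    def test_fewer_than_two_steps_empty(self):
        assert step_angle_series(steps_at_angles([0]), self.CFG, (0, 0)) == []


class TestLapCounting:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            ([[90.0] * 4], (1, 0)),
            ([[-90.0] * 8], (0, 2)),  # carry-over: -720 deg = 2 right laps
            ([[90.0, -90.0] * 6], (0, 0)),  # cancellation
            ([[90.0] * 3], (0, 0)),  # 270 deg: not a full lap
            ([[90.0] * 3, [90.0] * 3], (0, 0)),  # reset at breaks
            ([[45.0] * 16], (2, 0)),
        ],
    )
    def test_counting(self, theta, expected):
        assert count_laps([np.array(r) for r in theta]) == expected


def circling_paw_track(zone_id, label, n_laps, direction, radius, n_steps=8, stance_frames=7, gap=3, phase_deg=0.0):
    """Track stepping around the plate centre (12.5, 12.5)."""
    sign = 1 if direction == "left" else -1
    fi, xs, ys = [], [], []
    f = 0
    for k in range(n_steps * n_laps + 1):
        a = np.radians(phase_deg + sign * 360.0 * k / n_steps)
        for _ in range(stance_frames):
            fi.append(f)
            xs.append(12.5 + radius * np.cos(a))
            ys.append(12.5 + radius * np.sin(a))
            f += 1
        f += gap
    return make_track(zone_id, fi, np.column_stack([xs, ys]), label=label)


class TestCircling:
    @pytest.mark.parametrize("k", [1, 2, 5])
    @pytest.mark.parametrize("direction", ["left", "right"])
    def test_k_fast_laps_counted_exactly(self, k, direction):
        tracks = [
            circling_paw_track(0, "FL", k, direction, radius=3.2),
            circling_paw_track(1, "FR", k, direction, radius=5.6, phase_deg=40.0),
        ]
        r = circling(tracks, RATE, (12.5, 12.5))
        laps = (r.left_laps, r.right_laps)
        assert laps == ((k, 0) if direction == "left" else (0, k))

    def test_slow_stances_rejected(self):
        # same circular path, 800 ms supports: thigmotaxis, not circling
        tracks = [
            circling_paw_track(0, "FL", 3, "left", 3.2, stance_frames=24),
            circling_paw_track(1, "FR", 3, "left", 5.6, stance_frames=24),
        ]
        r = circling(tracks, RATE, (12.5, 12.5))
        assert (r.left_laps, r.right_laps) == (0.0, 0.0)

    def test_mean_over_front_paws_half_integral(self):
        tracks = [
            circling_paw_track(0, "FL", 3, "left", 3.2),
            circling_paw_track(1, "FR", 2, "left", 5.6),
        ]
        r = circling(tracks, RATE, (12.5, 12.5))
        assert r.left_laps == pytest.approx(2.5)

    def test_missing_front_paw_contributes_zero(self):
        tracks = [circling_paw_track(0, "FL", 2, "left", 3.2)]
        r = circling(tracks, RATE, (12.5, 12.5))
        assert r.left_laps == pytest.approx(1.0)  # mean(2, 0)

    def test_steps_pooled_across_tracks(self):
        # each stance its own track, as the tracker produces for 3 cm steps
        tracks = []
        for k in range(17):  # 2 laps of 8 steps + 1
            a = np.radians(360.0 * k / 8)
            xy = np.tile([12.5 + 3.2 * np.cos(a), 12.5 + 3.2 * np.sin(a)], (7, 1))
            tracks.append(make_track(k, np.arange(k * 10, k * 10 + 7), xy, label="FL"))
        steps = stance_steps(tracks, "FL", RATE)
        assert len(steps) == 17
        r = circling(tracks, RATE, (12.5, 12.5))
        assert r.left_laps == pytest.approx(1.0)  # mean(2, 0) with FR absent
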