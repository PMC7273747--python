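from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from posturokit.behavior_biomarkers import UndefinedResult
from posturokit.mobility_segmentation import StaticQuadrupedEpisode
from posturokit.posturography import (
    CHI2_90_2DF,
    BarycenterTrace,
    barycenter,
    barycenter_speed,
    compute_traces,
    export_statokinesiogram,
    max_support_surface,
    session_posturography,
    support_surface,
    sway_ellipse,
)

from conftest import make_track, quadruped_tracks

RATE = 30.0


class TestBarycenter:
    def test_equal_weights_rectangle_center(self):
        pos = [(0, 0), (2, 0), (0, 3), (2, 3)]
        assert barycenter(pos, [10, 10, 10, 10]) == pytest.approx((1.0, 1.5))

    def test_worked_asymmetric_stance(self):
        pos = [(0, 1), (2, 1), (0, -1), (2, -1)]  # FL, FR, RL, RR
        w = [100, 100, 50, 50]
        bx, by = barycenter(pos, w)
        assert bx == pytest.approx(1.0)
        assert by == pytest.approx(1.0 / 3.0)

    def test_single_loaded_paw(self):
        pos = [(0, 1), (2, 1), (0, -1), (2, -1)]
        assert barycenter(pos, [0, 42, 0, 0]) == pytest.approx((2.0, 1.0))

    def test_zero_weight_undefined(self):
        with pytest.raises(UndefinedResult):
            barycenter([(0, 0), (1, 0), (0, 1), (1, 1)], [0, 0, 0, 0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_barycenter_inside_paw_hull(self, seed):
        from shapely.geometry import MultiPoint, Point

        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 25, size=(4, 2))
        w = rng.uniform(0.1, 200, size=4)
        b = barycenter(pos, w)
        hull = MultiPoint([tuple(p) for p in pos]).convex_hull
        assert hull.distance(Point(b)) < 1e-9


def hull_area_bruteforce(pts):
    """Independent oracle: max |shoelace|/2 over all orderings of the four
    points and all triangles."""

    def shoelace(q):
        x, y = q[:, 0], q[:, 1]
        return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2

    best = 0.0
    for perm in permutations(range(4)):
        best = max(best, shoelace(pts[list(perm)]))
    for tri in combinations(range(4), 3):
        best = max(best, shoelace(pts[list(tri)]))
    return best


class TestSupportSurface:
    @pytest.mark.parametrize(
        "pts, area",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0),
            ([(0, 0), (4, 0), (4, 3), (0, 3)], 12.0),
            ([(0, 0), (2, 0), (1, 2), (1, 0.5)], 2.0),  # interior point dropped
            ([(0, 0), (1, 1), (2, 2), (3, 3)], 0.0),  # collinear
        ],
    )
    def test_examples(self, pts, area):
        assert support_surface(pts) == pytest.approx(area)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            pts = rng.uniform(0, 25, size=(4, 2))
            assert abs(support_surface(pts) - hull_area_bruteforce(pts)) < 1e-9

    def test_max_over_frames(self):
        n = 20
        tracks = quadruped_tracks(n, half_len=3.0, half_wid=1.8)
        # widen the stance for the last 5 frames
        for tr in tracks:
            sign = 1 if tr.label in ("FR", "RR") else -1
            tr.x[-5:] += sign * 1.0
        eps = [StaticQuadrupedEpisode(0, n, 0.0, n / RATE)]
        got = max_support_surface(tracks, eps, n)
        assert got == pytest.approx((3.6 + 2.0) * 6.0)


class TestSwayEllipse:
    def test_identical_points_degenerate(self):
        pts = np.tile([1.0, 2.0], (50, 1))
        with pytest.warns(UserWarning):
            r = sway_ellipse(pts)
        assert r.ellipse_area_cm2 == 0.0

    def test_isotropic_gaussian_matches_closed_form(self):
        rng = np.random.default_rng(0)
        sigma = 0.1
        pts = rng.normal(0, sigma, size=(100_000, 2))
        r = sway_ellipse(pts)
        expected = np.pi * CHI2_90_2DF * sigma**2
        assert abs(r.ellipse_area_cm2 - expected) / expected < 0.05
        assert r.retained_fraction == pytest.approx(0.9, abs=1e-3)

    def test_untrimmed_ellipse_also_matches(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 0.1, size=(100_000, 2))
        r = sway_ellipse(pts, trim=0.0)
        expected = np.pi * CHI2_90_2DF * 0.01
        assert abs(r.ellipse_area_cm2 - expected) / expected < 0.05

    @pytest.mark.parametrize("ratio", [1.0, 3.0, 10.0])
    def test_anisotropic_gaussian(self, ratio):
        rng = np.random.default_rng(int(ratio))
        sx, sy = 0.1, 0.1 * ratio
        pts = rng.normal(0, [sx, sy], size=(100_000, 2))
        r = sway_ellipse(pts)
        expected = np.pi * CHI2_90_2DF * sx * sy
        assert abs(r.ellipse_area_cm2 - expected) / expected < 0.05

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 0.1, size=(100_000, 2))
        r = sway_ellipse(pts)
        fresh = rng.normal(0, 0.1, size=(100_000, 2))
        d = fresh - np.array(r.center)
        a, b = r.semi_axes
        phi = np.radians(r.orientation_deg)
        u = d @ np.array([np.cos(phi), np.sin(phi)])
        v = d @ np.array([-np.sin(phi), np.cos(phi)])
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        assert abs(inside.mean() - 0.90) <= 0.02

    def test_robust_to_outliers(self):
        # the 10% trim absorbs a 5% cloud of far outliers
        rng = np.random.default_rng(3)
        pts = np.vstack([
            rng.normal(0, 0.1, size=(9_500, 2)),
            rng.normal(0, 5.0, size=(500, 2)),
        ])
        r = sway_ellipse(pts)
        expected = np.pi * CHI2_90_2DF * 0.01
        assert r.ellipse_area_cm2 < 3 * expected

    def test_too_few_samples(self):
        with pytest.raises(UndefinedResult):
            sway_ellipse(np.zeros((5, 2)))


def trace_from_xy(xy, rate=RATE, start=0):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    ep = StaticQuadrupedEpisode(start, start + n, start / rate, (start + n) / rate)
    return BarycenterTrace(episode=ep, t=start / rate + np.arange(n) / rate, xy=xy)


class TestBarycenterSpeed:
    def test_stationary_zero(self):
        assert barycenter_speed(trace_from_xy(np.tile([1, 1], (10, 1)))) == 0.0

    def test_straight_path(self):
        # 3 cm in 1.5 s (46 samples at 30 Hz)
        xy = np.column_stack([np.linspace(0, 3, 46), np.zeros(46)])
        assert barycenter_speed(trace_from_xy(xy)) == pytest.approx(2.0)

    def test_closed_loop_uses_path_not_displacement(self):
        # square loop, perimeter 4 cm, in 2 s (61 samples)
        steps = np.concatenate([
            np.tile([1 / 15, 0], (15, 1)), np.tile([0, 1 / 15], (15, 1)),
            np.tile([-1 / 15, 0], (15, 1)), np.tile([0, -1 / 15], (15, 1)),
        ])
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        assert barycenter_speed(trace_from_xy(xy)) == pytest.approx(2.0)


def session_with_sway(n=120, amp=0.3, freq=2.0, seed=0):
    """Quadruped stance whose loads oscillate, moving the barycenter."""
    tracks = quadruped_tracks(n)
    t = np.arange(n) / RATE
    f = 0.5 + amp * np.sin(2 * np.pi * freq * t) / 2
    rng = np.random.default_rng(seed)
    for tr in tracks:
        side = f if tr.label in ("FL", "RL") else 1 - f
        tr.w = 200.0 * side + rng.normal(0, 0.5, n)
    eps = [StaticQuadrupedEpisode(0, n, 0.0, n / RATE)]
    return tracks, eps


class TestSessionAggregation:
    def test_single_episode_equals_episode_values(self):
        tracks, eps = session_with_sway()
        res = session_posturography(tracks, eps, 120, RATE)
        row = res.per_episode[0]
        assert res.sway_area_cm2 == pytest.approx(row["sway_area_cm2"])
        assert res.mean_speed_cm_s == pytest.approx(row["speed_cm_s"])
        assert res.sfa == pytest.approx(row["speed_cm_s"] / row["sway_area_cm2"])

    def test_duration_weighted_mean(self):
        # duration-weighted combination of per-episode sway areas
        tracks, _ = session_with_sway(n=120)
        eps = [
            StaticQuadrupedEpisode(0, 30, 0.0, 1.0),
            StaticQuadrupedEpisode(30, 120, 1.0, 4.0),
        ]
        res = session_posturography(tracks, eps, 120, RATE)
        a = [r["sway_area_cm2"] for r in res.per_episode]
        d = [r["duration_s"] for r in res.per_episode]
        assert res.sway_area_cm2 == pytest.approx(np.average(a, weights=d))

    def test_translation_invariance(self):
        tracks, eps = session_with_sway()
        res = session_posturography(tracks, eps, 120, RATE)
        for tr in tracks:
            tr.x = tr.x + 3.0
            tr.y = tr.y - 2.0
        res2 = session_posturography(tracks, eps, 120, RATE)
        assert res2.sway_area_cm2 == pytest.approx(res.sway_area_cm2)
        assert res2.mean_speed_cm_s == pytest.approx(res.mean_speed_cm_s)
        assert res2.max_support_surface_cm2 == pytest.approx(res.max_support_surface_cm2)

    def test_scaling_dimensional_analysis(self):
        tracks, eps = session_with_sway()
        res = session_posturography(tracks, eps, 120, RATE)
        s = 2.0
        for tr in tracks:
            tr.x = tr.x * s
            tr.y = tr.y * s
        res2 = session_posturography(tracks, eps, 120, RATE)
        assert res2.sway_area_cm2 == pytest.approx(res.sway_area_cm2 * s**2)
        assert res2.mean_speed_cm_s == pytest.approx(res.mean_speed_cm_s * s)
        assert res2.sfa == pytest.approx(res.sfa / s)

    def test_no_episode_undefined(self):
        with pytest.raises(UndefinedResult):
            session_posturography([], [], 0, RATE)


class TestTraces:
    def test_barycenter_trace_inside_hull(self):
        tracks, eps = session_with_sway()
        (trace,) = compute_traces(tracks, eps, 120, RATE)
        assert trace.n_samples == 120
        assert np.all(trace.xy[:, 0] > 12.5 - 1.8) and np.all(trace.xy[:, 0] < 12.5 + 1.8)


class TestStatokinesiogramExport:
    def test_csv_row_count_and_figure(self, tmp_path):
        tracks, eps = session_with_sway(n=60)
        csv_path = export_statokinesiogram(
            tracks, eps, 60, RATE, tmp_path / "stato.csv", tmp_path / "stato.png"
        )
        lines = csv_path.read_text().strip().splitlines()
        assert len(lines) == 1 + 60 * 5  # header + 5 zones per frame
        assert (tmp_path / "stato.png").exists()

    def test_empty_episode_list_errors(self, tmp_path):
        with pytest.raises(UndefinedResult):
            export_statokinesiogram([], [], 0, RATE, tmp_path / "s.csv")
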