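import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flatbrain import curves
from flatbrain.errors import (
    DegenerateParameterizationError,
    InvalidInputError,
)

from _oracles import dense_walk_oracle, random_smooth_curve


class TestSegmentFit:
    def test_collinear_points_trace_the_line(self):
        seg = curves.fit_bezier_segment([(0, 0), (1, 1), (2, 2)])
        assert seg.order == 2
        t = np.linspace(0, 1, 101)
        p = seg(t)
        assert np.abs(p[:, 1] - p[:, 0]).max() < 1e-9

    def test_two_points_give_exact_line_segment(self):
        seg = curves.fit_bezier_segment([(0, 0), (10, 0)])
        assert seg.order == 1
        np.testing.assert_array_equal(seg.control, [[0, 0], [10, 0]])

    def test_refit_of_sampled_cubic_interpolates(self):
        # expected values computed by evaluating the original cubic at the
        # chord-length parameters, then refitting through the samples
        orig = curves.BezierSegment(np.array([(0, 0), (1, 2), (3, 2), (4, 0)], float))
        samples = orig(np.array([0.0, 0.3, 0.7, 1.0]))
        refit = curves.fit_bezier_segment(samples)
        t = curves.chord_length_parameters(samples)
        assert np.abs(refit(t) - samples).max() < 1e-9

    def test_interpolation_of_random_groups(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 7))
            pts = rng.uniform(-50, 50, (m, 2))
            while np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
                pts = rng.uniform(-50, 50, (m, 2))
            seg = curves.fit_bezier_segment(pts)
            t = curves.chord_length_parameters(pts)
            assert np.abs(seg(t) - pts).max() < 1e-9

    @pytest.mark.parametrize("bad", [[(0, 0)], []])
    def test_too_few_points_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            curves.fit_bezier_segment(bad)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateParameterizationError):
            curves.fit_bezier_segment([(0, 0), (0, 0), (1, 1)])


class TestPiecewise:
    def test_collinear_groups_stay_on_line(self):
        pts = np.column_stack([np.linspace(0, 10, 7), np.zeros(7)])
        seq = curves.PointSequence.from_points(pts, max_group=4)
        pc = curves.fit_piecewise(seq)
        u = np.linspace(0, pc.n_segments, 500)
        assert np.abs(pc.point(u)[:, 1]).max() < 1e-9

    def test_single_group_matches_plain_fit(self):
        pts = np.array([(0, 0), (1, 2), (3, 1), (5, 3)], float)
        seq = curves.PointSequence.from_points(pts, max_group=4)
        pc = curves.fit_piecewise(seq)
        seg = curves.fit_bezier_segment(pts)
        np.testing.assert_allclose(pc.segments[0].control, seg.control)

    def test_kinked_join_smoothed_to_common_tangent(self):
        # two quadratics meeting at (2, 0) with a ~20 degree kink
        a = np.array([(0, 0), (1, 0.3), (2, 0)], float)
        b = np.array([(2, 0), (3, -0.6), (4, -0.2)], float)
        seq = curves.PointSequence(np.vstack([a, b[1:]]), [0, 2, 4])
        pc = curves.fit_piecewise(seq)
        tl = pc.segments[0].derivative([1.0])[0]
        tr = pc.segments[1].derivative([0.0])[0]
        ang = np.arccos(np.clip(tl @ tr / np.linalg.norm(tl) / np.linalg.norm(tr), -1, 1))
        assert ang < 1e-6
        # positional continuity preserved exactly
        gap = np.linalg.norm(pc.segments[0](np.array([1.0])) - pc.segments[1](np.array([0.0])))
        assert gap < 1e-12

    def test_smoothing_is_idempotent(self, rng):
        for _ in range(20):
            pc = random_smooth_curve(rng)
            once = [s.control for s in pc.segments]
            twice = curves._smooth_joins(pc.segments)
            for c1, c2 in zip(once, (s.control for s in twice)):
                np.testing.assert_allclose(c1, c2, atol=1e-12)


class TestArcPositions:
    def test_straight_line_uniform(self):
        pc = curves.PiecewiseCurve([curves.fit_bezier_segment([(0, 0), (10, 0)])])
        pts = curves.arc_positions(pc, 5)
        np.testing.assert_allclose(pts[:, 0], [0, 2, 4, 6, 8, 10], atol=1e-9)
        np.testing.assert_allclose(pts[:, 1], 0, atol=1e-12)

    def test_n_equals_one_returns_endpoints(self, rng):
        pc = random_smooth_curve(rng)
        pts = curves.arc_positions(pc, 1)
        np.testing.assert_allclose(pts[0], pc.start, atol=1e-9)
        assert np.linalg.norm(pts[1] - pc.end) < 1e-3 * np.linalg.norm(pts[1] - pts[0])

    def test_quarter_circle_matches_dense_oracle(self):
        th = np.linspace(0, np.pi / 2, 7)
        seq = curves.PointSequence.from_points(
            np.column_stack([np.cos(th), np.sin(th)]), max_group=4)
        pc = curves.fit_piecewise(seq)
        pts, _, s = curves.equally_spaced(pc, 4)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert gaps.std() / gaps.mean() < 1e-3
        oracle = dense_walk_oracle(pc, s, 4)
        assert np.linalg.norm(pts - oracle, axis=1).max() < 1e-3 * s

    @pytest.mark.parametrize("N", [2, 37, 150])
    def test_spacing_cv_on_random_curves(self, rng, N):
        for _ in range(5):
            pc = random_smooth_curve(rng)
            pts, _, s = curves.equally_spaced(pc, N)
            assert pts.shape == (N + 1, 2)
            gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert gaps.std() / gaps.mean() < 1e-3
            assert np.linalg.norm(pts[-1] - pc.end) < s * 1e-3

    def test_invalid_n_rejected(self, rng):
        pc = random_smooth_curve(rng)
        with pytest.raises(InvalidInputError):
            curves.arc_positions(pc, 0)


class TestNormals:
    def test_horizontal_line_tissue_below(self):
        pc = curves.PiecewiseCurve([curves.fit_bezier_segment([(0, 0), (10, 0)])])
        n = curves.unit_normals(pc, np.linspace(0, 1, 6), tissue_side=1)
        np.testing.assert_allclose(n, np.tile([0.0, 1.0], (6, 1)), atol=1e-12)

    def test_ccw_circle_normals_point_inward(self):
        # counter-clockwise in y-up terms; tissue inside the arc
        th = np.linspace(0, np.pi / 2, 7)
        seq = curves.PointSequence.from_points(
            np.column_stack([np.cos(th), np.sin(th)]), max_group=4)
        pc = curves.fit_piecewise(seq)
        u = np.linspace(0, pc.n_segments, 50)
        p = pc.point(u)
        n = curves.unit_normals(pc, u, tissue_side=1)
        assert np.all(np.sum(n * (0 - p), axis=1) > 0)

    def test_flag_negates_normals(self, rng):
        pc = random_smooth_curve(rng)
        u = np.linspace(0, pc.n_segments, 20)
        np.testing.assert_array_equal(
            curves.unit_normals(pc, u, 1), -curves.unit_normals(pc, u, -1))


class TestSampleBoxes:
    def test_straight_curve_gives_axis_aligned_squares(self):
        pc = curves.PiecewiseCurve([curves.fit_bezier_segment([(0, 0), (10, 0)])])
        fr = curves.sample_frames(pc, 5, tissue_side=1)
        boxes = curves.make_sample_boxes(fr, 0.0, 2.0, 1.0)
        assert boxes.shape == (5, 4, 2)
        np.testing.assert_allclose(
            boxes[0], [[0, 0], [0, 2], [2, 2], [2, 0]], atol=1e-9)

    def test_zero_depth_window_rejected(self):
        pc = curves.PiecewiseCurve([curves.fit_bezier_segment([(0, 0), (10, 0)])])
        fr = curves.sample_frames(pc, 5)
        with pytest.raises(InvalidInputError):
            curves.make_sample_boxes(fr, 2.0, 2.0, 1.0)

    def test_curved_boxes_cover_annular_band_area(self):
        # quarter circle of radius 50 px; boxes over depths [0, 10] px should
        # tile the annulus between radii 40 and 50 (shoelace vs analytic)
        th = np.linspace(0, np.pi / 2, 13)
        seq = curves.PointSequence.from_points(
            50 * np.column_stack([np.cos(th), np.sin(th)]), max_group=4)
        pc = curves.fit_piecewise(seq)
        fr = curves.sample_frames(pc, 60, tissue_side=1)
        boxes = curves.make_sample_boxes(fr, 0.0, 10.0, 1.0)
        x, y = boxes[..., 0], boxes[..., 1]
        areas = 0.5 * np.abs(np.sum(
            x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1))
        annulus = 0.25 * np.pi * (50.0**2 - 40.0**2)
        assert abs(areas.sum() - annulus) / annulus < 0.02


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=2, max_value=500), st.integers(min_value=0, max_value=10_000))
def test_spacing_property_exact_count_and_cv(N, seed):
    """For any fitted curve and N, N+1 points come back with gap CV < 1e-3."""
    rng = np.random.default_rng(seed)
    pc = random_smooth_curve(rng)
    pts, _, s = curves.equally_spaced(pc, N)
    assert pts.shape == (N + 1, 2)
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    assert gaps.std() / gaps.mean() < 1e-3
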