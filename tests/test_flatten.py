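import numpy as np
import pytest

from flatbrain import flatten, phantom as ph, pipeline
from flatbrain.errors import InvalidInputError


def _straight_surface(M=3, N=4, spacing_um=100.0):
    """Flat, coplanar ribbons: straight lines along y in each slice plane."""
    curves = [np.column_stack([np.linspace(0, 400, N + 1), np.full(N + 1, 50.0)])
              for _ in range(M)]
    values = np.arange(M * N, dtype=float).reshape(M, N)
    x = np.arange(M) * spacing_um
    return flatten.build_surface(curves, values, (np.array([200.0, 50.0]),) * 2,
                                 x, pixel_size_um=1.0)


class TestBuildSurface:
    def test_two_slice_planar_mesh(self):
        s = _straight_surface(M=2, N=4)
        assert s.points.shape == (2, 5, 3)
        assert s.values.shape == (2, 4)
        # all ribbon points coplanar in z
        assert np.ptp(s.points[..., 2]) == 0.0

    def test_slice_planes_at_index_times_thickness(self):
        s = _straight_surface(M=4, N=3, spacing_um=100.0)
        np.testing.assert_array_equal(s.points[:, :, 0],
                                      np.repeat([[0], [100], [200], [300]], 4, axis=1))

    def test_missing_axis_mark_rejected(self):
        curves = [np.zeros((5, 2)), np.zeros((5, 2))]
        with pytest.raises(InvalidInputError):
            flatten.build_surface(curves, np.zeros((2, 4)), (None, np.zeros(2)),
                                  np.array([0.0, 100.0]), 1.0)


class TestZeroMarks:
    def _semicircle_surface(self, radii=None):
        th = np.linspace(0, np.pi, 9)
        r = np.ones(9) if radii is None else np.asarray(radii)
        curve = np.column_stack([100 + 50 * r * np.cos(th), 100 - 50 * r * np.sin(th)])
        curves = [curve, curve]
        values = np.zeros((2, 8))
        return flatten.build_surface(curves, values, (np.array([100.0, 100.0]),) * 2,
                                     np.array([0.0, 100.0]), 1.0)

    def test_apex_found_at_phi_half_pi(self):
        s = self._semicircle_surface()
        idx = flatten.find_zero_marks(s, np.pi / 2)
        np.testing.assert_array_equal(idx, [4, 4])  # middle sample = apex

    def test_tie_breaks_toward_more_distal_sample(self):
        # samples at angles 0.4 and 0.6 are equidistant from phi = 0.5;
        # the one at 0.6 is more distal and must win the tie
        th = np.array([0.1, 0.4, 0.6, 0.9])
        r = 50 * np.array([1.0, 1.0, 1.5, 1.0])
        curve = np.column_stack([100 + r * np.cos(th), 100 - r * np.sin(th)])
        s = flatten.build_surface([curve, curve], np.zeros((2, 3)),
                                  (np.array([100.0, 100.0]),) * 2,
                                  np.array([0.0, 100.0]), 1.0)
        idx = flatten.find_zero_marks(s, 0.5)
        np.testing.assert_array_equal(idx, [2, 2])

    def test_angle_outside_surface_rejected(self):
        # quarter arc spans [0, pi/2]; phi = -3pi/4 is > pi/2 from every sample
        th = np.linspace(0, np.pi / 2, 9)
        curve = np.column_stack([100 + 50 * np.cos(th), 100 - 50 * np.sin(th)])
        s = flatten.build_surface([curve, curve], np.zeros((2, 8)),
                                  (np.array([100.0, 100.0]),) * 2,
                                  np.array([0.0, 100.0]), 1.0)
        with pytest.raises(InvalidInputError):
            flatten.find_zero_marks(s, -3 * np.pi / 4)

    def test_phantom_apex_matches_analytic_angle(self, clean_recon, clean_phantom):
        surf = clean_recon.surfaces["L4"]
        idx = flatten.find_zero_marks(surf, np.pi / 2)
        # cylinder sampled uniformly in angle: apex is the middle bin edge
        N = clean_phantom.truth.spec.n_bins
        assert np.all(np.abs(idx - N // 2) <= 1)


class TestUnwrap:
    def test_flat_surface_unwraps_to_itself(self):
        s = _straight_surface(M=3, N=4)
        fm = flatten.unwrap(s, np.zeros(3, dtype=int))
        # u spacing equals the in-plane spacing (100 px * 1 µm -> 0.1 mm)
        np.testing.assert_allclose(np.diff(fm.u_edges, axis=1), 0.1, atol=1e-12)
        np.testing.assert_allclose(fm.v, [0.0, 0.1, 0.2], atol=1e-12)
        # quads congruent with the input geometry
        assert fm.quads.shape == (8, 4, 2)
        np.testing.assert_allclose(
            fm.quads[0], [[0, 0], [0.1, 0], [0.1, 0.1], [0, 0.1]], atol=1e-9)

    def test_arc_length_conserved_per_ribbon(self, clean_flatmap, clean_recon):
        surf = clean_recon.surfaces["L4"]
        for i in range(surf.n_slices):
            length_3d = np.sum(np.linalg.norm(np.diff(surf.points[i], axis=0), axis=1))
            length_2d = np.sum(np.abs(np.diff(clean_flatmap.u_edges[i]))) * 1000.0
            assert abs(length_2d - length_3d) / length_3d < 1e-9

    def test_zero_mark_pinned_at_u_zero(self, clean_recon):
        surf = clean_recon.surfaces["L4"]
        zeros = flatten.find_zero_marks(surf, np.pi / 2)
        fm = flatten.unwrap(surf, zeros)
        for i, j in enumerate(zeros):
            assert fm.u_edges[i, j] == 0.0

    def test_half_cylinder_width_is_pi_r(self, clean_flatmap, clean_phantom):
        r = clean_phantom.truth.spec.radius_mm
        widths = clean_flatmap.u_edges[:, -1] - clean_flatmap.u_edges[:, 0]
        assert np.abs(widths - np.pi * r).max() / (np.pi * r) < 0.005

    def test_painted_stripe_lands_at_analytic_u(self, clean_flatmap, clean_phantom):
        truth = clean_phantom.truth
        stripe = truth.spec.pattern[0]
        u_true = truth.stripe_u_mm(stripe)
        r = truth.spec.radius_mm
        bin_w = np.pi * r / truth.spec.n_bins
        cen = clean_flatmap.quads.mean(axis=1)
        w = np.nan_to_num(clean_flatmap.values)
        w[np.abs(cen[:, 0] - u_true) > 4 * stripe.width_mm] = 0.0  # isolate stripe
        u_est = np.sum(cen[:, 0] * w) / np.sum(w)
        assert abs(u_est - u_true) < bin_w

    def test_flatmap_round_trip(self, tmp_path, clean_flatmap):
        path = tmp_path / "fm.h5"
        flatten.save_flatmap(clean_flatmap, path)
        fm = flatten.load_flatmap(path)
        np.testing.assert_array_equal(fm.quads, clean_flatmap.quads)
        np.testing.assert_array_equal(fm.values, clean_flatmap.values)
        np.testing.assert_array_equal(fm.outline, clean_flatmap.outline)
        assert set(fm.landmarks) == set(clean_flatmap.landmarks)


def test_display_smoothing_leaves_input_untouched():
    pts = np.random.default_rng(0).random((4, 6, 3))
    before = pts.copy()
    out = flatten.smooth_mesh_for_display(pts)
    np.testing.assert_array_equal(pts, before)
    assert out.shape == pts.shape
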