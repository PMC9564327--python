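import numpy as np
import pytest

from flatbrain import mapmath
from flatbrain.errors import DegenerateGeometryError, InvalidInputError
from flatbrain.flatten import FlatMap


def _regular_flatmap(nx=12, ny=8, d=0.1, values=None):
    """A flat map of regular d x d quads on an nx x ny lattice."""
    quads, vals, si, bi = [], [], [], []
    for i in range(ny):
        for k in range(nx):
            u0, v0 = k * d, i * d
            quads.append([(u0, v0), (u0 + d, v0), (u0 + d, v0 + d), (u0, v0 + d)])
            vals.append(1.0 if values is None else values[i, k])
            si.append(i)
            bi.append(k)
    u_edges = np.tile(np.arange(nx + 1) * d, (ny + 1, 1))
    outline = np.array([(0, 0), (nx * d, 0), (nx * d, ny * d), (0, ny * d)])
    return FlatMap(np.array(quads), np.array(vals), np.array(si), np.array(bi),
                   outline, u_edges, np.arange(ny + 1) * d)


class TestAffine:
    def test_identity_from_equal_triplets(self):
        tri = np.array([(0, 0), (1, 0), (0, 1)], float)
        T = mapmath.affine_from_triplets(tri, tri)
        np.testing.assert_allclose(T.A, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(T.b, 0, atol=1e-12)

    def test_pure_scaling(self):
        tri = np.array([(0, 0), (1, 0), (0, 1)], float)
        T = mapmath.affine_from_triplets(tri, 2 * tri)
        np.testing.assert_allclose(T.A, 2 * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(T.b, 0, atol=1e-12)

    def test_random_triplets_reproduced_exactly(self, rng):
        for _ in range(300):
            src = rng.uniform(-10, 10, (3, 2))
            dst = rng.uniform(-10, 10, (3, 2))
            try:
                T = mapmath.affine_from_triplets(src, dst)
            except DegenerateGeometryError:
                continue
            assert np.abs(T.apply(src) - dst).max() < 1e-9

    def test_collinear_triplet_rejected(self):
        bad = np.array([(0, 0), (1, 1), (2, 2)], float)
        good = np.array([(0, 0), (1, 0), (0, 1)], float)
        with pytest.raises(DegenerateGeometryError):
            mapmath.affine_from_triplets(bad, good)

    def test_apply_identity_bit_identical(self):
        fm = _regular_flatmap()
        out = mapmath.apply_affine(fm, mapmath.AffineTransform2D.identity())
        np.testing.assert_array_equal(out.quads, fm.quads)

    def test_apply_translation_shifts_all_corners(self):
        fm = _regular_flatmap()
        T = mapmath.AffineTransform2D(np.eye(2), np.array([0.3, -0.2]))
        out = mapmath.apply_affine(fm, T)
        np.testing.assert_allclose(out.quads - fm.quads,
                                   np.broadcast_to([0.3, -0.2], fm.quads.shape))

    def test_forward_then_inverse_round_trip(self, rng):
        fm = _regular_flatmap()
        T = mapmath.AffineTransform2D(rng.uniform(-2, 2, (2, 2)) + 3 * np.eye(2),
                                      rng.uniform(-1, 1, 2))
        back = mapmath.apply_affine(mapmath.apply_affine(fm, T), T.inverse())
        assert np.abs(back.quads - fm.quads).max() < 1e-9


class TestRegrid:
    def test_constant_map_regrids_to_constant(self):
        fm = _regular_flatmap()
        g = mapmath.regrid(fm, 0.05)
        assert g.mask.any()
        assert np.nanmax(np.abs(g.values[g.mask] - 1.0)) < 1e-6

    def test_single_data_pixel_has_finite_centered_support(self):
        fm = _regular_flatmap(nx=1, ny=1, d=0.2)
        g = mapmath.regrid(fm, 0.02)
        assert g.mask.any() and not g.mask.all()  # finite masked support
        # a single quad normalizes to its own value everywhere on the support,
        # and the kernel (hence the mask) is centered on the quad centroid
        assert np.nanmax(np.abs(g.values[g.mask] - 1.0)) < 1e-9
        xs, ys = g.centers()
        ii, jj = np.nonzero(g.mask)
        assert abs(xs[jj].mean() - 0.1) <= 0.02 + 1e-12
        assert abs(ys[ii].mean() - 0.1) <= 0.02 + 1e-12

    def test_linear_ramp_matches_dense_rasterization(self, rng):
        ny, nx, d = 10, 14, 0.1
        vals = np.add.outer(np.arange(ny), np.arange(nx)).astype(float)
        fm = _regular_flatmap(nx, ny, d, vals)
        g = mapmath.regrid(fm, 0.025)
        # dense-rasterization oracle: paint each quad's value onto a fine
        # lattice, convolve directly at the kernel scale (sigma = half the
        # quad side), and read off the grid pixel centers
        from scipy.ndimage import gaussian_filter
        fine = 0.0025
        H = int(ny * d / fine)
        W = int(nx * d / fine)
        yy, xx = np.mgrid[:H, :W]
        img = vals[(yy * fine / d).astype(int), (xx * fine / d).astype(int)]
        smooth = gaussian_filter(img.astype(float), sigma=(d / 2) / fine,
                                 mode="nearest")
        xs, ys = g.centers()
        interior = g.mask.copy()
        interior[:, (xs < 1.5 * d) | (xs > (nx - 1.5) * d)] = False
        interior[(ys < 1.5 * d) | (ys > (ny - 1.5) * d), :] = False
        err = []
        for i, j in zip(*np.nonzero(interior)):
            oracle = smooth[int(round(ys[i] / fine)), int(round(xs[j] / fine))]
            err.append(g.values[i, j] - oracle)
        rms = np.sqrt(np.mean(np.square(err)))
        assert rms / np.ptp(vals) < 0.01

    def test_linearity_in_values(self, rng):
        ny, nx = 6, 9
        v1 = rng.random((ny, nx))
        v2 = rng.random((ny, nx))
        a, b = 2.3, -0.7
        g1 = mapmath.regrid(_regular_flatmap(nx, ny, 0.1, v1), 0.04)
        g2 = mapmath.regrid(_regular_flatmap(nx, ny, 0.1, v2), 0.04)
        g3 = mapmath.regrid(_regular_flatmap(nx, ny, 0.1, a * v1 + b * v2), 0.04)
        m = mapmath.common_mask([g1, g2, g3])
        assert np.abs(g3.values[m] - (a * g1.values[m] + b * g2.values[m])).max() < 1e-9

    def test_bad_pixel_size_rejected(self):
        with pytest.raises(InvalidInputError):
            mapmath.regrid(_regular_flatmap(), 0.0)


class TestCommonMask:
    def test_single_grid_returns_own_mask(self):
        g = mapmath.regrid(_regular_flatmap(), 0.05)
        np.testing.assert_array_equal(mapmath.common_mask([g]), g.mask)

    def test_disjoint_masks_give_empty(self):
        g = mapmath.regrid(_regular_flatmap(), 0.05)
        g2 = mapmath.GridMap(g.values.copy(), ~g.mask, g.pixel_mm, g.origin)
        assert not mapmath.common_mask([g, g2]).any()

    def test_mismatched_geometry_rejected(self):
        g = mapmath.regrid(_regular_flatmap(), 0.05)
        g2 = mapmath.GridMap(g.values.copy(), g.mask.copy(), g.pixel_mm,
                             g.origin + 0.5)
        with pytest.raises(InvalidInputError):
            mapmath.common_mask([g, g2])

    def test_partial_overlap_fraction_matches_geometry(self):
        g = mapmath.regrid(_regular_flatmap(), 0.05)
        shift = 3  # pixels
        m2 = np.zeros_like(g.mask)
        m2[:, shift:] = g.mask[:, :-shift]
        g2 = mapmath.GridMap(g.values.copy(), m2, g.pixel_mm, g.origin)
        inter = mapmath.common_mask([g, g2]).sum()
        expect = (g.mask[:, shift:] & g.mask[:, :-shift]).sum()
        assert inter == expect


def test_grid_save_load_round_trip(tmp_path):
    g = mapmath.regrid(_regular_flatmap(), 0.05)
    tif = tmp_path / "g.tif"
    csv = tmp_path / "g.csv"
    mapmath.save_grid(g, tif, csv)
    back = mapmath.load_grid(tif, 0.05, g.origin)
    np.testing.assert_allclose(np.where(back.mask, back.values, 0),
                               np.where(g.mask, g.values, 0), atol=1e-6)
    assert csv.exists()
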