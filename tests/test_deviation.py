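"""Deviation images, disagreement/union regions, and scalar summaries."""

import numpy as np
import pytest

from contourdev import (
    BinaryMask,
    DistanceImage,
    GridMismatchError,
    ImageGrid,
    StructureContours,
    dd_pair,
    dd_std,
    dd_vs_reference,
    disagreement_region,
    rasterize,
    signed_distance_exact,
    summarize,
    union_region,
)
from contourdev.fixtures import FixtureSpec, make_fixture

from conftest import circle_polygon, densify_polygon, grid_around, star_polygon, structure

GRID1 = ImageGrid((0, 0, 0), (1, 1, 1), (2, 2, 1))


def const_image(value, grid=GRID1):
    """Distance image with one constant value — for direct formula checks."""
    return DistanceImage(grid=grid, values=np.full(grid.shape, float(value)),
                         mode="slice2d", contoured_slices=frozenset({0}))


class TestFormulas:
    def test_pair_absolute_difference(self):
        dd = dd_pair(const_image(3.0), const_image(5.0))
        assert (dd.values == 2.0).all()
        assert dd.kind == "pair" and dd.n_analysed == 1

    def test_pair_symmetric_bit_exact(self):
        rng = np.random.default_rng(3)
        a = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        b = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        np.testing.assert_array_equal(dd_pair(a, b).values, dd_pair(b, a).values)

    def test_vs_reference_reduces_to_pair(self):
        rng = np.random.default_rng(4)
        a = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        r = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        np.testing.assert_array_equal(
            dd_vs_reference([a], r).values, dd_pair(a, r).values
        )

    def test_vs_reference_rms_of_plus_minus_two(self):
        ref = const_image(0.0)
        dd = dd_vs_reference([const_image(2.0), const_image(-2.0)], ref)
        np.testing.assert_allclose(dd.values, 2.0)

    def test_vs_reference_all_equal_is_zero(self):
        ref = const_image(1.5)
        dd = dd_vs_reference([const_image(1.5)] * 3, ref)
        assert (dd.values == 0.0).all()

    def test_std_population_formula(self):
        # distances {2, 4, 6} mm -> population std sqrt(8/3)
        dd = dd_std([const_image(2.0), const_image(4.0), const_image(6.0)])
        np.testing.assert_allclose(dd.values, np.sqrt(8.0 / 3.0))

    def test_std_sample_variance_option(self):
        dd = dd_std([const_image(2.0), const_image(4.0), const_image(6.0)],
                    sample_variance=True)
        np.testing.assert_allclose(dd.values, 2.0)

    def test_std_identical_images_zero(self):
        dd = dd_std([const_image(1.0)] * 4)
        assert (dd.values == 0.0).all()

    def test_std_of_two_is_half_pair(self):
        rng = np.random.default_rng(5)
        a = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        b = DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
        np.testing.assert_array_equal(
            dd_std([a, b]).values, dd_pair(a, b).values / 2.0
        )

    def test_std_order_invariant(self):
        rng = np.random.default_rng(6)
        imgs = [DistanceImage(GRID1, rng.normal(size=GRID1.shape), "slice2d", {0})
                for _ in range(5)]
        forward = dd_std(imgs).values
        np.testing.assert_array_equal(forward, dd_std(imgs[::-1]).values)

    def test_std_requires_two(self):
        with pytest.raises(ValueError, match="two"):
            dd_std([const_image(1.0)])

    def test_vs_reference_requires_input(self):
        with pytest.raises(ValueError, match="at least one"):
            dd_vs_reference([], const_image(0.0))

    def test_grid_mismatch_rejected(self):
        other = ImageGrid((0, 0, 0), (2, 2, 2), (2, 2, 1))
        with pytest.raises(GridMismatchError):
            dd_pair(const_image(1.0), const_image(1.0, grid=other))


class TestGeometricCases:
    def test_concentric_circles_constant_deviation(self, concentric_pair):
        inner, outer, grid = concentric_pair
        dd = dd_pair(signed_distance_exact(inner, grid),
                     signed_distance_exact(outer, grid))
        vals = dd.values[:, :, 0]
        assert np.isfinite(vals).all()
        np.testing.assert_allclose(vals, 2.0, atol=0.02)

    def test_identical_contours_zero_everywhere(self):
        poly = star_polygon(r=8, depth=2, spikes=5, n=180)
        grid = grid_around([poly], margin=4.0)
        d = signed_distance_exact(structure("s", poly), grid)
        d2 = signed_distance_exact(structure("s2", poly.copy()), grid)
        assert (dd_pair(d, d2).values[:, :, 0] == 0).all()

    def test_sigma_recovery_radial_family(self):
        """With per-contour radial offsets eps_i, D_i(x) = |x-c| - r - eps_i,
        so the per-voxel std of distances equals the std of the offsets."""
        spec = FixtureSpec(kind="perturbed_family", sigma=1.5, n_observers=8,
                           seed=11, n_vertices=180)
        structures, grid = make_fixture(spec)
        observers = [s for s in structures if s.role == "analysed"]
        dmaps = [signed_distance_exact(s, grid) for s in observers]
        dds = dd_std(dmaps)
        eps = np.random.default_rng(11).normal(0.0, 1.5, 8)
        union = union_region([rasterize(s, grid) for s in observers])
        measured = dds.values[union.values]
        np.testing.assert_allclose(measured, eps.std(), atol=0.05)


class TestRegions:
    def _hand_masks(self):
        grid = ImageGrid((0, 0, 0), (1, 1, 1), (3, 1, 1))
        def mk(bits):
            return BinaryMask(grid, np.asarray(bits, bool).reshape(3, 1, 1))
        # voxel 0: in all, voxel 1: in one of three, voxel 2: in none
        return [mk([1, 1, 0]), mk([1, 0, 0]), mk([1, 0, 0])]

    def test_disagreement_definition_cases(self):
        delta = disagreement_region(self._hand_masks()).values.ravel()
        np.testing.assert_array_equal(delta, [False, True, False])

    def test_identical_masks_no_disagreement(self):
        grid = ImageGrid((0, 0, 0), (1, 1, 1), (2, 2, 1))
        m = BinaryMask(grid, np.ones(grid.shape, bool))
        assert not disagreement_region([m, m, m]).values.any()

    def test_disagreement_concentric_annulus(self, concentric_pair):
        inner, outer, grid = concentric_pair
        delta = disagreement_region([rasterize(inner, grid), rasterize(outer, grid)])
        xs, ys = grid.slice_coordinates()
        r = np.hypot(*np.meshgrid(xs, ys, indexing="ij"))
        ring = (r > 10.1) & (r < 11.9)
        away = (r < 9.9) | (r > 12.1)
        assert delta.values[:, :, 0][ring].all()
        assert not delta.values[:, :, 0][away].any()

    def test_union_cases(self):
        masks = self._hand_masks()
        np.testing.assert_array_equal(
            union_region(masks).values.ravel(), [True, True, False]
        )
        np.testing.assert_array_equal(
            union_region(masks[:1]).values, masks[0].values
        )

    def test_union_disjoint_squares_adds_areas(self):
        sq1 = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], float)
        sq2 = sq1 + [10.0, 0.0]
        grid = grid_around([sq1, sq2], margin=2.0)
        m1 = rasterize(structure("a", sq1), grid)
        m2 = rasterize(structure("b", sq2), grid)
        union = union_region([m1, m2])
        assert union.values.sum() == m1.values.sum() + m2.values.sum()

    def test_union_nested_circles_is_outer(self, concentric_pair):
        inner, outer, grid = concentric_pair
        mo = rasterize(outer, grid)
        union = union_region([rasterize(inner, grid), mo])
        np.testing.assert_array_equal(union.values, mo.values)


class TestSummaries:
    def test_offset_squares_hausdorff(self, offset_squares):
        from scipy.spatial.distance import directed_hausdorff

        a, b, grid = offset_squares
        dd = dd_pair(signed_distance_exact(a, grid), signed_distance_exact(b, grid))
        s = summarize(dd, [rasterize(a, grid), rasterize(b, grid)])
        pa = densify_polygon(a.slices[0][0])
        pb = densify_polygon(b.slices[0][0])
        hausdorff = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
        assert s.dd_max == pytest.approx(hausdorff, abs=grid.in_plane_diagonal)
        assert s.dd_max == pytest.approx(3.0, abs=grid.in_plane_diagonal)

    def test_constant_deviation_mean_exact(self, concentric_pair):
        inner, outer, grid = concentric_pair
        masks = [rasterize(inner, grid), rasterize(outer, grid)]
        dd = dd_pair(signed_distance_exact(inner, grid),
                     signed_distance_exact(outer, grid))
        # force exactly constant deviation to pin down the averaging
        dd.values[np.isfinite(dd.values)] = 1.75
        s = summarize(dd, masks)
        assert s.dd_mean == 1.75
        assert s.dd_max == 1.75
        assert s.n_voxels_union >= s.n_voxels_disagreement > 0

    def test_identical_contours_all_zero(self):
        poly = circle_polygon(r=6, n=90)
        grid = grid_around([poly], margin=3.0)
        a, b = structure("a", poly), structure("b", poly.copy())
        dd = dd_pair(signed_distance_exact(a, grid), signed_distance_exact(b, grid))
        s = summarize(dd, [rasterize(a, grid), rasterize(b, grid)])
        assert s.dd_max == 0.0 and s.dd_mean == 0.0
        assert s.n_voxels_disagreement == 0

    def test_empty_union_is_error(self):
        grid = ImageGrid((0, 0, 0), (1, 1, 1), (2, 2, 1))
        empty = BinaryMask(grid, np.zeros(grid.shape, bool))
        dd = dd_pair(const_image(1.0), const_image(1.0))
        with pytest.raises(ValueError, match="union"):
            summarize(dd, [empty, empty])

    def test_statistics_restricted_to_valid_slices(self):
        """A slice contoured by only one structure must not contribute."""
        poly = circle_polygon(r=6, n=90)
        grid = grid_around([poly], margin=3.0, n_slices=2)
        a = StructureContours("a", {0: [poly], 1: [poly]})
        b = StructureContours("b", {0: [poly + [2.0, 0.0]]})
        dd = dd_pair(signed_distance_exact(a, grid), signed_distance_exact(b, grid))
        assert dd.valid_slices == frozenset({0})
        s = summarize(dd, [rasterize(a, grid), rasterize(b, grid)])
        # slice 1 (only 'a' contoured) would otherwise flood the region
        assert np.isfinite(s.dd_mean) and s.dd_max < 5.0

    def test_peak_confined_to_disagreement_region(self):
        """Deviations outside the union, and inside the intersection of all
        masks, never exceed the maximum over the disagreement region
        (up to one voxel diagonal: the supremum sits on the region
        boundary, between lattice points)."""
        cases = [
            (circle_polygon(r=10, n=180), circle_polygon(r=12, n=180)),
            (star_polygon(r=9, depth=2, spikes=5, n=180),
             star_polygon(r=9, depth=2, spikes=5, n=180) + [2.5, 1.0]),
        ]
        for pa, pb in cases:
            grid = grid_around([pa, pb], margin=6.0)
            a, b = structure("a", pa), structure("b", pb)
            dd = dd_pair(signed_distance_exact(a, grid),
                         signed_distance_exact(b, grid))
            ma, mb = rasterize(a, grid), rasterize(b, grid)
            delta = disagreement_region([ma, mb]).values
            union = union_region([ma, mb]).values
            intersection = ma.values & mb.values
            peak = dd.values[delta].max()
            tol = grid.in_plane_diagonal
            assert dd.values[~union].max() <= peak + tol
            if intersection.any():
                assert dd.values[intersection].max() <= peak + tol

    def test_mean_deviation_triangle_inequality_violation(self):
        """The mean deviation is not a metric: for three collinear circles
        the direct A-C disagreement exceeds the A-B plus B-C sum (fixture
        found by numeric search)."""
        grid = ImageGrid((-12, -12, 0), (1, 1, 1), (55, 25, 1))
        circles = {
            name: structure(name, circle_polygon(cx=cx, r=5.0, n=256))
            for name, cx in [("A", 0.0), ("B", 15.0), ("C", 30.0)]
        }
        dist = {k: signed_distance_exact(s, grid) for k, s in circles.items()}
        masks = {k: rasterize(s, grid) for k, s in circles.items()}

        def mean_dd(p, q):
            dd = dd_pair(dist[p], dist[q])
            return summarize(dd, [masks[p], masks[q]]).dd_mean

        assert mean_dd("A", "C") > mean_dd("A", "B") + mean_dd("B", "C")
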