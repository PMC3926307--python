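import numpy as np
import pytest

import ablazone as az
from ablazone.geometry import AxisDiameters, ShapeMetrics

from _oracles import line_mask_extent


class TestBarycenter:
    def test_sphere_center_recovered(self):
        grid, _ = az.make_sphere(10.0, center=(50.0, 50.0, 25.0), spacing=(1, 1, 0.5))
        assert az.barycenter(grid) == pytest.approx((50.0, 50.0, 25.0), abs=0.25)

    def test_single_voxel_exact(self):
        occ = np.zeros((8, 8, 8), bool)
        occ[3, 4, 5] = True
        grid = az.VolumeGrid(occ, (1, 1, 0.5))
        assert az.barycenter(grid) == pytest.approx((3.0, 4.0, 2.5))

    def test_two_voxels_midpoint(self):
        occ = np.zeros((12, 4, 4), bool)
        occ[0, 0, 0] = occ[10, 0, 0] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        assert az.barycenter(grid) == pytest.approx((5.0, 0.0, 0.0))


class TestPrincipalAxes:
    def test_axis_aligned_ellipsoid(self, ellipsoid):
        grid, _ = ellipsoid
        axes = az.principal_axes(grid)
        for row, expected in zip(axes, np.eye(3)):
            assert abs(row @ expected) > 0.999

    def test_rotated_ellipsoid_tracks_rotation(self):
        angle = 30.0
        grid, _ = az.make_ellipsoid((20, 15, 8), rotation=angle)
        axes = az.principal_axes(grid)
        t = np.deg2rad(angle)
        expected = np.array([np.cos(t), np.sin(t), 0.0])
        misalignment = np.degrees(np.arccos(min(1.0, abs(axes[0] @ expected))))
        assert misalignment < 2.0

    def test_sphere_isotropy(self, sphere20):
        """Any orthonormal triple is acceptable; eigenvalue spread is tiny."""
        grid, _ = sphere20
        coords = grid.foreground_world()
        c = coords - coords.mean(axis=0)
        evals = np.linalg.eigvalsh(c.T @ c / len(c))
        assert (evals.max() - evals.min()) / evals.max() < 0.01
        axes = az.principal_axes(grid)
        assert np.allclose(axes @ axes.T, np.eye(3), atol=1e-9)

    def test_collinear_mask_raises(self):
        occ = np.zeros((20, 5, 5), bool)
        occ[2:18, 2, 2] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        with pytest.raises(ValueError, match="collinear"):
            az.principal_axes(grid)

    def test_planar_mask_raises(self):
        occ = np.zeros((20, 20, 5), bool)
        occ[2:18, 2:18, 2] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        with pytest.raises(ValueError, match="planar"):
            az.principal_axes(grid)


class TestChordDiameter:
    def test_sphere_through_center(self, sphere20):
        grid, _ = sphere20
        d = az.chord_diameter(grid, (0, 0, 0), (1, 0, 0))
        assert d == pytest.approx(40.0, abs=min(grid.spacing))

    def test_ellipsoid_along_x(self, ellipsoid):
        grid, _ = ellipsoid
        d = az.chord_diameter(grid, (0, 0, 0), (1, 0, 0))
        assert d == pytest.approx(40.0, abs=min(grid.spacing))

    def test_dumbbell_outer_extent_spans_the_waist(self):
        """Interior thinning must not shorten the outer-extent chord."""
        grid, truth = az.make_dumbbell(5.0, 30.0, 2.0, spacing=(1, 1, 1))
        bc = az.barycenter(grid)
        d = az.chord_diameter(grid, bc, (1, 0, 0))
        assert d == pytest.approx(truth["long_diameter_mm"], abs=min(grid.spacing))
        assert d == pytest.approx(line_mask_extent(grid, bc, (1, 0, 0)), abs=0.3)

    def test_line_missing_foreground_raises(self, sphere20):
        grid, _ = sphere20
        with pytest.raises(ValueError, match="misses"):
            az.chord_diameter(grid, (0, 0, 30.0), (1, 0, 0))


class TestAxisDiameters:
    def test_ellipsoid_triple(self, ellipsoid):
        grid, truth = ellipsoid
        d = az.axis_diameters(grid)
        tol = min(grid.spacing)
        assert d.as_tuple == pytest.approx(truth["diameters_mm"], abs=tol)

    def test_sphere_triple(self, sphere20):
        grid, _ = sphere20
        d = az.axis_diameters(grid)
        assert d.as_tuple == pytest.approx((40.0, 40.0, 40.0), abs=min(grid.spacing))

    def test_rotation_invariance(self, ellipsoid, rotated_ellipsoid):
        g0, _ = ellipsoid
        g1, _ = rotated_ellipsoid
        d0 = np.asarray(az.axis_diameters(g0).as_tuple)
        d1 = np.asarray(az.axis_diameters(g1).as_tuple)
        assert np.abs(d0 - d1).max() <= 2 * max(g0.spacing)

    def test_ordering_invariant_on_varied_phantoms(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            semi = np.sort(rng.uniform(5, 15, 3))[::-1]
            g, _ = az.make_ellipsoid(semi, rotation=float(rng.uniform(0, 180)))
            d = az.axis_diameters(g)
            assert d.long_mm >= d.intermediate_mm >= d.short_mm > 0

    def test_axis_diameters_bounded_by_feret(self, ellipsoid):
        """Each chord through the barycenter is at most the overall extent."""
        grid, _ = ellipsoid
        d = az.axis_diameters(grid)
        pts = grid.foreground_world()
        # Feret diameter upper bound via bounding-box diagonal
        bbox_diag = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        assert d.long_mm <= bbox_diag + 1e-9


class TestShapeRatios:
    def test_circularity_worked_examples(self):
        # printed one-decimal group means: 17.2/42.1 -> 0.4, 53.8/71.0 -> 0.8
        d1 = AxisDiameters.from_lengths(42.1, 30.1, 17.2)
        assert az.circularity(d1) == pytest.approx(0.409, abs=5e-4)
        assert round(az.circularity(d1), 1) == 0.4
        d3 = AxisDiameters.from_lengths(71.0, 56.3, 53.8)
        assert az.circularity(d3) == pytest.approx(0.758, abs=5e-4)
        assert round(az.circularity(d3), 1) == 0.8

    def test_sphericity_worked_examples(self):
        d2 = AxisDiameters.from_lengths(43.7, 35.7, 27.9)
        assert az.sphericity(d2) == pytest.approx(1.374, abs=5e-4)
        assert round(az.sphericity(d2), 1) == 1.4
        d = AxisDiameters.from_lengths(40.0, 30.0, 16.0)
        assert az.sphericity(d) == pytest.approx(40.0 / 23.0)

    def test_sphere_limits(self):
        d = AxisDiameters.from_lengths(20.0, 20.0, 20.0)
        assert az.circularity(d) == 1.0
        assert az.sphericity(d) == 1.0

    def test_ordered_triples_bound_the_ratios(self):
        """Size-ordered diameters force circularity <= 1 and sphericity >= 1."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            triple = np.sort(rng.uniform(1, 80, 3))[::-1]
            s = ShapeMetrics.from_lengths(*triple)
            assert 0 < s.circularity <= 1
            assert s.sphericity >= 1

    def test_invalid_diameters_rejected(self):
        with pytest.raises(ValueError):
            AxisDiameters.from_lengths(10.0, 20.0, 5.0)
        with pytest.raises(ValueError):
            AxisDiameters.from_lengths(10.0, 5.0, 0.0)
        with pytest.raises(ValueError, match="orthonormal"):
            AxisDiameters(3.0, 2.0, 1.0, np.ones((3, 3)), np.zeros(3))
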