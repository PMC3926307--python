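import numpy as np
import pytest
from scipy import ndimage as ndi

import ablazone as az

from _oracles import brute_force_inscribed, nearest_background_distances


class TestDistanceMap:
    def test_single_voxel_distance_one(self):
        occ = np.zeros((5, 5, 5), bool)
        occ[2, 2, 2] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        assert az.distance_map(grid)[2, 2, 2] == pytest.approx(1.0)

    def test_cube_center_matches_exhaustive_search(self):
        occ = np.zeros((7, 7, 7), bool)
        occ[2:5, 2:5, 2:5] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        dm = az.distance_map(grid)
        fg = np.argwhere(occ)
        oracle = nearest_background_distances(grid)
        assert dm[fg[:, 0], fg[:, 1], fg[:, 2]] == pytest.approx(oracle, abs=1e-9)
        assert dm[3, 3, 3] == pytest.approx(2.0)

    def test_anisotropic_slab_mid_distance(self):
        """5-voxel slab at 0.5 mm z-spacing: mid-slab distance is 1.5 mm."""
        occ = np.zeros((21, 21, 9), bool)
        occ[:, :, 2:7] = True
        grid = az.VolumeGrid(occ, (1, 1, 0.5))
        dm = az.distance_map(grid)
        assert dm[10, 10, 4] == pytest.approx(1.5)
        oracle = nearest_background_distances(grid)
        fg = np.argwhere(occ)
        assert dm[fg[:, 0], fg[:, 1], fg[:, 2]] == pytest.approx(oracle, abs=1e-9)

    def test_border_touching_zone_is_bounded(self):
        """Foreground on the grid border still sees background via padding."""
        occ = np.ones((6, 6, 6), bool)
        grid = az.VolumeGrid(occ, (1, 1, 1))
        dm = az.distance_map(grid)
        assert dm[0, 0, 0] == pytest.approx(1.0)


class TestLargestInscribedSphere:
    def test_sphere_is_its_own_inscribed_sphere(self, sphere20):
        grid, _ = sphere20
        s = az.largest_inscribed_sphere(grid)
        assert s.diameter_mm == pytest.approx(40.0, abs=1.0)
        assert np.linalg.norm(s.center) <= 1.0
        assert s.barycenter_offset_mm <= 1.0

    def test_ellipsoid_inscribed_equals_short_axis(self, ellipsoid):
        grid, truth = ellipsoid
        s = az.largest_inscribed_sphere(grid)
        assert s.diameter_mm == pytest.approx(truth["inscribed_diameter_mm"], abs=1.0)
        assert np.linalg.norm(s.center - truth["center"]) <= 1.0

    def test_notched_sphere_matches_analytic_truth_and_oracle(self, notched_sphere):
        grid, truth = notched_sphere
        bc = az.barycenter(grid)
        s = az.largest_inscribed_sphere(grid, bc)
        assert s.diameter_mm < truth["outer_diameter_mm"]
        assert s.diameter_mm == pytest.approx(truth["inscribed_diameter_mm"], abs=1.0)
        idx, dmax = brute_force_inscribed(grid, bc)
        assert s.diameter_mm == pytest.approx(
            2 * (dmax - min(grid.spacing) / 2), abs=1e-6
        )
        assert tuple(grid.world_to_index(s.center)[0]) == idx

    def test_containment_every_inner_voxel_is_foreground(self, notched_sphere):
        grid, _ = notched_sphere
        s = az.largest_inscribed_sphere(grid)
        pts = grid.world_coordinates(np.indices(grid.shape).reshape(3, -1).T)
        inside = np.linalg.norm(pts - s.center, axis=1) <= s.diameter_mm / 2
        assert grid.occupancy.ravel()[inside].all()

    def test_erosion_dilation_monotonicity(self, ellipsoid):
        grid, _ = ellipsoid
        d0 = az.largest_inscribed_sphere(grid).diameter_mm
        eroded = grid.with_occupancy(ndi.binary_erosion(grid.occupancy))
        dilated = grid.with_occupancy(ndi.binary_dilation(grid.occupancy))
        assert az.largest_inscribed_sphere(eroded).diameter_mm <= d0 + 1e-9
        assert az.largest_inscribed_sphere(dilated).diameter_mm >= d0 - 1e-9

    def test_eccentricity_detected_only_when_present(self, sphere20, notched_sphere):
        sym, _ = sphere20
        ecc, truth = notched_sphere
        assert az.largest_inscribed_sphere(sym).barycenter_offset_mm <= 1.0
        off = az.largest_inscribed_sphere(ecc).barycenter_offset_mm
        assert off > 1.0
        assert off == pytest.approx(truth["chebyshev_radial_distance_mm"], abs=1.5)

    def test_tie_break_prefers_barycenter_then_linear_index(self):
        """An elongated box has a medial ridge of equal maxima."""
        occ = np.zeros((30, 11, 11), bool)
        occ[3:27, 3:8, 3:8] = True
        grid = az.VolumeGrid(occ, (1, 1, 1))
        bc = az.barycenter(grid)
        s = az.largest_inscribed_sphere(grid, bc)
        idx, _ = brute_force_inscribed(grid, bc)
        assert tuple(grid.world_to_index(s.center)[0]) == idx


class TestTumorSphere:
    @pytest.mark.parametrize(
        "inscribed,margin,expected",
        [(19.6, 5.0, 9.6), (39.0, 5.0, 29.0), (53.8, 5.0, 43.8), (8.0, 5.0, 0.0)],
    )
    def test_margin_subtraction(self, inscribed, margin, expected):
        s = az.InscribedSphere(np.zeros(3), inscribed, 0.0)
        t = az.treatable_tumor_sphere(s, margin)
        assert t.diameter_mm == pytest.approx(expected)
        assert np.array_equal(t.center, s.center)

    def test_negative_margin_rejected(self):
        s = az.InscribedSphere(np.zeros(3), 20.0, 0.0)
        with pytest.raises(ValueError, match="margin"):
            az.treatable_tumor_sphere(s, -1.0)


class TestCoverage:
    def test_concentric_small_tumor_covered(self, sphere20):
        grid, _ = sphere20
        ins = az.largest_inscribed_sphere(grid)
        tumor = az.TumorSphere(ins.center, 10.0, 5.0)
        res = az.coverage_check(grid, tumor, margin_mm=5.0)
        assert res.covered
        assert res.min_margin_mm >= 15.0 - max(grid.spacing)
        assert res.first_failure is None

    def test_oversized_tumor_not_covered(self, sphere20):
        grid, _ = sphere20
        res = az.coverage_check(grid, az.TumorSphere(np.zeros(3), 31.0, 5.0), 5.0)
        assert not res.covered
        assert res.first_failure is not None

    def test_off_center_tumor_matches_voxelwise_oracle(self, ellipsoid):
        from _oracles import brute_force_coverage
        from ablazone.chebyshev import _tumor_indices

        grid, _ = ellipsoid
        for shift, margin in [((8.0, 0, 0), 2.0), ((8.0, 0, 0), 6.0), ((0, 10.0, 0), 1.0)]:
            tumor = az.TumorSphere(np.asarray(shift), 8.0, margin)
            res = az.coverage_check(grid, tumor, margin)
            oracle = brute_force_coverage(grid, _tumor_indices(grid, tumor), margin)
            assert res.covered == oracle

    def test_tumor_grid_on_mismatched_lattice_rejected(self, sphere20):
        grid, _ = sphere20
        other, _ = az.make_sphere(5.0, spacing=(1, 1, 0.5))
        with pytest.raises(ValueError, match="disagree"):
            az.coverage_check(grid, other, 5.0)

    def test_tumor_mask_coverage(self, sphere20):
        grid, _ = sphere20
        small = az.sphere_mask(grid, (0.0, 0.0, 0.0), 10.0)
        assert az.coverage_check(grid, small, 5.0).covered
        big = az.sphere_mask(grid, (10.0, 0.0, 0.0), 25.0)
        assert not az.coverage_check(grid, big, 5.0).covered

    def test_margin_consistency_of_tumor_sphere(self, notched_sphere):
        """A tumor sphere at the Chebyshev center passes its own margin."""
        grid, _ = notched_sphere
        ins = az.largest_inscribed_sphere(grid)
        for margin in (2.0, 5.0):
            t = az.treatable_tumor_sphere(ins, margin)
            if t.diameter_mm <= 0:
                continue
            assert az.coverage_check(grid, t, margin).covered
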