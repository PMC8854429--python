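import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsatract.io import ROIMask, ScalarVolume, VoxelGrid
from tsatract.phantom import PhantomSpec, arc_curve, make_probability_pairs
from tsatract.tract import (
    CoreTrajectory,
    bidirectional_population_average,
    build_core_polyline,
    estimate_tract,
    flood_fill_distances,
    normalize_directed,
    threshold_with_dilated_rois,
    tract_probability,
    uncertainty_field,
    vertex_orientations,
)
from conftest import bfs_oracle, dist_to_polyline


def _vol(grid, arr):
    return ScalarVolume(grid, np.asarray(arr, float))


class TestNormalizeDirected:
    def test_direct_division(self):
        grid = VoxelGrid.isotropic((3, 1, 1), 2.0)
        vol, ok = normalize_directed(_vol(grid, [[[10]], [[5]], [[0]]]), 10)
        assert ok
        np.testing.assert_allclose(vol.data.ravel(), [1.0, 0.5, 0.0])

    def test_waypoint_ratio_clipped(self):
        # a voxel visited by 20 streamlines of which only 10 reach the target:
        # the raw ratio is 2.0 and is clipped to 1
        grid = VoxelGrid.isotropic((1, 1, 1), 2.0)
        assert 20 / 10 == 2.0
        vol, _ = normalize_directed(_vol(grid, [[[20]]]), 10)
        assert vol.data[0, 0, 0] == 1.0

    def test_zero_total_marks_unconnectable(self):
        grid = VoxelGrid.isotropic((2, 2, 2), 2.0)
        vol, ok = normalize_directed(_vol(grid, np.ones((2, 2, 2))), 0)
        assert not ok
        assert (vol.data == 0).all()


class TestBidirectionalAverage:
    def test_min_of_equal_maps_is_identity_up_to_scaling(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 2.0)
        rng = np.random.default_rng(0)
        m = _vol(grid, rng.uniform(0, 1, (4, 4, 4)))
        out = bidirectional_population_average([(m, m)], smoothing_fwhm=0.0)
        np.testing.assert_allclose(out.data, m.data / m.data.max(), atol=1e-12)

    def test_one_direction_zero_gives_zero(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 2.0)
        m = _vol(grid, np.random.default_rng(1).uniform(0, 1, (4, 4, 4)))
        z = _vol(grid, np.zeros((4, 4, 4)))
        out = bidirectional_population_average([(m, z)], smoothing_fwhm=0.0)
        assert (out.data == 0).all()

    def test_participant_average_then_global_renormalisation(self):
        # two participants with symmetric maps valued 0.2 and 0.6 at one voxel
        grid = VoxelGrid.isotropic((2, 1, 1), 2.0)
        p1 = _vol(grid, [[[0.2]], [[1.0]]])
        p2 = _vol(grid, [[[0.6]], [[1.0]]])
        out = bidirectional_population_average([(p1, p1), (p2, p2)], smoothing_fwhm=0.0)
        # mean is (0.4, 1.0); global max 1.0 leaves the average untouched
        np.testing.assert_allclose(out.data.ravel(), [0.4, 1.0])

    def test_grid_mismatch_rejected(self):
        a = _vol(VoxelGrid.isotropic((2, 2, 2), 2.0), np.ones((2, 2, 2)))
        b = _vol(VoxelGrid.isotropic((2, 2, 2), 3.0), np.ones((2, 2, 2)))
        with pytest.raises(Exception, match="grid"):
            bidirectional_population_average([(a, b)])


class TestThreshold:
    def _rois(self, grid):
        m = np.zeros(grid.dims, bool)
        a = m.copy()
        a[0, 0, 0] = True
        b = m.copy()
        b[-1, -1, -1] = True
        return ROIMask(grid, a, "a"), ROIMask(grid, b, "b")

    def test_subthreshold_field_keeps_only_dilated_rois(self):
        grid = VoxelGrid.isotropic((10, 10, 10), 2.0)
        roi_a, roi_b = self._rois(grid)
        members = threshold_with_dilated_rois(
            _vol(grid, np.full(grid.dims, 0.05)), roi_a, roi_b, alpha=0.07
        )
        from scipy.ndimage import binary_dilation, generate_binary_structure

        struct = generate_binary_structure(3, 3)
        expect = binary_dilation(roi_a.mask, struct, 3) | binary_dilation(roi_b.mask, struct, 3)
        np.testing.assert_array_equal(members, expect)

    def test_uniform_high_field_keeps_everything(self):
        grid = VoxelGrid.isotropic((6, 6, 6), 2.0)
        roi_a, roi_b = self._rois(grid)
        members = threshold_with_dilated_rois(
            _vol(grid, np.full(grid.dims, 0.5)), roi_a, roi_b
        )
        assert members.all()

    def test_threshold_is_inclusive_at_alpha(self):
        grid = VoxelGrid.isotropic((6, 6, 6), 2.0)
        roi_a, roi_b = self._rois(grid)
        field = np.zeros(grid.dims)
        field[3, 3, 3] = 0.07
        members = threshold_with_dilated_rois(_vol(grid, field), roi_a, roi_b, alpha=0.07)
        assert members[3, 3, 3]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_raising_alpha_shrinks_members(self, seed):
        grid = VoxelGrid.isotropic((8, 8, 8), 2.0)
        roi_a, roi_b = self._rois(grid)
        field = _vol(grid, np.random.default_rng(seed).uniform(0, 1, grid.dims))
        lo = threshold_with_dilated_rois(field, roi_a, roi_b, alpha=0.2)
        hi = threshold_with_dilated_rois(field, roi_a, roi_b, alpha=0.6)
        assert (hi <= lo).all()  # set inclusion


class TestFloodFill:
    def test_linear_corridor_distances(self):
        grid = VoxelGrid.isotropic((1, 1, 10), 2.0)
        members = np.ones(grid.dims, bool)
        seed = np.zeros(grid.dims, bool)
        seed[0, 0, 0] = True
        dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"))
        np.testing.assert_array_equal(dmap.labels[0, 0], [0] + list(range(1, 10)))

    def test_disconnected_member_unassigned(self):
        grid = VoxelGrid.isotropic((1, 1, 5), 2.0)
        members = np.ones(grid.dims, bool)
        members[0, 0, 2] = False
        seed = np.zeros(grid.dims, bool)
        seed[0, 0, 0] = True
        dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"))
        assert dmap.labels[0, 0, 3] == 0 and dmap.labels[0, 0, 4] == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_oracle_on_random_sets(self, connectivity):
        rng = np.random.default_rng(connectivity)
        grid = VoxelGrid.isotropic((10, 10, 10), 2.0)
        for _ in range(10):
            members = rng.uniform(size=grid.dims) < 0.5
            seed_idx = tuple(rng.integers(0, 10, size=3))
            members[seed_idx] = True
            seed = np.zeros(grid.dims, bool)
            seed[seed_idx] = True
            dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"), connectivity)
            oracle = bfs_oracle(members, [seed_idx], connectivity)
            for v in map(tuple, np.argwhere(members)):
                expect = oracle.get(v, 0)
                if v == seed_idx:
                    expect = 0
                assert dmap.labels[v] == expect, (v, connectivity)


class TestCorePolyline:
    def test_straight_phantom_recovers_line(self, straight_estimate, straight_spec):
        traj = straight_estimate.trajectory
        assert traj.accepted
        diag = np.sqrt(3) * 2.0
        devs = [dist_to_polyline(v, straight_spec.curve) for v in traj.vertices]
        assert max(devs) <= diag

    def test_broken_corridor_rejected(self):
        grid = VoxelGrid.isotropic((1, 1, 12), 2.0)
        field = np.ones(grid.dims)
        members = np.ones(grid.dims, bool)
        members[0, 0, 5:8] = False  # corridor broken before the target
        seed = np.zeros(grid.dims, bool)
        seed[0, 0, 0] = True
        target = np.zeros(grid.dims, bool)
        target[0, 0, 11] = True
        dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"))
        traj = build_core_polyline(
            _vol(grid, field), dmap, ROIMask(grid, target, "t"), target_dilation=0
        )
        assert traj.status == "rejected"

    def test_decoy_beyond_segment_limit_skipped(self):
        # corridor along z with a side arm leading to a decoy of higher
        # probability in stratum 7; the decoy is 4.47 mm from the stratum-6
        # corridor vertex, so the 4 mm segment constraint forces the
        # second-best (corridor) voxel, with no flag
        grid = VoxelGrid.isotropic((7, 7, 12), 2.0)
        field = np.zeros(grid.dims)
        members = np.zeros(grid.dims, bool)
        field[3, 3, :] = 0.8
        members[3, 3, :] = True
        for arm in [(3, 4, 4), (3, 5, 4)]:  # low-probability arm, d = 5 and 6
            field[arm] = 0.1
            members[arm] = True
        decoy = (3, 5, 5)  # reached via the arm at d = 7, same stratum as (3,3,7)
        field[decoy] = 0.99
        members[decoy] = True
        seed = np.zeros(grid.dims, bool)
        seed[3, 3, 0] = True
        target = np.zeros(grid.dims, bool)
        target[3, 3, 11] = True
        dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"), connectivity=6)
        assert dmap.labels[decoy] == dmap.labels[3, 3, 7] == 7
        prev_vertex = grid.voxel_to_world([3.0, 3.0, 6.0])
        assert np.linalg.norm(
            grid.voxel_to_world(np.array(decoy, float)) - prev_vertex
        ) == pytest.approx(np.sqrt(20), abs=1e-12)  # 4.47 mm > 4 mm
        traj = build_core_polyline(
            _vol(grid, field), dmap, ROIMask(grid, target, "t"), target_dilation=0
        )
        assert traj.accepted
        assert traj.flags == []
        on_axis = np.abs(traj.vertices[:, :2] - 6.0) < 1e-9
        assert on_axis.all()

    def test_flag_recorded_when_no_candidate_fits(self):
        # a corridor with a forced right-angle turn whose only candidate
        # violates the pi/3 angle constraint: vertex still added, but flagged
        grid = VoxelGrid.isotropic((1, 9, 9), 2.0)
        field = np.zeros(grid.dims)
        members = np.zeros(grid.dims, bool)
        path = [(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 1, 2), (0, 2, 2)]
        for p in path:
            field[p] = 0.9
            members[p] = True
        seed = np.zeros(grid.dims, bool)
        seed[0, 0, 0] = True
        target = np.zeros(grid.dims, bool)
        target[0, 2, 2] = True
        dmap = flood_fill_distances(members, ROIMask(grid, seed, "s"), connectivity=6)
        traj = build_core_polyline(
            _vol(grid, field), dmap, ROIMask(grid, target, "t"), target_dilation=0
        )
        assert traj.accepted
        assert traj.flags  # 90-degree turn recorded for inspection


class TestVertexOrientations:
    def test_collinear_vertices_share_direction(self):
        verts = np.array([[0, 0, 0], [2, 0, 0], [4, 0, 0], [6, 0, 0]], float)
        omega = vertex_orientations(verts)
        np.testing.assert_allclose(omega, np.tile([1, 0, 0], (4, 1)), atol=1e-12)

    def test_right_angle_bend_bisects(self):
        verts = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0]], float)
        omega = vertex_orientations(verts)
        np.testing.assert_allclose(omega[1], [np.sqrt(0.5), np.sqrt(0.5), 0], atol=1e-12)

    def test_two_vertex_polyline(self):
        omega = vertex_orientations(np.array([[0, 0, 0], [0, 0, 2]], float))
        np.testing.assert_allclose(omega, [[0, 0, 1], [0, 0, 1]])

    def test_duplicate_vertices_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            vertex_orientations(np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float))


def _toy_trajectory():
    verts = np.array([[10, 10, 10], [14, 10, 10], [18, 10, 10]], float)
    return CoreTrajectory(verts, vertex_orientations(verts), [], "accepted")


class TestUncertaintyField:
    def test_phi_is_one_at_a_vertex(self):
        grid = VoxelGrid.isotropic((15, 15, 15), 2.0)
        phi = uncertainty_field(_toy_trajectory(), grid)
        idx = tuple(np.round(grid.world_to_voxel([10, 10, 10])).astype(int))
        assert phi.data[idx] == pytest.approx(1.0, abs=1e-12)

    def test_pure_radial_offset_at_sigma_r(self):
        grid = VoxelGrid.isotropic((15, 15, 15), 2.0)
        phi = uncertainty_field(_toy_trajectory(), grid, sigma_radial=4.0)
        # 4 mm radially from the middle vertex, i.e. exactly sigma_r away
        idx = tuple(np.round(grid.world_to_voxel([14, 14, 10])).astype(int))
        assert phi.data[idx] == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_zero_beyond_radius(self):
        grid = VoxelGrid.isotropic((20, 20, 20), 2.0)
        phi = uncertainty_field(_toy_trajectory(), grid, radius=8.0)
        centres = grid.voxel_centres().reshape(grid.dims + (3,))
        far = np.ones(grid.dims, bool)
        for v in _toy_trajectory().vertices:
            far &= np.linalg.norm(centres - v, axis=-1) > 8.0
        assert far.any()
        assert (phi.data[far] == 0).all()

    def test_rotation_invariance_of_value_multiset(self):
        # rotating trajectory and grid together by 90 degrees permutes voxels
        grid = VoxelGrid.isotropic((15, 15, 15), 2.0)
        phi_x = uncertainty_field(_toy_trajectory(), grid)
        verts_y = np.array([[10, 10, 10], [10, 14, 10], [10, 18, 10]], float)
        traj_y = CoreTrajectory(verts_y, vertex_orientations(verts_y), [], "accepted")
        phi_y = uncertainty_field(traj_y, grid)
        np.testing.assert_allclose(
            np.sort(phi_x.data.ravel()), np.sort(phi_y.data.ravel()), atol=1e-12
        )


class TestTractProbability:
    def _dmap(self, grid, labels):
        from tsatract.tract import DistanceMap

        return DistanceMap(grid, labels)

    def test_per_stratum_normalisation(self):
        grid = VoxelGrid.isotropic((2, 1, 1), 2.0)
        labels = np.ones(grid.dims, int)
        phi = _vol(grid, np.ones(grid.dims))
        p = _vol(grid, [[[0.2]], [[0.1]]])
        out = tract_probability(phi, p, self._dmap(grid, labels))
        np.testing.assert_allclose(out.data.ravel(), [1.0, 0.5])

    def test_zero_stratum_stays_zero(self):
        grid = VoxelGrid.isotropic((2, 1, 1), 2.0)
        labels = np.ones(grid.dims, int)
        out = tract_probability(
            _vol(grid, np.zeros(grid.dims)), _vol(grid, np.ones(grid.dims)),
            self._dmap(grid, labels),
        )
        assert (out.data == 0).all()

    def test_unlabelled_voxels_zero_and_unit_phi_renormalises_p(self):
        # 3 strata of 2 voxels plus one unlabelled voxel; hand-computed
        grid = VoxelGrid.isotropic((7, 1, 1), 2.0)
        labels = np.array([1, 1, 2, 2, 3, 3, 0]).reshape(grid.dims)
        p = np.array([0.2, 0.4, 0.9, 0.3, 0.05, 0.1, 0.7]).reshape(grid.dims)
        out = tract_probability(
            _vol(grid, np.ones(grid.dims)), _vol(grid, p), self._dmap(grid, labels)
        )
        expect = [0.5, 1.0, 1.0, 1 / 3, 0.5, 1.0, 0.0]
        np.testing.assert_allclose(out.data.ravel(), expect)

    def test_stratum_maxima_are_one_on_phantom(self, straight_estimate):
        est = straight_estimate
        labels = est.distance_map.labels
        for d in range(1, est.distance_map.max_distance + 1):
            vals = est.p_tract.data[labels == d]
            if (vals > 0).any():
                assert vals.max() == pytest.approx(1.0, abs=1e-12)


class TestArcPhantom:
    def test_arc_recovery_within_voxel_diagonal(self):
        grid = VoxelGrid.isotropic((48, 48, 24), 2.0)
        curve = arc_curve([47.0, 16.0, 23.0], 30.0, np.pi * 0.85, np.pi * 0.15,
                          plane="xy", n=300)
        spec = PhantomSpec(grid, curve, tube_sigma=4.0, roi_radius=4.0, seed=21)
        pairs, orient, roi_a, roi_b = make_probability_pairs(spec, 6)
        est = estimate_tract(pairs, roi_a, roi_b)
        assert est.accepted
        diag = np.sqrt(3) * 2.0
        devs = [dist_to_polyline(v, curve) for v in est.trajectory.vertices]
        assert max(devs) <= diag

    def test_overthresholding_rejects(self, straight_phantom):
        # a threshold above the jittered ridge floor breaks every route
        pairs, orient, roi_a, roi_b = straight_phantom
        est = estimate_tract(pairs, roi_a, roi_b, alpha=0.999)
        assert not est.accepted
        assert est.phi is None and est.p_tract is None
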