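import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import littplan as lp
from littplan.geometry import SkullSurface

from conftest import identity_affine


def brute_force_distance(mask: lp.BinaryMask, points: np.ndarray) -> np.ndarray:
    """Independent oracle: min Euclidean distance to any source voxel centre."""
    centres = mask.world_from_voxel(np.argwhere(mask.data))
    return np.array([np.linalg.norm(centres - p, axis=1).min() for p in points])


class TestDistanceField:
    def test_face_neighbour_distance_is_one_spacing(self):
        data = np.zeros((15, 15, 15), dtype=bool)
        data[7, 7, 7] = True
        field = lp.distance_field(lp.BinaryMask(data, identity_affine(-7)))
        assert field.query(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)
        assert field.query(np.array([5.0, 0.0, 0.0])) == pytest.approx(5.0, abs=1e-9)

    def test_zero_on_source_voxels(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[2, 3, 4] = True
        field = lp.distance_field(lp.BinaryMask(data, np.eye(4)))
        assert field.query(np.array([2.0, 3.0, 4.0])) == 0.0

    def test_empty_mask_is_an_error(self):
        with pytest.raises(lp.GeometryError):
            lp.distance_field(lp.BinaryMask(np.zeros((4, 4, 4), dtype=bool), np.eye(4)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((24, 24, 24)) < 0.01
        data[12, 12, 12] = True
        mask = lp.BinaryMask(data, identity_affine(-12))
        field = lp.distance_field(mask)
        pts = rng.uniform(-11, 11, size=(50, 3))
        expected = brute_force_distance(mask, pts)
        diag = np.sqrt(3.0)
        assert np.all(np.abs(field.query(pts) - expected) <= diag)

    def test_anisotropic_spacing_honoured(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[4, 4, 4] = True
        affine = np.diag([1.0, 1.0, 2.0, 1.0])
        field = lp.distance_field(lp.BinaryMask(data, affine))
        # one voxel step along the 2 mm axis is 2 mm away
        assert field.query(affine[:3, :3] @ np.array([4, 4, 5]) + affine[:3, 3]) == pytest.approx(2.0)

    def test_lipschitz_in_world_mm(self):
        rng = np.random.default_rng(3)
        data = rng.random((20, 20, 20)) < 0.02
        data[10, 10, 10] = True
        mask = lp.BinaryMask(data, identity_affine(-10))
        field = lp.distance_field(mask)
        p = rng.uniform(-9, 9, size=(200, 3))
        q = p + rng.uniform(-3, 3, size=(200, 3))
        dp, dq = field.query(p), field.query(q)
        slack = np.sqrt(3.0)  # one voxel diagonal of interpolation tolerance
        assert np.all(np.abs(dp - dq) <= np.linalg.norm(p - q, axis=1) + slack)

    def test_outside_grid_clamps_to_border(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        field = lp.distance_field(lp.BinaryMask(data, np.eye(4)))
        inside = field.query(np.array([4.0, 2.0, 2.0]))
        outside = field.query(np.array([40.0, 2.0, 2.0]))
        assert outside == pytest.approx(inside)


class TestSampleNodes:
    def test_two_nodes_are_the_endpoints(self):
        traj = lp.Trajectory(np.zeros(3), np.array([10.0, 0, 0]))
        nodes = lp.sample_nodes(traj, 2)
        assert np.allclose(nodes, [traj.entry, traj.target])

    def test_midpoint_at_half_length(self):
        traj = lp.Trajectory(np.zeros(3), np.array([100.0, 0, 0]))
        assert np.allclose(lp.sample_nodes(traj, 3)[1], [50.0, 0, 0])

    def test_128_nodes_equally_spaced(self):
        traj = lp.Trajectory(np.array([3.0, -2.0, 7.0]), np.array([-40.0, 55.0, 13.0]))
        nodes = lp.sample_nodes(traj, 128)
        gaps = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        assert np.all(np.abs(gaps - traj.length / 127) < 1e-9)

    @given(st.integers(min_value=-5, max_value=1))
    @settings(deadline=None, derandomize=True)
    def test_fewer_than_two_nodes_rejected(self, n):
        traj = lp.Trajectory(np.zeros(3), np.ones(3))
        with pytest.raises(lp.ParameterError):
            lp.sample_nodes(traj, n)

    def test_zero_length_trajectory_rejected(self):
        with pytest.raises(lp.GeometryError):
            lp.Trajectory(np.ones(3), np.ones(3))


def _slab_skull(axis=2):
    """Flat skull slab normal to one axis inside a 40^3 grid."""
    data = np.zeros((40, 40, 40), dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(28, 32)
    data[tuple(sl)] = True
    return lp.BinaryMask(data, identity_affine(-20))


class TestSkullNormal:
    def test_flat_slab_normal_is_axis_aligned(self):
        mask = _slab_skull(axis=2)
        n = lp.skull_normal(mask, np.array([0.0, 0.0, 7.5]))
        angle = np.degrees(np.arccos(abs(n @ np.array([0, 0, 1.0]))))
        assert angle < 2.0
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-6)

    def test_sphere_normal_is_radial(self):
        shape = (72, 72, 72)
        affine = identity_affine(-36)
        i, j, k = np.meshgrid(*[np.arange(s) - 36 for s in shape], indexing="ij")
        r = np.sqrt(i**2 + j**2 + k**2)
        mask = lp.BinaryMask((r >= 28) & (r <= 32), affine)
        surf = SkullSurface(mask)
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            entry = 27.0 * d  # just inside the inner table
            n = surf.normals(entry[None, :])[0]
            angle = np.degrees(np.arccos(np.clip(n @ d, -1, 1)))
            assert angle < 2.0

    def test_far_point_is_an_error(self):
        mask = _slab_skull(axis=2)
        with pytest.raises(lp.GeometryError):
            lp.skull_normal(mask, np.array([0.0, 0.0, -15.0]))


class TestDrillingAngle:
    def test_closed_form_values(self):
        traj = lp.Trajectory(np.zeros(3), np.array([0, 0, 10.0]))
        assert lp.drilling_angle(traj, np.array([0, 0, 1.0])) == pytest.approx(0.0)
        assert lp.drilling_angle(traj, np.array([1.0, 0, 0])) == pytest.approx(90.0)
        n = np.array([np.sin(np.radians(30)), 0, np.cos(np.radians(30))])
        assert lp.drilling_angle(traj, n) == pytest.approx(30.0, abs=1e-9)

    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    @settings(deadline=None, derandomize=True)
    def test_orientation_insensitive(self, d, n):
        d, n = np.asarray(d), np.asarray(n)
        if np.linalg.norm(d) < 1e-3 or np.linalg.norm(n) < 1e-3:
            return
        traj = lp.Trajectory(np.zeros(3), d)
        assert lp.drilling_angle(traj, n) == pytest.approx(lp.drilling_angle(traj, -n))
        assert 0.0 <= lp.drilling_angle(traj, n) <= 90.0


class TestSegmentIntersects:
    def _mask(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[12:20, 12:20, 12:20] = True
        return lp.BinaryMask(data, identity_affine(-16))

    def test_outside_bounding_box_is_false(self):
        traj = lp.Trajectory(np.array([14.0, -14, -14]), np.array([14.0, 14, 14]))
        assert not lp.segment_intersects(self._mask(), traj)

    def test_through_centre_is_true(self):
        traj = lp.Trajectory(np.array([-15.0, 0, 0]), np.array([15.0, 0, 0]))
        assert lp.segment_intersects(self._mask(), traj)

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((16, 16, 16)) < 0.02
        mask = lp.BinaryMask(data, identity_affine(-8))
        traj = lp.Trajectory(rng.uniform(-8, 8, 3), rng.uniform(-8, 8, 3))
        # independent oracle: 0.01 mm sampling with explicit rounding test
        n = int(np.ceil(traj.length / 0.01)) + 1
        pts = traj.entry + np.linspace(0, 1, n)[:, None] * (traj.target - traj.entry)
        ijk = np.rint(pts + 8).astype(int)
        ok = np.all((ijk >= 0) & (ijk < 16), axis=1)
        oracle = bool(data[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]].any()) if ok.any() else False
        assert lp.segment_intersects(mask, traj) == oracle


class TestMinDistanceAlong:
    def test_through_source_is_zero(self):
        data = np.zeros((16, 16, 16), dtype=bool)
        data[8, 8, 8] = True
        field = lp.distance_field(lp.BinaryMask(data, identity_affine(-8)))
        traj = lp.Trajectory(np.array([-7.0, 0, 0]), np.array([7.0, 0, 0]))
        assert lp.min_distance_along(traj, field, 129) == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_line(self):
        data = np.zeros((32, 32, 32), dtype=bool)
        data[16, 4:28, 16] = True  # straight source along y
        field = lp.distance_field(lp.BinaryMask(data, identity_affine(-16)))
        traj = lp.Trajectory(np.array([7.0, -10, 0]), np.array([7.0, 10, 0]))
        assert lp.min_distance_along(traj, field, 128) == pytest.approx(7.0, abs=np.sqrt(3))

    def test_dilating_source_never_increases_distance(self):
        from scipy import ndimage

        rng = np.random.default_rng(5)
        data = rng.random((24, 24, 24)) < 0.01
        data[12, 12, 12] = True
        affine = identity_affine(-12)
        grown = ndimage.binary_dilation(data, iterations=2)
        f1 = lp.distance_field(lp.BinaryMask(data, affine))
        f2 = lp.distance_field(lp.BinaryMask(grown, affine))
        for seed in range(5):
            r = np.random.default_rng(seed)
            traj = lp.Trajectory(r.uniform(-10, 10, 3), r.uniform(-10, 10, 3))
            assert lp.min_distance_along(traj, f2) <= lp.min_distance_along(traj, f1) + 1e-9


class TestRigidTranslationInvariance:
    def test_all_outputs_shift_with_the_world(self):
        rng = np.random.default_rng(11)
        data = rng.random((20, 20, 20)) < 0.03
        data[10, 10, 10] = True
        t = np.array([17.0, -23.0, 41.0])
        a1 = identity_affine(-10)
        a2 = a1.copy()
        a2[:3, 3] += t
        f1 = lp.distance_field(lp.BinaryMask(data, a1))
        f2 = lp.distance_field(lp.BinaryMask(data, a2))
        entry, target = np.array([-9.0, 1, 2]), np.array([8.0, -3, 1])
        tr1 = lp.Trajectory(entry, target)
        tr2 = lp.Trajectory(entry + t, target + t)
        assert lp.min_distance_along(tr1, f1) == pytest.approx(
            lp.min_distance_along(tr2, f2), abs=1e-6
        )
        m1 = lp.BinaryMask(data, a1)
        m2 = lp.BinaryMask(data, a2)
        assert lp.segment_intersects(m1, tr1) == lp.segment_intersects(m2, tr2)
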