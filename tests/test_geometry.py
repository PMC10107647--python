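"""Rotation parameterization, transforms and the sum-of-distances cost."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from lmreg3d import (
    AxisScales,
    EulerAngles,
    PairingMismatchError,
    PointSet,
    apply_scale,
    landmark_cost,
    rotation_matrix,
    transform_points,
)

from conftest import random_angles


class TestRotationMatrix:
    def test_identity_angles_give_identity(self):
        np.testing.assert_allclose(
            rotation_matrix(EulerAngles(0, 0, 0)), np.eye(3), atol=1e-15
        )

    def test_orthonormal_proper_on_random_angles(self, rng):
        for _ in range(1000):
            R = rotation_matrix(random_angles(rng))
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_matches_independent_euler_implementation(self, rng):
        # intrinsic Z-Y-X convention, cross-checked against scipy
        for _ in range(50):
            a = random_angles(rng)
            expected = Rotation.from_euler(
                "ZYX", [a.phi, a.theta, a.psi]
            ).as_matrix()
            np.testing.assert_allclose(rotation_matrix(a), expected, atol=1e-12)

    def test_applying_twice_equals_matrix_product(self, rng):
        a = random_angles(rng)
        R = rotation_matrix(a)
        v = rng.uniform(-5, 5, 3)
        np.testing.assert_allclose(R @ (R @ v), (R @ R) @ v, atol=1e-12)

    def test_non_finite_angle_rejected(self):
        with pytest.raises(ValueError):
            EulerAngles(np.nan, 0, 0)
        with pytest.raises(ValueError):
            EulerAngles(0, np.inf, 0)

    def test_normalized_wraps_into_canonical_range(self):
        a = EulerAngles(3 * np.pi, -np.pi, 2 * np.pi).normalized()
        arr = a.as_array()
        assert np.all(arr >= -np.pi) and np.all(arr < np.pi)
        np.testing.assert_allclose(
            rotation_matrix(a),
            rotation_matrix(EulerAngles(3 * np.pi, -np.pi, 2 * np.pi)),
            atol=1e-12,
        )


angle_st = st.floats(min_value=-4 * np.pi, max_value=4 * np.pi, allow_nan=False)


@given(phi=angle_st, theta=angle_st, psi=angle_st)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_rotation_matrix_is_always_proper(phi, theta, psi):
    R = rotation_matrix(EulerAngles(phi, theta, psi))
    np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
    assert abs(np.linalg.det(R) - 1.0) < 1e-12


class TestPointSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PointSet(ids=[1, 1], coords=[[0, 0, 0], [1, 1, 1]])

    def test_non_finite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PointSet.from_coords([[0, np.nan, 0]])

    def test_select_carries_ids(self):
        ps = PointSet(ids=[10, 20, 30], coords=np.arange(9.0).reshape(3, 3))
        sub = ps.select([2, 0])
        assert sub.ids.tolist() == [30, 10]
        np.testing.assert_array_equal(sub.coords, ps.coords[[2, 0]])


class TestApplyScale:
    def test_unit_scales_leave_points_unchanged(self, rng):
        ps = PointSet.from_coords(rng.uniform(0, 10, (5, 3)))
        out = apply_scale(ps, AxisScales(1, 1, 1))
        np.testing.assert_array_equal(out.coords, ps.coords)
        np.testing.assert_array_equal(out.ids, ps.ids)

    def test_componentwise_multiplication(self):
        ps = PointSet.from_coords([[2.0, 4.0, 10.0]])
        out = apply_scale(ps, AxisScales(1, 1, 0.5))
        np.testing.assert_allclose(out.coords, [[2.0, 4.0, 5.0]])

    def test_z_spacing_converts_slice_indices_to_physical(self):
        # live-embryo stacks: 0.575 um between z-slices
        slices = PointSet.from_coords([[0.0, 0.0, k] for k in (0, 1, 10, 40)])
        out = apply_scale(slices, AxisScales(1, 1, 0.575))
        np.testing.assert_allclose(out.coords[:, 2], [0.0, 0.575, 5.75, 23.0])

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            AxisScales(1, 0, 1)
        with pytest.raises(ValueError):
            AxisScales(1, 1, -2)


class TestTransformPoints:
    def test_identity_transform(self, rng):
        ps = PointSet.from_coords(rng.uniform(0, 10, (4, 3)))
        out = transform_points(ps, EulerAngles(), ps.centroid, ps.centroid)
        np.testing.assert_allclose(out.coords, ps.coords, atol=1e-12)

    def test_rotation_center_is_fixed_point(self, rng):
        c = rng.uniform(0, 10, 3)
        target = rng.uniform(0, 10, 3)
        ps = PointSet.from_coords([c])
        out = transform_points(ps, random_angles(rng), c, target)
        np.testing.assert_allclose(out.coords[0], target, atol=1e-12)

    def test_round_trip_with_inverse_rotation(self, rng):
        ps = PointSet.from_coords(rng.uniform(0, 10, (6, 3)))
        a = random_angles(rng)
        c1, c2 = rng.uniform(0, 10, 3), rng.uniform(0, 10, 3)
        fwd = transform_points(ps, a, c1, c2)
        # inverse rotation = transpose; recover its Euler angles via scipy
        inv = Rotation.from_matrix(rotation_matrix(a).T).as_euler("ZYX")
        back = transform_points(fwd, EulerAngles(*inv), c2, c1)
        np.testing.assert_allclose(back.coords, ps.coords, atol=1e-9)

    def test_rigidity_preserves_pairwise_distances(self, rng):
        from scipy.spatial.distance import pdist

        ps = PointSet.from_coords(rng.uniform(0, 50, (8, 3)))
        out = transform_points(ps, random_angles(rng), rng.uniform(0, 5, 3), rng.uniform(0, 5, 3))
        np.testing.assert_allclose(pdist(out.coords), pdist(ps.coords), atol=1e-9)


class TestLandmarkCost:
    def test_zero_at_true_angles_for_exact_rotation(self, rigid_pair_factory):
        first, second, angles = rigid_pair_factory(n=6)
        # cost aligns second onto first, so evaluate at the inverse angles
        inv = Rotation.from_matrix(rotation_matrix(angles).T).as_euler("ZYX")
        assert landmark_cost(first, second, EulerAngles(*inv)) < 1e-9

    def test_single_pair_costs_zero_for_any_angles(self, rng):
        p = PointSet.from_coords([[1.0, 2.0, 3.0]])
        q = PointSet.from_coords([[9.0, -4.0, 0.5]])
        assert landmark_cost(p, q, random_angles(rng)) < 1e-12

    def test_matches_per_pair_distance_sum_at_identity(self, rng):
        p = PointSet.from_coords(rng.uniform(0, 10, (5, 3)))
        q = PointSet.from_coords(rng.uniform(0, 10, (5, 3)))
        moved = q.coords - q.centroid + p.centroid
        expected = np.sum(np.linalg.norm(moved - p.coords, axis=1))
        assert landmark_cost(p, q, EulerAngles()) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_common_translation(self, rng):
        p = PointSet.from_coords(rng.uniform(0, 10, (5, 3)))
        q = PointSet.from_coords(rng.uniform(0, 10, (5, 3)))
        a = random_angles(rng)
        shifted = q.with_coords(q.coords + [17.0, -3.0, 42.0])
        assert landmark_cost(p, q, a) == pytest.approx(
            landmark_cost(p, shifted, a), abs=1e-9
        )

    def test_invariant_to_simultaneous_reordering(self, rng):
        p = PointSet.from_coords(rng.uniform(0, 10, (6, 3)))
        q = PointSet.from_coords(rng.uniform(0, 10, (6, 3)))
        a = random_angles(rng)
        perm = rng.permutation(6)
        assert landmark_cost(p.select(perm), q.select(perm), a) == pytest.approx(
            landmark_cost(p, q, a), abs=1e-9
        )

    def test_squared_mode_sums_squared_distances(self, rng):
        p = PointSet.from_coords(rng.uniform(0, 10, (4, 3)))
        q = PointSet.from_coords(rng.uniform(0, 10, (4, 3)))
        moved = q.coords - q.centroid + p.centroid
        expected = np.sum(np.sum((moved - p.coords) ** 2, axis=1))
        assert landmark_cost(p, q, EulerAngles(), squared=True) == pytest.approx(
            expected, abs=1e-10
        )

    def test_unequal_counts_raise_pairing_mismatch(self):
        p = PointSet.from_coords(np.zeros((3, 3)) + np.arange(3)[:, None])
        q = PointSet.from_coords(np.zeros((4, 3)) + np.arange(4)[:, None])
        with pytest.raises(PairingMismatchError):
            landmark_cost(p, q, EulerAngles())
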