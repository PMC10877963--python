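"""Pose math and guidance-parameter geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tracheoguide.errors import FrameMismatchError
from tracheoguide.geometry import (
    ANATOMICAL_FRAME,
    Frame,
    Pose6DOF,
    RigidTransform,
    apply_transform,
    axis_to_euler,
    euler_to_rotation,
    guidance_parameters,
    needle_axis,
    normalize_angle_deg,
)


def _rx(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


angles = st.floats(-180, 180, allow_nan=False, width=32)


class TestEulerToRotation:
    def test_identity(self):
        assert np.allclose(euler_to_rotation(0, 0, 0), np.eye(3))

    def test_quarter_turn_about_z_maps_x_to_y(self):
        rot = euler_to_rotation(0, 0, 90)
        assert np.allclose(rot @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @pytest.mark.parametrize("rpy", [(10, 20, 30), (-45, 80, 170), (5, -90, 12)])
    def test_matches_elementary_matrix_product(self, rpy):
        # Intrinsic Z-Y-X composition equals Rz(yaw) @ Ry(pitch) @ Rx(roll).
        roll, pitch, yaw = rpy
        expected = _rz(yaw) @ _ry(pitch) @ _rx(roll)
        assert np.allclose(euler_to_rotation(roll, pitch, yaw), expected, atol=1e-12)

    @given(roll=angles, pitch=angles, yaw=angles)
    def test_orthonormal_det_plus_one(self, roll, pitch, yaw):
        rot = euler_to_rotation(roll, pitch, yaw)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)
        assert math.isclose(np.linalg.det(rot), 1.0, abs_tol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            euler_to_rotation(float("nan"), 0, 0)


class TestNeedleAxis:
    def test_identity_orientation_points_along_z(self):
        pose = Pose6DOF(np.zeros(3), 0, 0, 0)
        assert np.allclose(needle_axis(pose), [0, 0, 1])

    def test_yaw_only_leaves_local_z_axis_unchanged(self):
        pose = Pose6DOF(np.zeros(3), 0, 0, 137.0)
        assert np.allclose(needle_axis(pose), [0, 0, 1], atol=1e-12)

    def test_roll_90_matches_elementary_rotation_of_z(self):
        pose = Pose6DOF(np.zeros(3), 90, 0, 0)
        assert np.allclose(needle_axis(pose), _rx(90) @ [0, 0, 1], atol=1e-12)

    @given(x=st.floats(-1, 1), y=st.floats(-1, 1), z=st.floats(0.1, 1))
    def test_axis_to_euler_round_trip(self, x, y, z):
        v = np.array([x, y, z])
        v /= np.linalg.norm(v)
        pose = Pose6DOF(np.zeros(3), *axis_to_euler(v))
        assert np.allclose(needle_axis(pose), v, atol=1e-7)


def _brute_force_params(pose, target):
    """Independent oracle: explicit projection formulas via cross products."""
    axis = pose.rotation() @ np.array([0.0, 0.0, 1.0])
    d = np.asarray(target, float) - pose.position
    dtt = float(np.dot(d, axis))
    radial = float(np.linalg.norm(np.cross(axis, d)))  # |d| sin(angle)
    euclid = float(np.linalg.norm(d))
    cos_a = axis[2] / np.linalg.norm(axis)
    a3 = math.degrees(math.acos(np.clip(cos_a, -1, 1)))
    alpha = min(a3, 180 - a3)
    return radial, dtt, euclid, alpha


class TestGuidanceParameters:
    def test_coincident_tip_and_target(self):
        pose = Pose6DOF(np.array([1.0, 2.0, 3.0]), 33, -12, 140)
        g = guidance_parameters(pose, np.array([1.0, 2.0, 3.0]))
        assert g.radial_distance_R == 0
        assert g.depth_to_target_DTT == 0
        assert g.euclidean_distance == 0

    def test_three_four_five_triangle(self):
        pose = Pose6DOF(np.zeros(3), 0, 0, 0)  # axis +Z
        g = guidance_parameters(pose, np.array([3.0, 4.0, 10.0]))
        assert g.radial_distance_R == pytest.approx(5.0, abs=1e-12)
        assert g.depth_to_target_DTT == pytest.approx(10.0, abs=1e-12)
        assert g.euclidean_distance == pytest.approx(math.sqrt(125), abs=1e-12)

    def test_alpha_is_cone_angle_from_vertical(self):
        vertical = Pose6DOF(np.zeros(3), 0, 0, 0)
        assert guidance_parameters(vertical, np.array([0, 0, 10.0])).alpha_deg == 0
        # needle axis in the sagittal (Y-Z) plane at 45 degrees to +Z
        tilted = Pose6DOF(np.zeros(3), *axis_to_euler([0, math.sqrt(0.5), math.sqrt(0.5)]))
        g = guidance_parameters(tilted, np.array([0, 0, 10.0]))
        assert g.alpha_deg == pytest.approx(45.0, abs=1e-9)

    def test_dtt_sign_negative_on_overshoot(self):
        pose = Pose6DOF(np.array([0, 0, 10.0]), 0, 0, 0)
        g = guidance_parameters(pose, np.array([0, 0, 4.0]))
        assert g.depth_to_target_DTT == pytest.approx(-6.0)

    def test_oracle_equivalence_on_random_configurations(self, rng):
        for _ in range(300):
            pose = Pose6DOF(
                rng.normal(0, 30, 3), *rng.uniform(-180, 180, 3)
            )
            target = rng.normal(0, 30, 3)
            g = guidance_parameters(pose, target)
            r, dtt, eu, alpha = _brute_force_params(pose, target)
            assert g.radial_distance_R == pytest.approx(r, abs=1e-9)
            assert g.depth_to_target_DTT == pytest.approx(dtt, abs=1e-9)
            assert g.euclidean_distance == pytest.approx(eu, abs=1e-9)
            assert g.alpha_deg == pytest.approx(alpha, abs=1e-9)

    def test_pythagoras(self, rng):
        for _ in range(200):
            pose = Pose6DOF(rng.normal(0, 20, 3), *rng.uniform(-180, 180, 3))
            g = guidance_parameters(pose, rng.normal(0, 20, 3))
            assert g.euclidean_distance**2 == pytest.approx(
                g.radial_distance_R**2 + g.depth_to_target_DTT**2, abs=1e-6
            )
            assert g.radial_distance_R <= g.euclidean_distance + 1e-12

    def test_radial_distance_increases_moving_target_off_axis(self):
        pose = Pose6DOF(np.zeros(3), 0, 0, 0)
        radii = [
            guidance_parameters(pose, np.array([off, 0, 25.0])).radial_distance_R
            for off in (0.0, 1.0, 3.0, 8.0, 20.0)
        ]
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_frame_mismatch_without_registration(self):
        pose = Pose6DOF(np.zeros(3), 0, 0, 0)
        target = Pose6DOF(np.ones(3), 0, 0, 0, frame=ANATOMICAL_FRAME)
        with pytest.raises(FrameMismatchError):
            guidance_parameters(pose, target)


class TestRigidTransform:
    def test_identity_leaves_input_unchanged(self):
        pose = Pose6DOF(np.array([1.0, 2, 3]), 10, 20, 30)
        out = apply_transform(pose, RigidTransform.identity())
        assert np.allclose(out.position, pose.position)
        assert out.roll == pytest.approx(pose.roll)

    def test_pure_translation_shifts_positions_only(self):
        t = RigidTransform(np.eye(3), np.array([5.0, -2, 1]))
        pose = Pose6DOF(np.zeros(3), 12, 34, 56)
        out = apply_transform(pose, t)
        assert np.allclose(out.position, [5, -2, 1])
        assert (out.roll, out.pitch, out.yaw) == pytest.approx(
            (pose.roll, pose.pitch, pose.yaw)
        )

    def test_distances_preserved(self, rng):
        t = RigidTransform.random(rng)
        a, b = rng.normal(0, 30, 3), rng.normal(0, 30, 3)
        d0 = np.linalg.norm(a - b)
        d1 = np.linalg.norm(apply_transform(a, t) - apply_transform(b, t))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_improper_rotation_rejected(self):
        reflect = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflect, np.zeros(3))

    def test_r_dtt_euclidean_invariant_under_common_transform(self, rng):
        for _ in range(100):
            pose = Pose6DOF(rng.normal(0, 30, 3), *rng.uniform(-180, 180, 3))
            target = rng.normal(0, 30, 3)
            g0 = guidance_parameters(pose, target)
            t = RigidTransform.random(rng)
            g1 = guidance_parameters(apply_transform(pose, t), apply_transform(target, t))
            assert g1.radial_distance_R == pytest.approx(g0.radial_distance_R, abs=1e-6)
            assert g1.depth_to_target_DTT == pytest.approx(
                g0.depth_to_target_DTT, abs=1e-6
            )
            assert g1.euclidean_distance == pytest.approx(g0.euclidean_distance, abs=1e-6)

    def test_alpha_invariant_under_z_preserving_transform(self, rng):
        # rotations about +Z fix the coronal-plane normal, so alpha is unchanged
        for _ in range(50):
            pose = Pose6DOF(rng.normal(0, 30, 3), *rng.uniform(-180, 180, 3))
            target = rng.normal(0, 30, 3)
            t = RigidTransform(_rz(rng.uniform(0, 360)), rng.normal(0, 10, 3))
            g0 = guidance_parameters(pose, target)
            g1 = guidance_parameters(apply_transform(pose, t), apply_transform(target, t))
            assert g1.alpha_deg == pytest.approx(g0.alpha_deg, abs=1e-6)


@given(a=st.floats(-1e4, 1e4, allow_nan=False))
def test_angle_normalization_half_open_interval(a):
    r = normalize_angle_deg(a)
    assert -180 < r <= 180
    assert math.isclose(
        math.cos(math.radians(a)), math.cos(math.radians(r)), abs_tol=1e-9
    )
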