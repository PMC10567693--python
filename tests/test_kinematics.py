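"""Unit and property tests for frames, angles, events and differentiation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from pitchload import kinematics as K
from pitchload.kinematics import (
    EventSet,
    GapError,
    JointAngleSeries,
    KinematicsError,
    MarkerTrial,
    build_segment_frames,
    compose_yxy,
    compose_zxy,
    detect_mer,
    differentiate,
    euler_yxy,
    euler_zxy,
    fill_gaps,
    joint_angles,
    mirror_trial,
)

from conftest import (
    RATE,
    canonical_arm_pose,
    make_static_trial,
    random_rigid_pose,
)


# ---------------------------------------------------------------------------
# marker trial validation and gaps
# ---------------------------------------------------------------------------


class TestMarkerTrial:
    def test_validate_passes_on_canonical_pose(self):
        make_static_trial(canonical_arm_pose()).validate()

    def test_nonuniform_time_rejected(self):
        trial = make_static_trial(canonical_arm_pose())
        trial.time = trial.time**1.01
        with pytest.raises(KinematicsError, match="uniform"):
            trial.validate()

    def test_missing_landmark_rejected(self):
        trial = make_static_trial(canonical_arm_pose())
        del trial.landmarks["acromion"]
        with pytest.raises(KinematicsError, match="acromion"):
            trial.validate()

    def test_short_gap_interpolated(self):
        trial = make_static_trial(canonical_arm_pose(), n=40)
        trial.landmarks["acromion"][10:14] = np.nan
        filled = fill_gaps(trial)
        assert np.all(np.isfinite(filled.landmarks["acromion"]))
        np.testing.assert_allclose(
            filled.landmarks["acromion"] - trial.landmarks["acromion"][0],
            0.0,
            atol=1e-12,
        )

    def test_long_gap_invalidates(self):
        trial = make_static_trial(canonical_arm_pose(), n=40)
        trial.landmarks["acromion"][10:17] = np.nan
        with pytest.raises(GapError, match="acromion"):
            fill_gaps(trial)

    def test_boundary_gap_invalidates(self):
        trial = make_static_trial(canonical_arm_pose(), n=40)
        trial.landmarks["acromion"][:2] = np.nan
        with pytest.raises(GapError):
            fill_gaps(trial)


# ---------------------------------------------------------------------------
# segment frames
# ---------------------------------------------------------------------------


class TestSegmentFrames:
    def test_canonical_alignment(self):
        # styloid/epicondyle lines along global x, forearm long axis along
        # -y (wrist below elbow): the forearm basis must be the global basis
        # up to the package's signed axis permutation (y longitudinal,
        # z radial, x = y cross z)
        ulna = np.array([0.0, 0.0, 1.0])
        elbow = ulna + np.array([0.0, 0.27, 0.0])
        pose = {
            "ulna_styloid": ulna,
            "radius_styloid": ulna + np.array([0.05, 0.0, 0.0]),
            "lateral_humeral_epicondyle": elbow + np.array([0.035, 0.0, 0.0]),
            "medial_humeral_epicondyle": elbow - np.array([0.035, 0.0, 0.0]),
            "acromion": elbow + np.array([0.02, 0.33, 0.02]),
            "third_proximal_interphalangeal": ulna
            + np.array([0.025, -0.20, 0.0]),
        }
        from conftest import TRUNK_BASE

        pose.update(TRUNK_BASE)
        frames = build_segment_frames(make_static_trial(pose))
        expected = np.array(
            [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]]
        )  # columns: x = -Z, y = +Y, z = +X
        np.testing.assert_allclose(frames.bases["forearm"][0], expected, atol=1e-9)

    def test_orthonormal_right_handed_on_random_poses(self, rng):
        for _ in range(25):
            frames = build_segment_frames(make_static_trial(random_rigid_pose(rng)))
            for basis in frames.bases.values():
                rtr = np.transpose(basis, (0, 2, 1)) @ basis
                assert np.abs(rtr - np.eye(3)).max() < 1e-9
                assert np.allclose(np.linalg.det(basis), 1.0)

    def test_rigid_rotation_equivariance(self, rng):
        pose = canonical_arm_pose()
        q = Rotation.random(rng=rng).as_matrix()
        rotated = {k: q @ v for k, v in pose.items()}
        f0 = build_segment_frames(make_static_trial(pose))
        f1 = build_segment_frames(make_static_trial(rotated))
        for seg in f0.bases:
            np.testing.assert_allclose(
                f1.bases[seg][0], q @ f0.bases[seg][0], atol=1e-9
            )

    def test_mirrored_left_trial_matches_right(self):
        right = make_static_trial(canonical_arm_pose())
        left = mirror_trial(right)
        assert left.handedness == "left"
        f_r = build_segment_frames(right)
        f_l = build_segment_frames(left)  # mirrored back internally
        for seg in f_r.bases:
            np.testing.assert_allclose(f_l.bases[seg], f_r.bases[seg], atol=1e-12)

    def test_collinear_landmarks_rejected(self):
        pose = canonical_arm_pose()
        # collapse the epicondyle line onto the upper-arm long axis
        axis = pose["acromion"] - 0.5 * (
            pose["lateral_humeral_epicondyle"] + pose["medial_humeral_epicondyle"]
        )
        centre = 0.5 * (
            pose["lateral_humeral_epicondyle"] + pose["medial_humeral_epicondyle"]
        )
        pose["lateral_humeral_epicondyle"] = centre + 1e-12 * axis
        pose["medial_humeral_epicondyle"] = centre - 1e-12 * axis
        with pytest.raises(KinematicsError, match="upper_arm"):
            build_segment_frames(make_static_trial(pose))


# ---------------------------------------------------------------------------
# rotation decompositions
# ---------------------------------------------------------------------------


class TestDecompositions:
    def test_identity_gives_zero_angles(self):
        np.testing.assert_allclose(euler_zxy(np.eye(3)), 0.0, atol=1e-12)

    def test_pure_flexion(self):
        r = compose_zxy(1.0, 0.0, 0.0)
        np.testing.assert_allclose(euler_zxy(r), [1.0, 0.0, 0.0], atol=1e-12)

    def test_round_trip_example(self):
        angles = (0.3, 0.2, -0.5)
        np.testing.assert_allclose(
            euler_zxy(compose_zxy(*angles)), angles, atol=1e-10
        )

    def test_zxy_matches_scipy(self, rng):
        for _ in range(200):
            a, b, c = rng.uniform(-1.3, 1.3, 3)
            r = compose_zxy(a, b, c)
            ref = Rotation.from_matrix(r).as_euler("ZXY")
            np.testing.assert_allclose(euler_zxy(r), ref, atol=1e-10)

    def test_yxy_matches_scipy(self, rng):
        for _ in range(200):
            a, c = rng.uniform(-np.pi, np.pi, 2)
            b = rng.uniform(0.1, np.pi - 0.1)
            r = compose_yxy(a, b, c)
            ref = Rotation.from_matrix(r).as_euler("YXY")
            np.testing.assert_allclose(euler_yxy(r), ref, atol=1e-10)

    @given(
        a=st.floats(-1.4, 1.4),
        b=st.floats(-1.4, 1.4),
        c=st.floats(-1.4, 1.4),
    )
    @settings(max_examples=200, deadline=None)
    def test_zxy_round_trip_property(self, a, b, c):
        np.testing.assert_allclose(
            euler_zxy(compose_zxy(a, b, c)), (a, b, c), atol=1e-9
        )

    @given(
        a=st.floats(-3.0, 3.0),
        b=st.floats(0.05, np.pi - 0.05),
        c=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_yxy_round_trip_property(self, a, b, c):
        np.testing.assert_allclose(
            euler_yxy(compose_yxy(a, b, c)), (a, b, c), atol=1e-9
        )


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------


def _angles_for_pose(pose):
    return joint_angles(build_segment_frames(make_static_trial(pose)))


class TestJointAngles:
    def test_floating_axis_orthogonality(self, rng):
        for _ in range(10):
            frames = build_segment_frames(make_static_trial(random_rigid_pose(rng)))
            e1 = frames.bases["upper_arm"][:, :, 2]
            e3 = frames.bases["forearm"][:, :, 1]
            e2 = np.cross(e3, e1)
            e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
            assert np.abs(np.sum(e2 * e1, axis=1)).max() < 1e-12
            assert np.abs(np.sum(e2 * e3, axis=1)).max() < 1e-12

    def test_elbow_decomposition_matches_frame_euler(self, rng):
        # the geometric floating-axis construction must agree with the
        # algebraic z-x-y factorization of the relative rotation
        for _ in range(20):
            frames = build_segment_frames(make_static_trial(random_rigid_pose(rng)))
            r_rel = (
                np.transpose(frames.bases["upper_arm"], (0, 2, 1))
                @ frames.bases["forearm"]
            )
            expected = euler_zxy(r_rel[0])
            got = joint_angles(frames).elbow[0]
            np.testing.assert_allclose(
                np.unwrap(got - expected), 0.0, atol=1e-9
            )

    def test_rigid_motion_invariance(self, rng):
        pose = canonical_arm_pose()
        q = Rotation.random(rng=rng).as_matrix()
        tr = rng.uniform(-1, 1, 3)
        moved = {k: q @ v + tr for k, v in pose.items()}
        a0 = _angles_for_pose(pose)
        a1 = _angles_for_pose(moved)
        np.testing.assert_allclose(a1.elbow, a0.elbow, atol=1e-9)
        np.testing.assert_allclose(a1.shoulder, a0.shoulder, atol=1e-9)


# ---------------------------------------------------------------------------
# MER detection
# ---------------------------------------------------------------------------


def _angle_series(axial, rate=RATE):
    n = axial.size
    t = np.arange(n) / rate
    zeros = np.zeros((n, 3))
    shoulder = zeros.copy()
    shoulder[:, 2] = axial
    return JointAngleSeries(time=t, elbow=zeros, shoulder=shoulder)


class TestDetectMer:
    def test_parabolic_minimum(self):
        t = np.arange(121) / RATE
        axial = (t - 0.5) ** 2  # external rotation = minimum
        ev = detect_mer(_angle_series(axial))
        assert abs(ev.mer_time - 0.5) <= 1.0 / RATE

    def test_tie_takes_earliest(self):
        axial = np.zeros(100)
        axial[40] = axial[41] = -1.0
        ev = detect_mer(_angle_series(axial))
        assert ev.mer_index == 40

    def test_boundary_extremum_warns_and_flags(self):
        axial = np.linspace(0.0, -1.0, 50)
        with pytest.warns(UserWarning, match="boundary"):
            ev = detect_mer(_angle_series(axial))
        assert "mer_on_boundary" in ev.flags

    def test_events_within_bounds(self):
        ev = detect_mer(_angle_series(np.cos(np.linspace(0, 6, 200))))
        assert isinstance(ev, EventSet)
        assert 0 <= ev.mer_index < 200


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


class TestDifferentiate:
    def test_quadratic_position_exact_acceleration(self):
        t = np.arange(60) / RATE
        pos = np.stack([t**2, np.zeros_like(t), np.zeros_like(t)], axis=1)
        acc = differentiate(pos, RATE, order=2)
        np.testing.assert_allclose(acc[2:-2], [[2.0, 0.0, 0.0]] * 56, atol=1e-6)

    def test_constant_series_zero_derivative(self):
        out = differentiate(np.full(50, 3.3), RATE, order=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_second_derivative_truncation_bound(self):
        f = 5.0
        t = np.arange(240) / RATE
        x = np.sin(2 * np.pi * f * t)
        d2 = differentiate(x, RATE, order=2)
        exact = -((2 * np.pi * f) ** 2) * np.sin(2 * np.pi * f * t)
        # iterated central differences span a 2*dt stencil, so the leading
        # truncation term is (2 pi f)^4 (2 dt)^2 / 12 = (2 pi f)^4 dt^2 / 3
        bound = (2 * np.pi * f) ** 4 * (1.0 / RATE) ** 2 / 3.0
        assert np.abs(d2[4:-4] - exact[4:-4]).max() < bound

    def test_too_short_series_rejected(self):
        with pytest.raises(KinematicsError):
            differentiate(np.ones(2), RATE)

    def test_angular_velocity_constant_rate_rotation(self):
        w_true = np.array([0.0, 0.0, 2.0])
        t = np.arange(120) / RATE
        basis = np.stack(
            [Rotation.from_rotvec(w_true * ti).as_matrix() for ti in t]
        )
        w = K.angular_velocity(basis, RATE)
        np.testing.assert_allclose(w[2:-2] - w_true, 0.0, atol=1e-3)
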