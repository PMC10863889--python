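"""Filtering, pose estimation, Cardan angles and derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from footmech.errors import DegenerateGeometryError, ParameterError
from footmech.rigid_body import (
    angular_velocity,
    butter_zero_lag,
    cardan_zxy_compose,
    cardan_zxy_decompose,
    estimate_pose,
    estimate_pose_series,
    relative_joint_rotation,
    residual_cutoff,
)

from conftest import random_rotations


def reference_procrustes(ref, obs, weights=None):
    """Independent Kabsch solution, written separately from the package."""
    ref = np.asarray(ref, float)
    obs = np.asarray(obs, float)
    w = np.full(len(ref), 1.0 / len(ref)) if weights is None else np.asarray(weights, float) / np.sum(weights)
    rc = (w[:, None] * ref).sum(0)
    oc = (w[:, None] * obs).sum(0)
    H = np.zeros((3, 3))
    for i in range(len(ref)):
        H += w[i] * np.outer(ref[i] - rc, obs[i] - oc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, oc - R @ rc


def measure_sine_gain(freq, cutoff, rate=1000.0, duration=20.0):
    t = np.arange(0, duration, 1.0 / rate)
    x = np.sin(2 * np.pi * freq * t)
    y = butter_zero_lag(x, cutoff, rate)
    core = slice(len(t) // 4, 3 * len(t) // 4)  # away from edges
    return np.abs(y[core]).max()


class TestButterZeroLag:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        assert np.allclose(butter_zero_lag(x, 10.0, 150.0), x, atol=1e-9)

    def test_two_pass_gain_at_cutoff_is_half(self):
        gain = measure_sine_gain(10.0, 10.0)
        assert abs(gain - 0.5) < 0.01  # 0.5 within 2%

    def test_passband_preserved_well_below_cutoff(self):
        gain = measure_sine_gain(0.5, 10.0)
        assert abs(gain - 1.0) < 0.005

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 400))
        lhs = butter_zero_lag(2 * a + 3 * b, 8.0, 150.0)
        rhs = 2 * butter_zero_lag(a, 8.0, 150.0) + 3 * butter_zero_lag(b, 8.0, 150.0)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            butter_zero_lag(np.zeros(100), 75.0, 150.0)

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError):
            butter_zero_lag(np.zeros(5), 10.0, 150.0)


class TestResidualCutoff:
    def test_noisy_sine_selects_low_cutoff(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 4, 1 / 150)
        x = np.sin(2 * np.pi * 2 * t) + rng.normal(0, 0.05, t.shape)
        assert 2.0 <= residual_cutoff(x, 150.0) <= 8.0

    def test_clean_sine_selects_lowest_passing_candidate(self):
        t = np.arange(0, 4, 1 / 150)
        fc = residual_cutoff(np.sin(2 * np.pi * 2 * t), 150.0)
        assert fc >= 2.0
        # brute-force check: it is the lowest candidate within tolerance
        cands = np.arange(1.0, 0.9 * 75, 0.5)
        res = np.array([np.sqrt(np.mean((np.sin(2 * np.pi * 2 * t)
                                         - butter_zero_lag(np.sin(2 * np.pi * 2 * t), c, 150.0)) ** 2))
                        for c in cands])
        rms = np.sqrt(np.mean(np.sin(2 * np.pi * 2 * t) ** 2))
        expected = cands[np.argmax(res <= 0.01 * rms)]
        assert fc == expected

    def test_pure_noise_returns_sentinel_with_warning(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="noise-dominated"):
            fc = residual_cutoff(rng.standard_normal(600), 150.0)
        assert fc == pytest.approx(67.0)


class TestPoseEstimation:
    def test_identity(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 0.9]])
        R, t = estimate_pose(ref, ref)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)

    def test_exact_rotation_recovered(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        Ry = np.array([[0, 0, 1], [0, 1, 0], [-1, 0, 0]], float)  # 90 deg about y
        R, t = estimate_pose(ref, ref @ Ry.T + 0.5)
        assert np.abs(R - Ry).max() < 1e-12
        assert np.allclose(t, 0.5, atol=1e-12)

    def test_matches_independent_oracle_under_noise(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 0.05, (6, 3))
        R0 = random_rotations(rng, 1)[0]
        obs = ref @ R0.T + np.array([0.1, 0.2, 0.3]) + rng.normal(0, 0.001, (6, 3))
        R, t = estimate_pose(ref, obs)
        Ro, to = reference_procrustes(ref, obs)
        assert np.abs(R - Ro).max() < 1e-12
        assert np.abs(t - to).max() < 1e-12
        # orientation error below 1 degree at 1 mm noise
        ang = np.arccos(np.clip((np.trace(R.T @ R0) - 1) / 2, -1, 1))
        assert np.degrees(ang) < 1.0

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_series_estimator_matches_scalar(self, n):
        rng = np.random.default_rng(n)
        ref = rng.normal(0, 0.05, (n, 3))
        Rs = random_rotations(rng, 20)
        obs = np.einsum("tij,nj->tni", Rs, ref) + rng.normal(0, 0.002, (20, n, 3))
        R_ser, t_ser = estimate_pose_series(ref, obs)
        for k in range(20):
            Rk, tk = estimate_pose(ref, obs[k])
            assert np.abs(R_ser[k] - Rk).max() < 1e-12
            assert np.abs(t_ser[k] - tk).max() < 1e-12

    def test_collinear_cluster_rejected(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            estimate_pose(ref, ref)

    def test_reflection_never_returned(self):
        # an obs set that is a mirror image of ref still yields det(R) = +1
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        obs = ref * np.array([1, 1, -1])
        R, _ = estimate_pose(ref, obs)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)


class TestCardan:
    def test_identity(self):
        assert np.allclose(cardan_zxy_decompose(np.eye(3)), 0.0, atol=1e-12)

    def test_single_axis_flexion(self):
        R = cardan_zxy_compose([30.0, 0.0, 0.0])
        ang = cardan_zxy_decompose(R)
        assert np.allclose(ang, [30.0, 0.0, 0.0], atol=1e-12)

    def test_round_trip_seeded(self):
        rng = np.random.default_rng(7)
        ang = np.stack([rng.uniform(-179, 179, 1000),
                        rng.uniform(-85, 85, 1000),
                        rng.uniform(-179, 179, 1000)], axis=1)
        R = cardan_zxy_compose(ang)
        R2 = cardan_zxy_compose(cardan_zxy_decompose(R))
        assert np.abs(R - R2).max() < 1e-10

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(g=st.floats(-179, 179), a=st.floats(-85, 85), b=st.floats(-179, 179))
    def test_round_trip_property(self, g, a, b):
        R = cardan_zxy_compose([g, a, b])
        ang = cardan_zxy_decompose(R)
        assert np.allclose(ang, [g, a, b], atol=1e-8)

    def test_gimbal_lock_warns(self):
        R = cardan_zxy_compose([10.0, 90.0, 0.0])
        with pytest.warns(UserWarning, match="gimbal"):
            cardan_zxy_decompose(R)


class TestRelativeRotation:
    def test_neutral_is_identity(self):
        rng = np.random.default_rng(11)
        A, B = random_rotations(rng, 2)
        rel = relative_joint_rotation(A[None], B[None], A, B)
        assert np.abs(rel[0] - np.eye(3)).max() < 1e-12

    def test_single_axis_beyond_neutral(self):
        A = np.eye(3)
        Rz10 = cardan_zxy_compose([10.0, 0, 0])
        rel = relative_joint_rotation(A[None], (A @ Rz10)[None], A, A)
        assert np.allclose(cardan_zxy_decompose(rel[0]), [10.0, 0, 0], atol=1e-10)

    def test_common_rotation_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            P, D, P0, D0, C = random_rotations(rng, 5)
            rel = relative_joint_rotation(P[None], D[None], P0, D0)
            rel_c = relative_joint_rotation((C @ P)[None], (C @ D)[None], P0, D0)
            assert np.abs(rel - rel_c).max() < 1e-12


class TestAngularVelocity:
    def test_constant_pose_zero(self):
        R = np.repeat(np.eye(3)[None], 10, axis=0)
        assert np.abs(angular_velocity(R, 150.0)).max() == 0.0

    def test_constant_rate_rotation_about_z(self):
        t = np.arange(0, 1, 1 / 150)
        R = cardan_zxy_compose(np.stack([np.degrees(t), 0 * t, 0 * t], axis=1))
        w = angular_velocity(R, 150.0)
        assert np.abs(w[1:-1] - [0, 0, 1.0]).max() < 1e-4

    def test_identical_motion_zero_relative(self):
        # proximal and distal segments spinning identically -> relative
        # angular velocity (dist - prox) vanishes
        rng = np.random.default_rng(17)
        ang = np.cumsum(rng.normal(0, 0.1, (50, 3)), axis=0)
        w_prox = angular_velocity(cardan_zxy_compose(ang), 150.0)
        w_dist = angular_velocity(cardan_zxy_compose(ang.copy()), 150.0)
        assert np.abs(w_dist - w_prox).max() < 1e-12
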