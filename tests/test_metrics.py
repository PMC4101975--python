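"""Alignment angles, rigid registration, target error, membrane error, depth."""
import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from cochleoplan import (
    alignment_angles,
    angular_insertion_depth,
    membrane_plane_error,
    register_fiducials,
    target_error,
)
from cochleoplan.errors import EvaluationError, RegistrationError

from conftest import random_rotation

ANCHOR = np.array([3.0, 0.5, -0.4])  # off-axis anchor in the basal turn
U_INPLANE = np.array([-0.5 / np.linalg.norm([0.5, 3.0]), 3.0 / np.linalg.norm([0.5, 3.0]), 0.0])


class TestAlignmentAngles:
    def test_identical_directions_give_zero(self, axis_aligned_frame):
        ang = alignment_angles(U_INPLANE, U_INPLANE, axis_aligned_frame, ANCHOR)
        assert ang.delta == pytest.approx(0.0, abs=1e-12)
        assert ang.epsilon == pytest.approx(0.0, abs=1e-12)

    def test_tilt_below_membrane_plane_is_positive_delta(self, axis_aligned_frame):
        # rotate u by 10 deg toward -z about the in-plane normal
        u = U_INPLANE
        v = np.cos(np.radians(10)) * u + np.sin(np.radians(10)) * np.array([0, 0, -1.0])
        ang = alignment_angles(v, u, axis_aligned_frame, ANCHOR)
        assert ang.delta == pytest.approx(10.0, abs=1e-9)
        assert ang.epsilon == pytest.approx(0.0, abs=1e-9)

    def test_inplane_rotation_toward_modiolus_is_negative_epsilon(self, axis_aligned_frame):
        u = np.array([0.0, 1.0, 0.0])
        anchor = np.array([3.0, 0.0, -0.4])  # radial direction is +x here
        c, s = np.cos(np.radians(5)), np.sin(np.radians(5))
        v = np.array([-s, c, 0.0])  # 5 deg toward -x (the modiolus)
        ang = alignment_angles(v, u, axis_aligned_frame, anchor)
        assert ang.delta == pytest.approx(0.0, abs=1e-9)
        assert ang.epsilon == pytest.approx(-5.0, abs=1e-9)

    def test_trajectory_parallel_to_z_raises(self, axis_aligned_frame):
        with pytest.raises(EvaluationError, match="parallel to the z-axis"):
            alignment_angles([0, 0, -1.0], U_INPLANE, axis_aligned_frame, ANCHOR)

    def test_invariance_under_rigid_transform(self, axis_aligned_frame):
        from cochleoplan import LandmarkSet, build_cochlear_frame

        rng = np.random.default_rng(23)
        q = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        u = U_INPLANE
        v = Rotation.from_rotvec(np.radians(7) * np.array([0, 0, 1.0])).apply(u)
        ref = alignment_angles(v, u, axis_aligned_frame, ANCHOR)
        lm_t = LandmarkSet(
            R=q @ [5, 0, 0] + t, C=q @ [0, 0, 0] + t, A=q @ [0, 0, 4] + t,
            I=q @ [4, 0, 0] + t, side="right",
        )
        frame_t = build_cochlear_frame(lm_t)
        moved = alignment_angles(q @ v, q @ u, frame_t, q @ ANCHOR + t)
        assert moved.delta == pytest.approx(ref.delta, abs=1e-9)
        assert moved.epsilon == pytest.approx(ref.epsilon, abs=1e-9)


class TestRegistration:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (5, 3))
        tr = register_fiducials(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)
        assert tr.fre == pytest.approx(0.0, abs=1e-12)

    def test_exact_recovery_of_random_transforms(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pts = rng.uniform(-10, 10, (6, 3))
            q = random_rotation(rng)
            t = rng.uniform(-20, 20, 3)
            tr = register_fiducials(pts, pts @ q.T + t)
            assert np.max(np.abs(tr.rotation - q)) < 1e-9
            assert np.max(np.abs(tr.translation - t)) < 1e-9
            assert tr.fre < 1e-9

    def test_matches_scipy_kabsch(self):
        """Independent cross-check against scipy's Kabsch implementation."""
        rng = np.random.default_rng(2)
        moving = rng.uniform(-10, 10, (8, 3))
        fixed = moving @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
        fixed += rng.normal(scale=0.2, size=fixed.shape)
        tr = register_fiducials(moving, fixed)
        rot_ref, _ = Rotation.align_vectors(
            fixed - fixed.mean(axis=0), moving - moving.mean(axis=0)
        )
        assert np.max(np.abs(tr.rotation - rot_ref.as_matrix())) < 1e-9

    def test_noisy_fre_within_expected_band(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-30, 30, (6, 3))
        fres = []
        for _ in range(100):
            q = random_rotation(rng)
            t = rng.uniform(-10, 10, 3)
            noisy = base @ q.T + t + rng.normal(scale=0.1, size=base.shape)
            fres.append(register_fiducials(base, noisy).fre)
        assert 0.03 <= min(fres) and max(fres) <= 0.2

    def test_rotation_stays_proper_under_reflection_prone_noise(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(-5, 5, (4, 3))
        mirrored = base * np.array([1.0, 1.0, -1.0]) + rng.normal(scale=0.3, size=base.shape)
        tr = register_fiducials(base, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 10, (5, 3))
        tr = register_fiducials(pts, pts @ random_rotation(rng).T + [1, 2, 3])
        back = tr.inverse().apply(tr.apply(pts))
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_too_few_or_collinear_pairs_raise(self):
        with pytest.raises(RegistrationError, match=">= 3"):
            register_fiducials([[0, 0, 0], [1, 0, 0]], [[0, 0, 0], [1, 0, 0]])
        line = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError, match="collinear"):
            register_fiducials(line, line)


class TestTargetError:
    def test_axis_through_target_is_zero(self):
        assert target_error([1, 2, 3.0], [1, 2, 3.0], [0, 0, 1.0]) == pytest.approx(0.0)

    def test_parallel_offset(self):
        err = target_error([0.3, 0, 0.0], [0, 0, -5.0], [0, 0, 1.0])
        assert err == pytest.approx(0.30, abs=1e-12)

    def test_matches_1d_minimization_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            p = rng.uniform(-10, 10, 3)
            a = rng.uniform(-10, 10, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            res = minimize_scalar(lambda s: np.linalg.norm(p - (a + s * d)))
            assert target_error(p, a, d) == pytest.approx(res.fun, abs=1e-7)

    def test_zero_direction_raises(self):
        with pytest.raises(EvaluationError, match="zero length"):
            target_error([1, 2, 3.0], [0, 0, 0.0], [0, 0, 0.0])


class TestMembranePlaneError:
    @staticmethod
    def _tilted_membrane(tilt_deg, n=20000, seed=0):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, np.pi, n)
        rho = 3.0
        x, y = rho * np.cos(theta), rho * np.sin(theta)
        return np.stack([x, y, x * np.tan(np.radians(tilt_deg))], axis=1)

    def test_flat_membrane_gives_zero(self):
        pts = self._tilted_membrane(0.0)
        prof = membrane_plane_error(pts)
        assert prof.window_mean == 0.0
        assert np.all(prof.bin_mean_abs_z == 0.0)

    def test_tilted_membrane_matches_integral_oracle(self):
        pts = self._tilted_membrane(2.0, n=400000, seed=1)
        prof = membrane_plane_error(pts, theta_window=(45.0, 60.0))
        # closed form: mean of |rho cos(theta) tan(2 deg)| over theta in [45, 60] deg
        lo, hi = np.radians(45), np.radians(60)
        expected = 3.0 * np.tan(np.radians(2.0)) * (np.sin(hi) - np.sin(lo)) / (hi - lo)
        assert prof.window_mean == pytest.approx(expected, rel=0.01)

    def test_profile_monotone_in_tilt(self):
        means = [
            membrane_plane_error(self._tilted_membrane(t, seed=2)).window_mean
            for t in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_empty_window_raises(self):
        pts = self._tilted_membrane(1.0)
        pts = pts[(np.degrees(np.arctan2(pts[:, 1], pts[:, 0])) % 360) > 90]
        with pytest.raises(EvaluationError, match="window"):
            membrane_plane_error(pts, theta_window=(0.0, 5.0))

    def test_phantom_truth_membrane_error_is_zero(self, default_recovery):
        rep = default_recovery
        local = rep.frame.world_to_local(rep.phantom.truth.membrane_points)
        prof = membrane_plane_error(local)
        assert prof.window_mean < 1e-12
        assert np.max(prof.bin_mean_abs_z) < 1e-12


class TestAngularInsertionDepth:
    @staticmethod
    def _contacts(angles_deg, radius=2.0):
        phi = np.radians(np.asarray(angles_deg, dtype=float))
        return np.stack(
            [radius * np.cos(phi), radius * np.sin(phi), -0.2 * np.ones_like(phi)], axis=1
        )

    def test_no_wrap(self, axis_aligned_frame):
        depth = angular_insertion_depth(self._contacts([10, 90, 200, 310]), axis_aligned_frame)
        assert depth == pytest.approx(310.0)

    def test_single_wrap(self, axis_aligned_frame):
        depth = angular_insertion_depth(self._contacts([300, 350, 30]), axis_aligned_frame)
        assert depth == pytest.approx(390.0)

    def test_single_contact(self, axis_aligned_frame):
        depth = angular_insertion_depth(self._contacts([45]), axis_aligned_frame)
        assert depth == pytest.approx(45.0)

    def test_multi_turn(self, axis_aligned_frame):
        depth = angular_insertion_depth(
            self._contacts([10, 120, 240, 0, 120, 240, 0, 60]), axis_aligned_frame
        )
        assert depth == pytest.approx(780.0)

    def test_contact_on_axis_raises(self, axis_aligned_frame):
        with pytest.raises(Exception, match="z-axis"):
            angular_insertion_depth(np.array([[0.0, 0.0, 1.0]]), axis_aligned_frame)

    def test_empty_contacts_raise(self, axis_aligned_frame):
        with pytest.raises(EvaluationError, match="contacts"):
            angular_insertion_depth(np.empty((0, 3)), axis_aligned_frame)
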