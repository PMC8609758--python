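"""Rigid landmark registration: exact recovery, robustness and I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from guidedev.core_geometry import BurPose, measure_deviations
from guidedev.exceptions import (
    CorrespondenceError,
    DegenerateLandmarksError,
    InsufficientLandmarksError,
)
from guidedev.registration import (
    LandmarkSet,
    RigidTransform,
    apply_transform,
    compose,
    fit_rigid,
    invert,
    load_transform_json,
    load_transform_text,
    read_fcsv,
    save_transform_json,
    save_transform_text,
    write_fcsv,
)


def _random_transform(rng, scale=1.0):
    R = Rotation.from_rotvec(rng.uniform(0, np.pi) * _unit(rng.normal(size=3))).as_matrix()
    return RigidTransform(R, rng.uniform(-30, 30, 3), scale)


def _unit(v):
    return v / np.linalg.norm(v)


def _random_landmarks(rng, n=6, frame="pre"):
    labels = tuple(f"L{i}" for i in range(n))
    return LandmarkSet(labels, rng.uniform(-40, 40, (n, 3)), frame)


def _rotation_angle_deg(R1, R2):
    # arcsin form: numerically exact near zero, unlike arccos of the trace
    return np.degrees(2 * np.arcsin(min(np.linalg.norm(R1 - R2) / (2 * np.sqrt(2)), 1.0)))


class TestFitRigid:
    def test_identity_on_identical_frames(self, rng):
        ls = _random_landmarks(rng)
        rep = fit_rigid(ls, ls)
        assert np.allclose(rep.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(rep.transform.translation, 0, atol=1e-12)
        assert rep.fre_mm < 1e-12

    @given(seed=st.integers(0, 5_000))
    def test_exact_recovery_of_generating_transform(self, seed):
        rng = np.random.default_rng(seed)
        fixed = _random_landmarks(rng, n=4)
        T = _random_transform(rng)
        moving = LandmarkSet(fixed.labels, invert(T).apply_points(fixed.points), "post")
        rep = fit_rigid(moving, fixed)
        assert _rotation_angle_deg(rep.transform.rotation, T.rotation) < 1e-7
        assert np.linalg.norm(rep.transform.translation - T.translation) < 1e-7
        assert rep.fre_mm < 1e-9

    def test_reflection_is_rejected(self, rng):
        fixed = _random_landmarks(rng, n=4)
        mirrored = fixed.points * np.array([-1.0, 1.0, 1.0])
        rep = fit_rigid(LandmarkSet(fixed.labels, mirrored, "m"), fixed)
        assert np.linalg.det(rep.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rep.fre_mm > 0.1

    def test_correspondence_by_label_not_order(self, rng):
        fixed = _random_landmarks(rng)
        T = _random_transform(rng)
        moving_pts = invert(T).apply_points(fixed.points)
        perm = rng.permutation(len(fixed))
        moving = LandmarkSet(tuple(fixed.labels[i] for i in perm), moving_pts[perm], "post")
        rep = fit_rigid(moving, fixed)
        assert rep.fre_mm < 1e-9

    def test_fre_is_rms_of_residuals(self, rng):
        fixed = _random_landmarks(rng)
        noisy = LandmarkSet(fixed.labels, fixed.points + rng.normal(0, 0.3, fixed.points.shape), "n")
        rep = fit_rigid(noisy, fixed)
        assert rep.fre_mm == pytest.approx(np.sqrt(np.mean(rep.residuals_mm**2)), rel=1e-12)

    def test_insufficient_landmarks(self, rng):
        ls = _random_landmarks(rng, n=2)
        with pytest.raises(InsufficientLandmarksError):
            fit_rigid(ls, ls)

    def test_collinear_landmarks(self):
        pts = np.outer(np.arange(4, dtype=float), [1.0, 2.0, 3.0])
        ls = LandmarkSet(("a", "b", "c", "d"), pts, "x")
        with pytest.raises(DegenerateLandmarksError):
            fit_rigid(ls, ls)

    def test_label_mismatch(self, rng):
        a = _random_landmarks(rng)
        b = LandmarkSet(tuple(f"M{i}" for i in range(6)), a.points, "y")
        with pytest.raises(CorrespondenceError):
            fit_rigid(a, b)

    def test_similarity_fit_recovers_scale(self, rng):
        fixed = _random_landmarks(rng)
        T = _random_transform(rng, scale=1.37)
        moving = LandmarkSet(fixed.labels, invert(T).apply_points(fixed.points), "post")
        rep = fit_rigid(moving, fixed, allow_scale=True)
        assert rep.transform.scale == pytest.approx(1.37, rel=1e-9)
        assert rep.fre_mm < 1e-9

    def test_fre_increases_with_landmark_noise(self):
        # E[FRE] must be monotone in the localisation noise sd
        rng = np.random.default_rng(0)
        sigmas = [0.02, 0.05, 0.1, 0.2, 0.5]
        means = []
        fixed = _random_landmarks(rng)
        for sigma in sigmas:
            fres = []
            for _ in range(200):
                noisy = LandmarkSet(
                    fixed.labels, fixed.points + rng.normal(0, sigma, fixed.points.shape), "n"
                )
                fres.append(fit_rigid(noisy, fixed).fre_mm)
            means.append(np.mean(fres))
        rho, _ = spearmanr(sigmas, means)
        assert rho > 0.9


class TestTransformAlgebra:
    @given(seed=st.integers(0, 5_000))
    def test_inverse_round_trip_on_pose(self, seed):
        rng = np.random.default_rng(seed)
        T = _random_transform(rng)
        p = BurPose(rng.uniform(-20, 20, 3), rng.uniform(-20, 20, 3) + [0, 0, 30])
        q = apply_transform(invert(T), apply_transform(T, p))
        assert np.allclose(q.base, p.base, atol=1e-9)
        assert np.allclose(q.tip, p.tip, atol=1e-9)

    def test_length_preserved(self, rng):
        T = _random_transform(rng)
        p = BurPose([0, 0, 0], [0, 0, 16])
        assert apply_transform(T, p).length == pytest.approx(16.0, abs=1e-9)

    def test_identity_neutral(self, rng):
        T = _random_transform(rng)
        I = RigidTransform.identity()
        assert np.allclose(compose(I, T).as_matrix(), T.as_matrix(), atol=1e-12)
        assert np.allclose(compose(T, invert(T)).as_matrix(), np.eye(4), atol=1e-9)

    @given(seed=st.integers(0, 5_000))
    def test_composition_associative(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C = (_random_transform(rng) for _ in range(3))
        left = compose(compose(A, B), C).as_matrix()
        right = compose(A, compose(B, C)).as_matrix()
        assert np.allclose(left, right, atol=1e-9)

    def test_compose_applies_first_argument_last(self, rng):
        # compose(T2, T1) maps x -> T2(T1(x))
        T1 = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        T2 = RigidTransform(Rotation.from_euler("z", 90, degrees=True).as_matrix(), [0.0, 0.0, 0.0])
        out = compose(T2, T1).apply_points(np.array([0.0, 0.0, 0.0]))
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-12)

    def test_svd_fit_agrees_with_scipy_align_vectors(self, rng):
        # independent cross-check of the closed-form orthogonal fit
        fixed = _random_landmarks(rng)
        noisy = LandmarkSet(fixed.labels, fixed.points + rng.normal(0, 0.2, fixed.points.shape), "n")
        rep = fit_rigid(noisy, fixed)
        F0 = fixed.points - fixed.points.mean(0)
        M0 = noisy.points - noisy.points.mean(0)
        R_ref, _ = Rotation.align_vectors(F0, M0)
        assert _rotation_angle_deg(rep.transform.rotation, R_ref.as_matrix()) < 1e-6


class TestEndToEndConsistency:
    def test_deviations_through_registration_match_direct(self, rng):
        """Measuring after registering a noiselessly transformed frame equals
        measuring in the common frame directly."""
        pre_landmarks = _random_landmarks(rng)
        T = _random_transform(rng)
        post_landmarks = LandmarkSet(pre_landmarks.labels, T.apply_points(pre_landmarks.points), "post")
        planned = BurPose([5, 5, 5], [5, 5, 21])
        actual_pre = BurPose([5.2, 5.1, 5], [5.4, 5.6, 20.9])
        direct = measure_deviations(planned, actual_pre)
        rep = fit_rigid(moving=post_landmarks, fixed=pre_landmarks)
        recovered = rep.transform.apply_pose(apply_transform(T, actual_pre))
        via_reg = measure_deviations(planned, recovered)
        assert via_reg.coronal_mm == pytest.approx(direct.coronal_mm, abs=1e-9)
        assert via_reg.apical_mm == pytest.approx(direct.apical_mm, abs=1e-9)
        assert via_reg.angular_deg == pytest.approx(direct.angular_deg, abs=1e-9)


class TestLandmarkIO:
    def test_fcsv_round_trip(self, tmp_path, rng):
        ls = _random_landmarks(rng)
        path = tmp_path / "frame.fcsv"
        write_fcsv(ls, path)
        back = read_fcsv(path)
        assert back.labels == ls.labels
        np.testing.assert_array_equal(back.points, ls.points)

    def test_reads_slicer_style_file(self, tmp_path):
        text = (
            "# Markups fiducial file version = 4.11\n"
            "# CoordinateSystem = LPS\n"
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
            "F-1,1.5,-2.25,3.0,0,0,0,1,1,1,0,incisal_edge,,vtkMRMLScalarVolumeNode1\n"
            "F-2,4.0,5.0,6.5,0,0,0,1,1,1,0,mb_cusp,,\n"
        )
        p = tmp_path / "slicer.fcsv"
        p.write_text(text)
        ls = read_fcsv(p)
        assert ls.labels == ("incisal_edge", "mb_cusp")
        np.testing.assert_allclose(ls.points[0], [1.5, -2.25, 3.0])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LandmarkSet(("a", "a"), np.zeros((2, 3)), "x")

    def test_transform_text_and_json_round_trip(self, tmp_path, rng):
        T = _random_transform(rng)
        save_transform_text(T, tmp_path / "t.txt")
        save_transform_json(T, tmp_path / "t.json")
        for back in (load_transform_text(tmp_path / "t.txt"), load_transform_json(tmp_path / "t.json")):
            assert np.allclose(back.as_matrix(), T.as_matrix(), atol=1e-12)
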