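"""Landmark affine fitting and resampling into a common frame."""

import numpy as np
import pytest

from tumorburden.core import BinaryMask, ContractError, GridGeometry, ScalarVolume
from tumorburden.metrics import dice
from tumorburden.registration import (
    AffineTransform,
    LandmarkPairSet,
    apply_transform,
    fiducial_registration_error,
    fit_affine_landmarks,
    register_slice_stack,
)
from tumorburden.phantom import slice_and_perturb
from tumorburden.segmentation import SegmentationSpec, threshold_segment

from conftest import random_volume


def _normal_equations_fit(moving, fixed):
    """Independent oracle: solve the least-squares normal equations by
    explicit matrix inversion."""
    n, d = moving.shape
    design = np.hstack([moving, np.ones((n, 1))])
    coeffs = np.linalg.inv(design.T @ design) @ design.T @ fixed
    return coeffs[:d, :].T, coeffs[d, :]


class TestFitAffine:
    def test_identity_landmarks(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        t = fit_affine_landmarks(LandmarkPairSet(pts, pts))
        np.testing.assert_allclose(t.linear, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)
        assert fiducial_registration_error(LandmarkPairSet(pts, pts), t) < 1e-12

    def test_exact_interpolation_at_four_points(self):
        moving = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 1]], dtype=float)
        linear = np.diag([1.1, 1.1, 1.1])
        translation = np.array([2.0, -1.0, 0.5])
        fixed = moving @ linear.T + translation
        t = fit_affine_landmarks(LandmarkPairSet(moving, fixed))
        np.testing.assert_allclose(t.linear, linear, atol=1e-9)
        np.testing.assert_allclose(t.translation, translation, atol=1e-9)
        assert fiducial_registration_error(LandmarkPairSet(moving, fixed), t) < 1e-9

    def test_matches_normal_equations_oracle_under_jitter(self):
        rng = np.random.default_rng(10)
        moving = rng.uniform(-5, 5, size=(10, 3))
        linear = np.eye(3) + rng.uniform(-0.2, 0.2, size=(3, 3))
        translation = rng.uniform(-3, 3, size=3)
        fixed = moving @ linear.T + translation + rng.normal(0, 0.1, size=(10, 3))
        t = fit_affine_landmarks(LandmarkPairSet(moving, fixed))
        lin_o, tr_o = _normal_equations_fit(moving, fixed)
        np.testing.assert_allclose(t.linear, lin_o, atol=1e-9)
        np.testing.assert_allclose(t.translation, tr_o, atol=1e-9)

    def test_degenerate_configuration_reports_direction(self):
        # all moving points in the z=0 plane
        moving = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]], dtype=float)
        with pytest.raises(ContractError, match="deficient direction"):
            fit_affine_landmarks(LandmarkPairSet(moving, moving + 1.0))

    def test_too_few_pairs_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.raises(ContractError, match="at least 4"):
            LandmarkPairSet(pts, pts)

    def test_rigid_motion_invariance(self):
        """Applying one rigid motion to both frames conjugates the fit exactly."""
        rng = np.random.default_rng(11)
        moving = rng.uniform(-4, 4, size=(8, 3))
        fixed = moving @ (np.eye(3) * 1.05).T + [1.0, 2.0, -0.5] + rng.normal(0, 0.05, (8, 3))
        theta = 0.4
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        shift = np.array([3.0, -1.0, 2.0])
        rigid = AffineTransform(rot, shift)
        base = fit_affine_landmarks(LandmarkPairSet(moving, fixed))
        conj = fit_affine_landmarks(LandmarkPairSet(rigid.apply(moving), rigid.apply(fixed)))
        expected = rigid.compose(base).compose(rigid.inverse())
        np.testing.assert_allclose(conj.linear, expected.linear, atol=1e-9)
        np.testing.assert_allclose(conj.translation, expected.translation, atol=1e-9)

    def test_fre_shrinks_with_noise(self):
        rng = np.random.default_rng(12)
        moving = rng.uniform(-4, 4, size=(10, 3))
        linear, translation = np.eye(3) * 0.95, np.array([0.5, 0.5, -0.5])
        errs = []
        for sigma in (0.5, 0.1, 0.0):
            fixed = moving @ linear.T + translation + rng.normal(0, sigma, (10, 3))
            lm = LandmarkPairSet(moving, fixed)
            errs.append(fiducial_registration_error(lm, fit_affine_landmarks(lm)))
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 1e-9


class TestApplyTransform:
    def test_identity(self):
        rng = np.random.default_rng(13)
        vol = random_volume(rng, (5, 5, 5), (1, 1, 1))
        out = apply_transform(vol, AffineTransform.identity(3), vol.geometry)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_one_voxel_translation_shifts_lattice(self):
        rng = np.random.default_rng(14)
        vol = random_volume(rng, (5, 4, 3), (0.5, 1.0, 2.0))
        t = AffineTransform(np.eye(3), np.array([0.5, 0.0, 0.0]))  # +1 voxel along x
        out = apply_transform(vol, t, vol.geometry)
        np.testing.assert_array_equal(out.values[1:], vol.values[:-1])
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_pointwise_pullback_oracle(self):
        rng = np.random.default_rng(15)
        vol = random_volume(rng, (6, 6, 6), (1.0, 1.0, 1.5))
        linear = np.eye(3) + rng.uniform(-0.15, 0.15, (3, 3))
        t = AffineTransform(linear, rng.uniform(-1, 1, 3))
        out = apply_transform(vol, t, vol.geometry, interpolation="nearest")
        inv = t.inverse()
        probes = rng.integers(0, 6, size=(20, 3))
        for ijk in probes:
            world = vol.geometry.index_to_world(ijk.astype(float))
            src_idx = np.rint(vol.geometry.world_to_index(inv.apply(world))).astype(int)
            if np.all((src_idx >= 0) & (src_idx < 6)):
                expected = vol.values[tuple(src_idx)]
            else:
                expected = 0.0
            assert out.values[tuple(ijk)] == expected

    def test_mask_requires_nearest(self):
        geom = GridGeometry(shape=(3, 3, 3), spacing=(1, 1, 1))
        mask = BinaryMask(geometry=geom, values=np.ones((3, 3, 3), bool))
        with pytest.raises(ContractError, match="nearest"):
            apply_transform(mask, AffineTransform.identity(3), geom, interpolation="linear")

    def test_inverse_round_trip_interior(self):
        rng = np.random.default_rng(16)
        vol = random_volume(rng, (8, 8, 8), (1, 1, 1))
        t = AffineTransform(np.eye(3), np.array([1.0, 0.0, 0.0]))
        fwd = apply_transform(vol, t, vol.geometry)
        back = apply_transform(fwd, t.inverse(), vol.geometry)
        np.testing.assert_array_equal(back.values[2:-2, 2:-2, 2:-2], vol.values[2:-2, 2:-2, 2:-2])


class TestSliceStack:
    def _identity_landmarks(self, plane_geom):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        return LandmarkPairSet(pts, pts)

    def test_identity_per_slice(self):
        rng = np.random.default_rng(17)
        target = GridGeometry(shape=(8, 8, 4), spacing=(0.5, 0.5, 1.0))
        plane = GridGeometry(shape=(8, 8), spacing=(0.5, 0.5))
        slices = [ScalarVolume(geometry=plane, values=rng.random((8, 8))) for _ in range(4)]
        lms = [self._identity_landmarks(plane) for _ in range(4)]
        out = register_slice_stack(slices, lms, target)
        for k in range(4):
            np.testing.assert_array_equal(out.values[:, :, k], slices[k].values)

    def test_quarter_turn_recovered(self):
        n = 9
        plane = GridGeometry(shape=(n, n), spacing=(1.0, 1.0))
        target = GridGeometry(shape=(n, n, 1), spacing=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(18)
        original = rng.random((n, n))
        c = (n - 1) / 2.0
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        translation = np.array([c, c]) - rot @ np.array([c, c])
        t = AffineTransform(rot, translation)  # 90 degrees about the slice center
        rotated = apply_transform(ScalarVolume(geometry=plane, values=original), t, plane)
        fixed = np.array([[1.0, 1.0], [n - 2.0, 1.0], [1.0, n - 2.0], [n - 2.0, n - 2.0]])
        lm = LandmarkPairSet(t.apply(fixed), fixed)
        out = register_slice_stack([rotated], [lm], target)
        np.testing.assert_array_equal(out.values[1:-1, 1:-1, 0], original[1:-1, 1:-1])

    def test_count_mismatch_rejected(self):
        plane = GridGeometry(shape=(4, 4), spacing=(1, 1))
        target = GridGeometry(shape=(4, 4, 3), spacing=(1, 1, 1))
        slices = [ScalarVolume(geometry=plane, values=np.zeros((4, 4)))] * 2
        lms = [self._identity_landmarks(plane)] * 2
        with pytest.raises(ContractError, match="slice count"):
            register_slice_stack(slices, lms, target)

    def test_phantom_self_consistency_dice(self, clean_phantom):
        """Perturb every tdTomato slice by a known random 2-D affine, re-register
        from landmarks, and require Dice >= 0.95 against the original truth."""
        rng = np.random.default_rng(19)
        volume = clean_phantom.tdtomato
        slices, landmarks = slice_and_perturb(volume, rng, max_rotation_deg=8.0,
                                              max_shift_mm=0.8)
        recovered = register_slice_stack(slices, landmarks, volume.geometry)
        spec = SegmentationSpec("tdTomato", clean_phantom.thresholds["tdTomato"])
        recovered_mask = threshold_segment(recovered, spec)
        assert dice(recovered_mask, clean_phantom.truth) >= 0.95
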