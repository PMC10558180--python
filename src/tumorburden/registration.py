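"""Landmark-based least-squares affine registration.

Two registration problems appear in the workflow: a 3-D affine taking the
in vivo MRI/PET frame into the ex vivo MRI frame, and a per-slice 2-D affine
taking each cleared optical slice into its matching ex vivo MRI slice plane.
Both are solved from point correspondences (landmarks) by ordinary least
squares; with exactly d+1 non-degenerate pairs the fit interpolates exactly.

Transforms map *moving* world coordinates (mm) to *fixed* world coordinates.
Resampling pulls each target voxel center back through the inverse transform
and samples the moving image; samples outside the moving field of view take
value 0 (false for masks), matching the convention that everything outside
the brain is removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, ContractError, GridGeometry, ScalarVolume

__all__ = [
    "LandmarkPairSet",
    "AffineTransform",
    "fit_affine_landmarks",
    "apply_transform",
    "register_slice_stack",
    "read_landmarks_tsv",
]


@dataclass(frozen=True)
class LandmarkPairSet:
    """Point correspondences (moving -> fixed), in world mm."""

    moving: np.ndarray  # (n, d)
    fixed: np.ndarray  # (n, d)

    def __post_init__(self) -> None:
        moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if moving.shape != fixed.shape:
            raise ContractError("moving and fixed point arrays must have identical shape")
        d = moving.shape[1]
        if d not in (2, 3):
            raise ContractError(f"landmarks must be 2-D or 3-D points, got {d}-D")
        if moving.shape[0] < d + 1:
            raise ContractError(
                f"a {d}-D affine needs at least {d + 1} landmark pairs, got {moving.shape[0]}"
            )
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed", fixed)

    @property
    def dimension(self) -> int:
        return self.moving.shape[1]


@dataclass(frozen=True)
class AffineTransform:
    """x_fixed = linear @ x_moving + translation, in world mm."""

    linear: np.ndarray  # (d, d)
    translation: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        linear = np.asarray(self.linear, dtype=float)
        translation = np.asarray(self.translation, dtype=float)
        d = translation.shape[0]
        if linear.shape != (d, d):
            raise ContractError("linear part and translation dimensions disagree")
        if abs(np.linalg.det(linear)) <= 1e-12:
            raise ContractError("affine linear part is singular (|det| <= 1e-12)")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "translation", translation)

    @property
    def dimension(self) -> int:
        return self.translation.shape[0]

    @classmethod
    def identity(cls, dimension: int) -> "AffineTransform":
        return cls(np.eye(dimension), np.zeros(dimension))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform(self.linear @ other.linear, self.linear @ other.translation + self.translation)


def fit_affine_landmarks(landmarks: LandmarkPairSet) -> AffineTransform:
    """Least-squares affine from landmark correspondences.

    Minimizes sum ||A m_i + t - f_i||^2 over (A, t).  With exactly d+1
    affinely independent pairs the residual is zero.  A degenerate moving
    configuration (all points within a (d-1)-dimensional affine subspace)
    raises a rank-deficiency error that reports the deficient direction.
    """
    d = landmarks.dimension
    n = landmarks.moving.shape[0]
    design = np.hstack([landmarks.moving, np.ones((n, 1))])
    rank = np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max()))
    if rank < d + 1:
        centered = landmarks.moving - landmarks.moving.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=True)
        deficient = vt[-1]
        raise ContractError(
            "degenerate landmark configuration: moving points span a subspace; "
            f"deficient direction ~ {np.round(deficient, 6).tolist()}"
        )
    coeffs, *_ = np.linalg.lstsq(design, landmarks.fixed, rcond=None)
    return AffineTransform(linear=coeffs[:d, :].T, translation=coeffs[d, :])


def fiducial_registration_error(landmarks: LandmarkPairSet, transform: AffineTransform) -> float:
    """Root-mean-square distance between transformed moving and fixed landmarks (mm)."""
    residual = transform.apply(landmarks.moving) - landmarks.fixed
    return float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))


def apply_transform(moving, transform: AffineTransform, target: GridGeometry, interpolation: str = "nearest"):
    """Resample a moving volume/mask into a target grid under an affine.

    Each target voxel center is pulled back through ``transform.inverse()``
    and sampled from the moving image; out-of-field samples are 0 / false.
    Masks must use nearest-neighbor interpolation so they stay binary.
    """
    if interpolation not in ("nearest", "linear"):
        raise ContractError(f"interpolation must be 'nearest' or 'linear', got {interpolation!r}")
    is_mask = isinstance(moving, BinaryMask)
    if is_mask and interpolation != "nearest":
        raise ContractError("masks must be resampled with nearest interpolation to stay binary")
    source = moving.geometry
    if transform.dimension != source.ndim or target.ndim != source.ndim:
        raise ContractError("transform/geometry dimensionality mismatch")

    axes = [target.voxel_centers(ax) for ax in range(target.ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    world = np.stack([m.ravel() for m in mesh], axis=1)
    moving_world = transform.inverse().apply(world)
    moving_idx = source.world_to_index(moving_world)  # fractional indices

    values = np.asarray(moving.values, dtype=float)
    if interpolation == "nearest":
        # explicit nearest-center gather: round to the nearest index and zero
        # everything whose nearest center falls outside the moving lattice
        idx = np.rint(moving_idx).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(source.shape)), axis=1)
        flat = np.zeros(idx.shape[0], dtype=float)
        flat[inside] = values[tuple(idx[inside].T)]
        sampled = flat.reshape(target.shape)
    else:
        sampled = ndimage.map_coordinates(
            values, moving_idx.T, order=1, mode="constant", cval=0.0, prefilter=False
        ).reshape(target.shape)
    if is_mask:
        return BinaryMask(geometry=target, values=sampled > 0.5)
    return ScalarVolume(geometry=target, values=sampled)


def register_slice_stack(
    optical_slices: list[ScalarVolume],
    per_slice_landmarks: list[LandmarkPairSet],
    target: GridGeometry,
) -> ScalarVolume:
    """Register 2-D optical slices slice-by-slice into a 3-D target frame.

    One landmark set per slice; slice i is mapped by its fitted 2-D affine
    into target plane i (physically: 1-mm coronal slices matched to the
    ex vivo MRI slice planes).  Slices are resampled with nearest
    interpolation and stacked along the third target axis.
    """
    if target.ndim != 3:
        raise ContractError("slice-stack target must be a 3-D geometry")
    if len(optical_slices) != len(per_slice_landmarks):
        raise ContractError(
            f"slice/landmark count mismatch: {len(optical_slices)} slices vs "
            f"{len(per_slice_landmarks)} landmark sets"
        )
    if len(optical_slices) != target.shape[2]:
        raise ContractError(
            f"slice count {len(optical_slices)} does not match target third-axis extent "
            f"{target.shape[2]} (one slice per target plane)"
        )
    plane = GridGeometry(shape=target.shape[:2], spacing=target.spacing[:2], origin=target.origin[:2])
    stacked = np.zeros(target.shape, dtype=float)
    for i, (sl, lm) in enumerate(zip(optical_slices, per_slice_landmarks)):
        if sl.geometry.ndim != 2:
            raise ContractError("optical slices must be 2-D volumes")
        transform = fit_affine_landmarks(lm)
        registered = apply_transform(sl, transform, plane, interpolation="nearest")
        stacked[:, :, i] = registered.values
    return ScalarVolume(geometry=target, values=stacked)


def read_landmarks_tsv(path) -> dict[int, LandmarkPairSet]:
    """Read per-slice landmark pairs from TSV.

    Columns: slice_index, moving_x, moving_y[, moving_z], fixed_x, fixed_y[, fixed_z]
    (coordinates in mm).  Returns a mapping slice_index -> LandmarkPairSet.
    """
    df = pd.read_csv(path, sep="\t")
    has_z = "moving_z" in df.columns
    mov_cols = ["moving_x", "moving_y"] + (["moving_z"] if has_z else [])
    fix_cols = ["fixed_x", "fixed_y"] + (["fixed_z"] if has_z else [])
    out: dict[int, LandmarkPairSet] = {}
    for idx, grp in df.groupby("slice_index"):
        out[int(idx)] = LandmarkPairSet(grp[mov_cols].to_numpy(), grp[fix_cols].to_numpy())
    return out
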