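"""Volume and mask data model with NIfTI I/O and the resampling primitives
the detection analysis depends on.

All geometry is axis-aligned: the world coordinate (mm) of voxel index
``(i, j, k)`` is ``origin + index * spacing``, with ``origin`` the world
position of the *center* of voxel ``(0, 0, 0)``.  Distances are always
computed in world millimetres so that anisotropic grids (e.g. 0.2 x 0.2 x
0.5 mm MRI vs 0.5 x 0.5 x 1 mm PET) are handled correctly.  Rotated
(oblique) geometries are rejected at the I/O boundary; any rotation must be
resolved by the registration module before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "ScalarVolume",
    "BinaryMask",
    "UnsupportedInputError",
    "ContractError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "upsample_nearest",
    "downsample_block_mean",
    "mask_volume_mm3",
]


class ContractError(ValueError):
    """An operation was called outside its documented preconditions."""


class UnsupportedInputError(ValueError):
    """The input file is valid but uses a feature this pipeline does not support."""


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned sampling lattice: voxel counts, spacing (mm) and origin (mm).

    ``origin`` is the world position of the center of voxel ``(0, ..., 0)``.
    Supports 2-D (optical slices) and 3-D grids.
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = (0.0,) * len(shape) if self.origin is None else tuple(float(o) for o in self.origin)
        if not (len(shape) == len(spacing) == len(origin)):
            raise ContractError("shape, spacing and origin must have equal dimension")
        if len(shape) not in (2, 3):
            raise ContractError(f"only 2-D and 3-D grids are supported, got {len(shape)}-D")
        if any(s < 1 for s in shape):
            raise ContractError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ContractError(f"all spacing components must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def isclose(self, other: "GridGeometry", rtol: float = 1e-5) -> bool:
        """Approximate equality: same shape, spacing/origin within ``rtol``.

        NIfTI-1 stores the affine in float32, so geometries round-tripped
        through disk match only to single precision.
        """
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=rtol, atol=1e-6)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-5)
        )

    @property
    def voxel_volume(self) -> float:
        """Volume (mm^d) of a single voxel."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (…, d) to world mm."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (…, d) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - np.array(self.origin)) / np.array(self.spacing)


def _check_lattice(geometry: GridGeometry, values: np.ndarray) -> None:
    if tuple(values.shape) != geometry.shape:
        raise ContractError(
            f"lattice shape {tuple(values.shape)} does not match geometry shape {geometry.shape}"
        )


@dataclass
class ScalarVolume:
    """A scalar image: intensity lattice on an axis-aligned grid.

    Units are modality dependent (arbitrary MR signal, PET activity
    concentration, fluorescence radiant efficiency); the analysis never mixes
    units across modalities without normalization.
    """

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_lattice(self.geometry, self.values)
        if not np.all(np.isfinite(self.values)):
            raise ContractError("volume contains non-finite values")


@dataclass
class BinaryMask:
    """A segmentation on an axis-aligned grid (boolean lattice)."""

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ContractError(f"mask values must be boolean/0-1, found {uniq[:5]}")
            values = values.astype(bool)
        self.values = values
        _check_lattice(self.geometry, self.values)

    @property
    def count(self) -> int:
        return int(self.values.sum())


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> GridGeometry:
    linear = affine[:3, :3]
    off_diag = linear - np.diag(np.diag(linear))
    scale = np.max(np.abs(np.diag(linear)))
    if np.max(np.abs(off_diag)) > 1e-6 * max(scale, 1.0):
        raise UnsupportedInputError(
            "oblique (rotated/sheared) affine: only axis-aligned volumes are supported; "
            "resolve rotation with the registration module first"
        )
    spacing = np.abs(np.diag(linear))
    return GridGeometry(shape=tuple(shape), spacing=tuple(spacing), origin=tuple(affine[:3, 3]))


def _affine_from_geometry(geometry: GridGeometry) -> np.ndarray:
    if geometry.ndim != 3:
        raise ContractError("NIfTI I/O requires a 3-D geometry")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(geometry.spacing)
    affine[:3, 3] = geometry.origin
    return affine


def read_volume(path) -> ScalarVolume:
    """Read a single 3-D scalar NIfTI volume.

    Raises ``UnsupportedInputError`` for 4-D images or oblique affines,
    naming the offending property.
    """
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        shape = shape[:3]
    elif len(shape) != 3:
        raise UnsupportedInputError(f"expected a single 3-D volume, got shape {img.shape}")
    geometry = _geometry_from_affine(np.asarray(img.affine), tuple(shape))
    values = np.asarray(img.dataobj, dtype=float).reshape(shape)
    return ScalarVolume(geometry=geometry, values=values)


def read_mask(path) -> BinaryMask:
    """Read a binary mask stored as a uint8 {0,1} NIfTI volume."""
    vol = read_volume(path)
    return BinaryMask(geometry=vol.geometry, values=vol.values)


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), _affine_from_geometry(volume.geometry))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from_geometry(mask.geometry))
    nib.save(img, str(path))


def _nearest_indices(target: GridGeometry, source: GridGeometry, axis: int) -> np.ndarray:
    centers = target.voxel_centers(axis)
    idx = np.rint((centers - source.origin[axis]) / source.spacing[axis]).astype(int)
    return np.clip(idx, 0, source.shape[axis] - 1)


def upsample_nearest(image, target: GridGeometry):
    """Resample a volume or mask onto a finer grid by nearest voxel center.

    Each target voxel takes the value of the source voxel whose center is
    nearest in world mm (separable per axis on axis-aligned grids).  Masks
    stay binary because values are only copied, never interpolated.

    The target must not be coarser than the source on any axis and must
    cover the same world extent to within one source voxel.
    """
    source = image.geometry
    if target.ndim != source.ndim:
        raise ContractError("dimension mismatch between input and target geometry")
    for ax in range(source.ndim):
        if target.spacing[ax] > source.spacing[ax] * (1 + 1e-9):
            raise ContractError(
                f"target spacing {target.spacing[ax]} coarser than input "
                f"{source.spacing[ax]} on axis {ax}; upsample_nearest only refines"
            )
        src_lo = source.origin[ax] - source.spacing[ax] / 2
        src_hi = source.origin[ax] + (source.shape[ax] - 0.5) * source.spacing[ax]
        tgt_lo = target.origin[ax] - target.spacing[ax] / 2
        tgt_hi = target.origin[ax] + (target.shape[ax] - 0.5) * target.spacing[ax]
        tol = source.spacing[ax] * (1 + 1e-9)
        if tgt_lo < src_lo - tol or tgt_hi > src_hi + tol:
            raise ContractError(
                f"target grid extends beyond the input field of view on axis {ax} "
                f"by more than one input voxel"
            )
    index_grids = np.ix_(*[_nearest_indices(target, source, ax) for ax in range(source.ndim)])
    resampled = image.values[index_grids]
    if isinstance(image, BinaryMask):
        return BinaryMask(geometry=target, values=resampled)
    return ScalarVolume(geometry=target, values=resampled)


def downsample_block_mean(volume: ScalarVolume, target_spacing) -> ScalarVolume:
    """Downsample by averaging non-overlapping blocks of voxels.

    ``target_spacing`` must be an integer multiple of the input spacing on
    every axis (e.g. fluorescence at 0.25 x 0.25 x 0.5 mm onto the PET grid
    at 0.5 x 0.5 x 1 mm uses 2 x 2 x 2 blocks).  Trailing partial blocks
    average only the voxels present, so no padding value leaks into means.
    """
    source = volume.geometry
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != source.ndim:
        raise ContractError("target_spacing dimension mismatch")
    factors = []
    for ax in range(source.ndim):
        ratio = target_spacing[ax] / source.spacing[ax]
        f = int(round(ratio))
        if f < 1 or abs(ratio - f) > 1e-6:
            ratios = tuple(target_spacing[a] / source.spacing[a] for a in range(source.ndim))
            raise ContractError(
                f"target spacing must be an integer multiple of input spacing per axis; "
                f"ratios are {ratios}"
            )
        factors.append(f)

    sums = volume.values
    counts = np.ones_like(volume.values)
    for ax, f in enumerate(factors):
        edges = np.arange(0, sums.shape[ax], f)
        sums = np.add.reduceat(sums, edges, axis=ax)
        counts = np.add.reduceat(counts, edges, axis=ax)
    means = sums / counts

    # block centers: center of the first full block, then strides of target spacing
    new_origin = tuple(
        source.origin[ax] + (factors[ax] - 1) / 2 * source.spacing[ax] for ax in range(source.ndim)
    )
    geometry = GridGeometry(shape=tuple(means.shape), spacing=target_spacing, origin=new_origin)
    return ScalarVolume(geometry=geometry, values=means)


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Volume of a mask in mm^3: true-voxel count times the voxel volume."""
    return mask.count * mask.geometry.voxel_volume
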