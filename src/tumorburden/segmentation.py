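"""Threshold segmentation, modality unions, and metric mask expansion.

Tumors are segmented per modality by a semi-automatic scheme: a per-tumor
intensity threshold plus an optional exclusion mask for regions that are
clearly not tumor (hyperintense ventricles on T2w, areas outside the brain).
Per-modality masks are combined by voxelwise union (T1+T2 -> "MRI",
MRI+PET), and an expanded MRI segmentation is produced by dilating the mask
by a metric radius (2 mm by default) measured in world millimetres, so the
expansion is isotropic in space even on anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ContractError, ScalarVolume

__all__ = ["SegmentationSpec", "threshold_segment", "union_masks", "expand_mask"]


@dataclass
class SegmentationSpec:
    """Per-tumor, per-modality segmentation parameters."""

    modality: str
    threshold: float
    exclusion: BinaryMask | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ContractError("segmentation threshold must be finite")


def threshold_segment(volume: ScalarVolume, spec: SegmentationSpec) -> BinaryMask:
    """Voxel is tumor iff value >= threshold and not in the exclusion mask.

    The comparison is inclusive so a noiseless image whose tumor voxels sit
    exactly at the generative cutoff segments to the exact truth mask.
    """
    if spec.exclusion is not None and spec.exclusion.geometry != volume.geometry:
        raise ContractError(
            f"exclusion mask geometry {spec.exclusion.geometry.shape} does not match "
            f"volume geometry {volume.geometry.shape}"
        )
    detected = volume.values >= spec.threshold
    if spec.exclusion is not None:
        detected &= ~spec.exclusion.values
    return BinaryMask(geometry=volume.geometry, values=detected)


def union_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise OR of masks on identical grids (T1+T2 -> MRI; MRI+PET)."""
    if not masks:
        raise ContractError("union_masks requires at least one mask")
    geometry = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geometry:
            raise ContractError("all masks in a union must share one geometry")
    combined = np.zeros(geometry.shape, dtype=bool)
    for m in masks:
        combined |= m.values
    return BinaryMask(geometry=geometry, values=combined)


def expand_mask(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Metric dilation: include every voxel whose center lies within
    ``radius_mm`` (Euclidean, world mm) of a true voxel center.

    Implemented with an anisotropic Euclidean distance transform (per-axis
    sampling = voxel spacing), not an index-space structuring element, so
    "2 mm" means millimetres on any grid.  Always a superset of the input.
    """
    if radius_mm < 0:
        raise ContractError(f"expansion radius must be >= 0, got {radius_mm}")
    if radius_mm == 0 or not mask.values.any():
        return BinaryMask(geometry=mask.geometry, values=mask.values.copy())
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.geometry.spacing)
    # tiny tolerance keeps voxels at exactly radius_mm inside despite float error
    expanded = dist <= radius_mm + 1e-9
    return BinaryMask(geometry=mask.geometry, values=expanded)
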