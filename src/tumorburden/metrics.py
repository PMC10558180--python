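"""Per-tumor detection scores against the fluorescence ground truth.

The tdTomato fluorescence segmentation is treated as the true tumor extent.
Each in vivo modality (T1w, T2w, their union "MRI", PET, MRI+PET, and the
2-mm expanded MRI) is scored voxel-wise on a common grid:

* sensitivity  = |detection ∩ truth| / |truth|
* specificity  = (|brain| - |(detection ∪ truth) ∩ brain|) / (|brain| - |truth|)
  — detection voxels outside the brain region are ignored
* Dice         = 2 |detection ∩ truth| / (|detection| + |truth|)
* max surface distance = worst case over both segmentations' surface voxels
  of the minimum world-mm distance to the other segmentation's surface
  (a symmetric Hausdorff distance over surface voxels); undefined ("nd")
  when either mask is empty.

Scores are computed on the fine (tdTomato) grid after nearest-neighbor
upsampling of the in vivo masks, mirroring how coarse in vivo images are
brought to the ex vivo frame; the scoring grid is a parameter so the
sensitivity of results to grid choice can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask, ContractError, GridGeometry, mask_volume_mm3, upsample_nearest
from .segmentation import expand_mask, union_masks

__all__ = [
    "DetectionResult",
    "UndefinedMetricError",
    "sensitivity",
    "specificity",
    "dice",
    "max_surface_distance",
    "surface_voxels",
    "evaluate_case",
    "MODALITIES",
]

#: Modalities scored per tumor, in reporting order.
MODALITIES = ("T1", "T2", "T1+T2", "PET", "MRI+PET", "expanded-MRI")


class UndefinedMetricError(ValueError):
    """The metric is undefined for these inputs (e.g. empty ground truth)."""


@dataclass
class DetectionResult:
    """Scores for one tumor and one detection modality.

    ``max_surface_distance_mm`` is ``None`` ("nd") when the detection mask is
    empty — the tumor was entirely undetected, so no surface exists.  In that
    case sensitivity and Dice are 0 and specificity is 1 by construction.
    """

    case_id: str
    modality: str
    volume_mm3: float
    sensitivity: float
    specificity: float
    dice: float
    max_surface_distance_mm: float | None
    gd_status: bool
    volume_unclipped_mm3: float | None = None
    error: str | None = field(default=None, repr=False)


def _require_same_geometry(*masks: BinaryMask) -> None:
    geom = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geom:
            raise ContractError("masks must share one geometry; resample first")


def sensitivity(detection: BinaryMask, truth: BinaryMask) -> float:
    """Fraction of true tumor voxels covered by the detection."""
    _require_same_geometry(detection, truth)
    n_truth = truth.count
    if n_truth == 0:
        raise UndefinedMetricError("ground truth is empty: sensitivity undefined")
    return int(np.count_nonzero(detection.values & truth.values)) / n_truth


def specificity(detection: BinaryMask, truth: BinaryMask, brain: BinaryMask) -> float:
    """Fraction of non-tumor brain voxels not flagged by the detection.

    Computed as (|brain| - |(detection ∪ truth) ∩ brain|) / (|brain| - |truth|);
    detection voxels outside the brain region do not count against specificity.
    Requires truth ⊆ brain and |brain| > |truth|.
    """
    _require_same_geometry(detection, truth, brain)
    if np.any(truth.values & ~brain.values):
        raise ContractError("truth mask must be contained in the brain region")
    n_brain = brain.count
    n_truth = truth.count
    if n_brain <= n_truth:
        raise UndefinedMetricError("brain region equals the tumor: specificity undefined")
    flagged = np.count_nonzero((detection.values | truth.values) & brain.values)
    return (n_brain - int(flagged)) / (n_brain - n_truth)


def dice(detection: BinaryMask, truth: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    _require_same_geometry(detection, truth)
    n_a, n_b = detection.count, truth.count
    if n_a == 0 and n_b == 0:
        raise UndefinedMetricError("both masks empty: Dice undefined")
    inter = int(np.count_nonzero(detection.values & truth.values))
    return 2 * inter / (n_a + n_b)


_FACE_STRUCTURE = {2: ndimage.generate_binary_structure(2, 1), 3: ndimage.generate_binary_structure(3, 1)}


def surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Indices (n, d) of surface voxels: true voxels with >= 1 false face-neighbor.

    Faces of the volume count as boundary, so a mask touching the edge of
    the field of view has surface voxels there.
    """
    structure = _FACE_STRUCTURE[mask.geometry.ndim]
    interior = ndimage.binary_erosion(mask.values, structure=structure, border_value=0)
    return np.argwhere(mask.values & ~interior)


def max_surface_distance(a: BinaryMask, b: BinaryMask) -> float | None:
    """Symmetric worst-case surface distance in world mm, or None if either
    mask is empty ("nd": the tumor was not detected at all)."""
    _require_same_geometry(a, b)
    if not a.values.any() or not b.values.any():
        return None
    spacing = np.array(a.geometry.spacing)
    surf_a = surface_voxels(a) * spacing
    surf_b = surface_voxels(b) * spacing
    tree_a = cKDTree(surf_a)
    tree_b = cKDTree(surf_b)
    d_ab = tree_b.query(surf_a, k=1)[0].max()
    d_ba = tree_a.query(surf_b, k=1)[0].max()
    return float(max(d_ab, d_ba))


def _score(case_id, modality, detection, truth, brain, gd_status, unclipped_volume=None) -> DetectionResult:
    return DetectionResult(
        case_id=case_id,
        modality=modality,
        volume_mm3=mask_volume_mm3(detection),
        sensitivity=sensitivity(detection, truth),
        specificity=specificity(detection, truth, brain),
        dice=dice(detection, truth) if (detection.count or truth.count) else 0.0,
        max_surface_distance_mm=max_surface_distance(detection, truth),
        gd_status=gd_status,
        volume_unclipped_mm3=unclipped_volume,
    )


def evaluate_case(
    case_id: str,
    truth: BinaryMask,
    brain: BinaryMask,
    detections: dict[str, BinaryMask],
    gd_status: bool,
    expansion_radius_mm: float = 2.0,
    scoring_grid: GridGeometry | None = None,
) -> list[DetectionResult]:
    """Score one tumor case across all modalities and their combinations.

    ``detections`` maps 'T1', 'T2', 'PET' to masks on their native grids;
    each is upsampled (nearest) to the scoring grid — by default the truth
    (tdTomato) grid — before scoring.  Emits one result per modality in
    ``MODALITIES``; a metric failure in one modality is recorded on that
    row's ``error`` field without aborting the others.
    """
    grid = scoring_grid if scoring_grid is not None else truth.geometry

    def on_grid(mask: BinaryMask) -> BinaryMask:
        return mask if mask.geometry == grid else upsample_nearest(mask, grid)

    truth_g = on_grid(truth)
    brain_g = on_grid(brain)
    base = {name: on_grid(detections[name]) for name in ("T1", "T2", "PET")}
    mri = union_masks([base["T1"], base["T2"]])
    combos = {
        "T1": base["T1"],
        "T2": base["T2"],
        "T1+T2": mri,
        "PET": base["PET"],
        "MRI+PET": union_masks([mri, base["PET"]]),
    }
    expanded = expand_mask(mri, expansion_radius_mm)
    expanded_clipped = BinaryMask(geometry=grid, values=expanded.values & brain_g.values)

    results: list[DetectionResult] = []
    for modality in MODALITIES:
        try:
            if modality == "expanded-MRI":
                res = _score(case_id, modality, expanded_clipped, truth_g, brain_g, gd_status,
                             unclipped_volume=mask_volume_mm3(expanded))
            else:
                res = _score(case_id, modality, combos[modality], truth_g, brain_g, gd_status)
        except (UndefinedMetricError, ContractError) as exc:
            res = DetectionResult(
                case_id=case_id, modality=modality, volume_mm3=math.nan,
                sensitivity=math.nan, specificity=math.nan, dice=math.nan,
                max_surface_distance_mm=None, gd_status=gd_status, error=str(exc),
            )
        results.append(res)
    return results


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as the reported tables do (0.735 -> 0.74)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
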