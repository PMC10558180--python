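"""Synthetic multimodal phantom cases.

Each phantom emulates one study subject as the analysis sees it: an
ellipsoidal brain on a fine ("optical/MRI-class") grid carrying a tumor
ground truth with a solid core and a partially infiltrated margin, plus the
per-modality appearances —

* tdTomato fluorescence proportional to tumor cell density (the ground
  truth channel: thresholding its noiseless image at the generative cutoff
  recovers the truth mask exactly);
* gadolinium-enhanced T1w showing the enhancing core only in Gd+ cases;
* T2w detecting the densest ``t2_detect_fraction`` of the tumor (diffuse
  infiltration goes undetected, as in the study's invasive lines);
* PET as tumor cell density times a contrast that depends on enhancement
  status and cellularity, blurred by a separable Gaussian point-spread
  function (FWHM in mm) and sampled on a coarser PET grid — partial-volume
  overshoot of the tumor boundary arises naturally;
* ASCT2 and lectin fluorescence as stated linear functions of cell density.

The fine grid defaults to 0.25 x 0.25 x 0.5 mm so the 0.5 x 0.5 x 1 mm PET
grid is an exact 2 x 2 x 2 block of fine voxels; the true optical in-plane
resolution (tens of microns) is deliberately not simulated — the analysis
contracts depend on the relative grid ratios, not the absolute scale.

``generate_cohort`` reproduces the study composition (4 Gd+, 5 Gd- visible
on PET, 4 Gd- invisible on PET) with per-case seeds derived reproducibly
from one master seed.  ``simulate_regression_table`` draws tumor-level
correlate tables directly from a standardized log-linear model with stated
effect sizes, for regression parameter-recovery experiments.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, ContractError, GridGeometry, ScalarVolume, downsample_block_mean

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "simulate_regression_table",
    "table1_fixture",
    "load_table1_scores",
    "slice_and_perturb",
]

STRATA = ("Gd+", "Gd- PET-visible", "Gd- PET-invisible")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic multimodal case.

    Distances are mm; intensities are arbitrary per-channel units with
    strictly positive backgrounds (required by contralateral normalization).
    """

    fine_shape: tuple[int, int, int] = (64, 64, 24)
    fine_spacing: tuple[float, float, float] = (0.25, 0.25, 0.5)
    pet_spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    brain_semi_axes: tuple[float, float, float] = (7.2, 6.4, 5.2)
    tumor_center_offset: tuple[float, float, float] = (2.4, 0.5, 0.0)
    tumor_radius: float = 2.4
    infiltration_width: float = 1.5
    infiltration_fill: float = 0.5
    min_tumor_density: float = 0.3
    cellularity: float = 1.0
    gd_status: bool = True
    pet_visible: bool = True
    t2_detect_fraction: float = 0.75
    contralateral_margin_mm: float = 2.0
    pet_psf_fwhm: float = 1.5
    pet_tumor_to_background: float = 3.0
    pet_background: float = 1.0
    pet_threshold: float = 1.35
    gd_uptake_boost: float = 1.3
    mri_background: float = 0.5
    mri_amplitude: float = 1.0
    fluor_background: float = 0.2
    tdtomato_amplitude: float = 1.0
    asct2_background: float = 0.3
    asct2_amplitude: float = 0.8
    lectin_background: float = 0.5
    lectin_amplitude: float = 0.4
    has_lectin: bool = True
    noise_sd_mri: float = 0.02
    noise_sd_pet: float = 0.02
    noise_sd_fluor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in (*self.brain_semi_axes, self.tumor_radius)):
            raise ContractError("brain semi-axes and tumor radius must be positive")
        if self.infiltration_width < 0:
            raise ContractError("infiltration width must be >= 0")
        for name in ("infiltration_fill", "min_tumor_density", "t2_detect_fraction", "cellularity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ContractError(f"{name} must lie in (0, 1], got {v}")
        outer = self.tumor_radius + self.infiltration_width
        for off, semi in zip(self.tumor_center_offset, self.brain_semi_axes):
            if abs(off) + outer > semi:
                raise ContractError(
                    f"tumor (radius+infiltration {outer} mm at offset {self.tumor_center_offset}) "
                    f"exceeds the brain ellipsoid semi-axes {self.brain_semi_axes}"
                )


@dataclass
class PhantomCase:
    """One generated case: geometry, ground truth, channels and cutoffs.

    Fine-grid members: ``brain``, ``truth``, ``contralateral`` masks and the
    ``t1``, ``t2``, ``tdtomato``, ``asct2``, ``lectin`` channels.  PET-grid
    members: ``pet`` plus ``truth_pet`` / ``brain_pet`` / ``contralateral_pet``
    masks.  ``thresholds`` holds the per-modality generative cutoffs the
    semi-automatic segmentation would choose.
    """

    case_id: str
    spec: PhantomSpec
    gd_status: bool
    stratum: str
    brain: BinaryMask
    truth: BinaryMask
    contralateral: BinaryMask
    t1: ScalarVolume
    t2: ScalarVolume
    tdtomato: ScalarVolume
    asct2: ScalarVolume
    lectin: ScalarVolume | None
    pet: ScalarVolume
    truth_pet: BinaryMask
    brain_pet: BinaryMask
    contralateral_pet: BinaryMask
    thresholds: dict[str, float]
    density: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _fine_geometry(spec: PhantomSpec) -> GridGeometry:
    return GridGeometry(shape=spec.fine_shape, spacing=spec.fine_spacing, origin=(0.0, 0.0, 0.0))


def _world_coordinates(geometry: GridGeometry) -> list[np.ndarray]:
    axes = [geometry.voxel_centers(ax) for ax in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _downsample_mask(mask: BinaryMask, target_spacing) -> BinaryMask:
    frac = downsample_block_mean(
        ScalarVolume(geometry=mask.geometry, values=mask.values.astype(float)), target_spacing
    )
    return BinaryMask(geometry=frac.geometry, values=frac.values >= 0.5)


def generate_phantom(spec: PhantomSpec, case_id: str = "phantom") -> PhantomCase:
    """Generate one multimodal case, deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    geometry = _fine_geometry(spec)
    xs, ys, zs = _world_coordinates(geometry)
    center = np.array(geometry.shape) / 2 * np.array(geometry.spacing) + np.array(geometry.origin) \
        - np.array(geometry.spacing) / 2  # brain centered mid-grid

    brain_vals = sum(((c - ctr) / semi) ** 2 for c, ctr, semi in
                     zip((xs, ys, zs), center, spec.brain_semi_axes)) <= 1.0
    brain = BinaryMask(geometry=geometry, values=brain_vals)

    tumor_center = center + np.array(spec.tumor_center_offset)
    r = np.sqrt(sum((c - tc) ** 2 for c, tc in zip((xs, ys, zs), tumor_center)))
    core = r <= spec.tumor_radius
    shell = (r > spec.tumor_radius) & (r <= spec.tumor_radius + spec.infiltration_width)
    if not np.all(brain_vals[core | shell]):
        raise ContractError("tumor exceeds the brain mask on this grid")

    # infiltrated margin: smoothed random field thresholded to fill the
    # requested fraction of the shell; density ramps from min_tumor_density
    # upward so the generative tdTomato cutoff separates tumor exactly
    field_raw = ndimage.gaussian_filter(rng.standard_normal(geometry.shape), sigma=2.0)
    density = np.zeros(geometry.shape)
    density[core] = 1.0
    n_shell = int(shell.sum())
    if n_shell and spec.infiltration_width > 0:
        u = field_raw[shell]
        cut = np.quantile(u, 1.0 - spec.infiltration_fill)
        infiltrated = u >= cut
        span = u.max() - cut
        ramp = (u - cut) / span if span > 0 else np.ones_like(u)
        d_shell = np.zeros(n_shell)
        d_shell[infiltrated] = spec.min_tumor_density + (1.0 - spec.min_tumor_density) * ramp[infiltrated]
        density[shell] = d_shell
    truth_vals = density >= spec.min_tumor_density
    truth = BinaryMask(geometry=geometry, values=truth_vals)

    # contralateral normal region: mirror of the tumor across the mid-sagittal
    # plane, keeping a safety margin from the (possibly midline-crossing)
    # tumor so no tumor or partial-volume signal enters the normalization
    from .segmentation import expand_mask

    mirrored = truth_vals[::-1, :, :]
    guard = expand_mask(truth, spec.contralateral_margin_mm)
    contra_vals = mirrored & brain_vals & ~guard.values
    contralateral = BinaryMask(geometry=geometry, values=contra_vals)

    def noisy(signal: np.ndarray, sd: float) -> np.ndarray:
        return signal + rng.normal(0.0, sd, signal.shape) if sd > 0 else signal

    amp = spec.mri_amplitude
    t1_signal = np.where(brain_vals, spec.mri_background, 0.0)
    if spec.gd_status:
        t1_signal = t1_signal + amp * core
    t1 = ScalarVolume(geometry=geometry, values=noisy(t1_signal, spec.noise_sd_mri))

    dens_in_truth = density[truth_vals]
    t2_cut = np.quantile(dens_in_truth, 1.0 - spec.t2_detect_fraction) if spec.t2_detect_fraction < 1 \
        else spec.min_tumor_density
    t2_mask = truth_vals & (density >= t2_cut)
    t2_signal = np.where(brain_vals, spec.mri_background, 0.0) + amp * t2_mask
    t2 = ScalarVolume(geometry=geometry, values=noisy(t2_signal, spec.noise_sd_mri))

    tdt_amp = spec.tdtomato_amplitude * spec.cellularity
    tdt_signal = np.where(brain_vals, spec.fluor_background, 0.0) + tdt_amp * density
    tdtomato = ScalarVolume(geometry=geometry, values=noisy(tdt_signal, spec.noise_sd_fluor))

    asct2_signal = np.where(brain_vals, spec.asct2_background, 0.0) \
        + spec.asct2_amplitude * spec.cellularity * density
    asct2 = ScalarVolume(geometry=geometry, values=noisy(asct2_signal, spec.noise_sd_fluor))

    lectin = None
    if spec.has_lectin:
        lectin_signal = np.where(brain_vals, spec.lectin_background, 0.0) \
            + spec.lectin_amplitude * density
        lectin = ScalarVolume(geometry=geometry, values=noisy(lectin_signal, spec.noise_sd_fluor))

    # PET: contrast scales with cellularity and BBB status; zero contrast for
    # the PET-invisible stratum; PSF blur then block-mean to the PET grid
    contrast = 0.0
    if spec.pet_visible:
        contrast = (spec.pet_tumor_to_background - 1.0) * spec.cellularity
        if spec.gd_status:
            contrast *= spec.gd_uptake_boost
    activity = spec.pet_background * (1.0 + contrast * density)
    if spec.pet_psf_fwhm > 0:
        sigma_vox = [spec.pet_psf_fwhm / 2.355 / s for s in geometry.spacing]
        activity = ndimage.gaussian_filter(activity, sigma=sigma_vox)
    pet_fine = ScalarVolume(geometry=geometry, values=activity)
    pet_coarse = downsample_block_mean(pet_fine, spec.pet_spacing)
    pet = ScalarVolume(geometry=pet_coarse.geometry,
                       values=noisy(pet_coarse.values, spec.noise_sd_pet))

    truth_pet = _downsample_mask(truth, spec.pet_spacing)
    brain_pet = _downsample_mask(brain, spec.pet_spacing)
    contralateral_pet = _downsample_mask(contralateral, spec.pet_spacing)

    thresholds = {
        "T1": spec.mri_background + amp / 2,
        "T2": spec.mri_background + amp / 2,
        "PET": spec.pet_threshold,
        "tdTomato": spec.fluor_background + tdt_amp * spec.min_tumor_density,
    }
    stratum = "Gd+" if spec.gd_status else ("Gd- PET-visible" if spec.pet_visible else "Gd- PET-invisible")

    return PhantomCase(
        case_id=case_id, spec=spec, gd_status=spec.gd_status, stratum=stratum,
        brain=brain, truth=truth, contralateral=contralateral,
        t1=t1, t2=t2, tdtomato=tdtomato, asct2=asct2, lectin=lectin,
        pet=pet, truth_pet=truth_pet, brain_pet=brain_pet,
        contralateral_pet=contralateral_pet, thresholds=thresholds, density=density,
    )


def generate_cohort(
    n_gd_pos: int = 4,
    n_gd_neg_pet_pos: int = 5,
    n_gd_neg_pet_neg: int = 4,
    base_spec: PhantomSpec | None = None,
    master_seed: int = 0,
    n_missing_lectin: int = 2,
) -> list[PhantomCase]:
    """Generate a cohort mirroring the study composition (default 4/5/4).

    Per-case seeds and biologic variation (tumor size, cellularity,
    infiltration, T2 conspicuity) derive reproducibly from ``master_seed``.
    Gd+ tumors are compact and cell dense; Gd- PET-visible tumors are
    intermediate; Gd- PET-invisible tumors are diffusely infiltrative with
    low cellularity.  The last ``n_missing_lectin`` cases lack the lectin
    channel, as in the study.
    """
    if min(n_gd_pos, n_gd_neg_pet_pos, n_gd_neg_pet_neg) < 0:
        raise ContractError("stratum counts must be >= 0")
    base = base_spec if base_spec is not None else PhantomSpec()
    master = np.random.default_rng(master_seed)
    plan = [("Gd+", True, True)] * n_gd_pos \
        + [("Gd- PET-visible", False, True)] * n_gd_neg_pet_pos \
        + [("Gd- PET-invisible", False, False)] * n_gd_neg_pet_neg
    cases: list[PhantomCase] = []
    total = len(plan)
    for i, (stratum, gd, pet_vis) in enumerate(plan):
        seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        if stratum == "Gd+":
            radius = rng.uniform(2.0, 2.8)
            width = rng.uniform(1.0, 1.6)
            cellularity = rng.uniform(0.8, 1.0)
            t2_frac = rng.uniform(0.7, 0.9)
        elif stratum == "Gd- PET-visible":
            radius = rng.uniform(1.6, 2.4)
            width = rng.uniform(1.2, 2.0)
            cellularity = rng.uniform(0.5, 0.8)
            t2_frac = rng.uniform(0.55, 0.8)
        else:
            radius = rng.uniform(1.2, 1.8)
            width = rng.uniform(1.5, 2.2)
            cellularity = rng.uniform(0.25, 0.45)
            t2_frac = rng.uniform(0.35, 0.55)
        # per-case staining efficiency: channel amplitudes jitter independently
        # so the biologic channels are correlated with cell density without
        # being collinear surrogates of one another across the cohort
        spec = replace(
            base, gd_status=gd, pet_visible=pet_vis, tumor_radius=radius,
            infiltration_width=width, cellularity=cellularity,
            t2_detect_fraction=t2_frac, seed=seed,
            tdtomato_amplitude=base.tdtomato_amplitude * float(rng.lognormal(0.0, 0.10)),
            asct2_amplitude=base.asct2_amplitude * float(rng.lognormal(0.0, 0.35)),
            lectin_amplitude=base.lectin_amplitude * float(rng.lognormal(0.0, 0.35)),
            has_lectin=(i < total - n_missing_lectin),
        )
        cases.append(generate_phantom(spec, case_id=f"case{i + 1:02d}"))
    return cases


def simulate_regression_table(
    n: int = 13,
    effects: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    lectin_missing: int = 0,
) -> pd.DataFrame:
    """Draw a tumor-level correlate table from a standardized log-linear model.

    Regressor logs are standard normal (gd_status Bernoulli(4/13), matching
    the study's enhancement rate); log uptake is the stated linear
    combination plus Gaussian noise.  Used for coefficient-recovery
    experiments where the generative effect sizes are known exactly.
    """
    if effects is None:
        effects = {"tdtomato": 1.2, "asct2": 0.3, "lectin": 0.15,
                   "tumor_volume": 0.2, "gd_status": 0.4}
    rng = np.random.default_rng(seed)
    cols = {}
    for name in ("tdtomato", "asct2", "lectin", "tumor_volume"):
        cols[name] = rng.standard_normal(n)
    # fixed enhancing count at the study's 4-in-13 rate (>= 1 so the
    # design is never degenerate), positions shuffled
    n_pos = max(1, round(4 * n / 13))
    gd = np.zeros(n)
    gd[rng.permutation(n)[:n_pos]] = 1.0
    log_uptake = sum(effects.get(k, 0.0) * v for k, v in cols.items()) \
        + effects.get("gd_status", 0.0) * gd + rng.normal(0.0, noise_sd, n)
    frame = pd.DataFrame(
        {
            "pet_uptake": np.exp(log_uptake),
            "tdtomato": np.exp(cols["tdtomato"]),
            "asct2": np.exp(cols["asct2"]),
            "lectin": np.exp(cols["lectin"]),
            "tumor_volume": np.exp(cols["tumor_volume"] + 4.0),  # ~55 mm3 scale
            "gd_status": gd.astype(int),
        },
        index=[f"sim{i + 1:02d}" for i in range(n)],
    )
    if lectin_missing:
        frame.loc[frame.index[-lectin_missing:], "lectin"] = math.nan
    return frame


def slice_and_perturb(
    volume: ScalarVolume,
    rng: np.random.Generator,
    max_rotation_deg: float = 10.0,
    max_shift_mm: float = 1.0,
    max_log_scale: float = 0.08,
    n_landmarks: int = 6,
):
    """Slice a 3-D volume into 2-D planes, misalign each with a known random
    2-D affine, and return (perturbed slices, per-slice landmark sets).

    Emulates the physical workflow (cleared slices deform and shift on the
    imaging stage, then are brought back by landmark registration): feeding
    the output to ``register_slice_stack`` with the original volume geometry
    as target should recover the input up to nearest-neighbor resampling.
    """
    from .registration import AffineTransform, LandmarkPairSet, apply_transform

    geometry = volume.geometry
    plane = GridGeometry(shape=geometry.shape[:2], spacing=geometry.spacing[:2],
                         origin=geometry.origin[:2])
    extent = [plane.spacing[a] * plane.shape[a] for a in range(2)]
    center = np.array([plane.origin[a] + extent[a] / 2 for a in range(2)])

    slices, landmark_sets = [], []
    for k in range(geometry.shape[2]):
        theta = math.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
        scale = math.exp(rng.uniform(-max_log_scale, max_log_scale))
        rot = scale * np.array([[math.cos(theta), -math.sin(theta)],
                                [math.sin(theta), math.cos(theta)]])
        shift = rng.uniform(-max_shift_mm, max_shift_mm, size=2)
        # perturbation about the slice center so tissue stays in the field
        translation = center - rot @ center + shift
        transform = AffineTransform(rot, translation)

        true_slice = ScalarVolume(geometry=plane, values=volume.values[:, :, k])
        perturbed = apply_transform(true_slice, transform, plane, interpolation="nearest")
        fixed_pts = center + rng.uniform(-0.3, 0.3, size=(n_landmarks, 2)) * np.array(extent)
        moving_pts = transform.apply(fixed_pts)
        slices.append(perturbed)
        landmark_sets.append(LandmarkPairSet(moving_pts, fixed_pts))
    return slices, landmark_sets


# ---------------------------------------------------------------------------
# published per-tumor score table (packaged fixture)

_WIDE_METRICS = ("volume_mm3", "sensitivity", "specificity", "dice", "max_surface_distance_mm")
_WIDE_MODALITIES = ("T1", "T2", "T1+T2", "PET", "MRI+PET")


def table1_fixture() -> pd.DataFrame:
    """The published 13-tumor score table, one wide row per tumor.

    Columns: case_id, cell_line, gd_status, then <metric>_<modality> for the
    five modalities, plus volume_mm3_Optical.  Undetected-tumor surface
    distances ("nd") are NaN.
    """
    ref = importlib.resources.files("tumorburden") / "data" / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", na_values=["nd"])
    frame["gd_status"] = frame["gd_status"].astype(bool)
    return frame


def load_table1_scores() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged per-tumor table in the analysis' long form.

    Returns ``(scores, case_info)`` ready for ``summarize_cohort``:
    ``scores`` has one row per (case, modality); ``case_info`` has one row
    per case with gd_status, pet_detected (PET volume > 0) and the optical
    ground-truth volume.
    """
    wide = table1_fixture()
    rows = []
    for _, row in wide.iterrows():
        for modality in _WIDE_MODALITIES:
            rows.append(
                {"case_id": row["case_id"], "modality": modality,
                 **{metric: row[f"{metric}_{modality}"] for metric in _WIDE_METRICS},
                 "gd_status": row["gd_status"]}
            )
    scores = pd.DataFrame(rows)
    case_info = pd.DataFrame(
        {
            "case_id": wide["case_id"],
            "cell_line": wide["cell_line"],
            "gd_status": wide["gd_status"],
            "pet_detected": wide["volume_mm3_PET"] > 0,
            "optical_volume_mm3": wide["volume_mm3_Optical"],
        }
    )
    return scores, case_info
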