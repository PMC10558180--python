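"""PET-uptake correlate analysis.

Fluciclovine uptake is related to biologic measurements from the cleared
tissue: tumor cell content (tdTomato fluorescence), amino acid transporter
expression (ASCT2 immunostain), perfused vasculature (lectin), tumor volume
and gadolinium enhancement status.  All intensity summaries are normalized
to the mean of a contralateral normal-brain region, which removes global
scale (scanner gain, laser power); the normalized, strictly positive values
are log-transformed and z-scored before an ordinary least-squares fit, so
coefficients are standardized and comparable across regressors.

Two granularities are supported: a tumor-level table (PET summarized by the
max over the tumor, fluorescence by the mean) and a voxel-level table on the
PET grid (fluorescence block-mean-downsampled to the PET voxel size).
Partial-regression (added-variable) plots are built from the two residual
regressions; by the Frisch-Waugh-Lovell theorem the slope of the y-residuals
on the x-residuals equals the multivariate coefficient of that regressor.

Lectin was not measured for every tumor; the conventional analysis fits the
full model on complete cases and a lectin-free model on all cases, and both
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import BinaryMask, ContractError, ScalarVolume, downsample_block_mean, mask_volume_mm3

__all__ = [
    "CorrelateRecord",
    "RegressionFit",
    "normalize_to_contralateral",
    "build_tumor_table",
    "build_voxel_table",
    "log_standardize",
    "fit_multivariate",
    "partial_regression",
]

#: Continuous columns that are log-transformed before standardization.
LOG_COLUMNS = ("pet_uptake", "tdtomato", "asct2", "lectin", "tumor_volume")


@dataclass
class CorrelateRecord:
    """Tumor-level normalized uptake and biologic covariates.

    All intensity fields are dimensionless ratios to the contralateral
    normal-brain mean and must be > 0 (required by the log transform);
    ``lectin`` may be None for tumors without a lectin measurement.
    """

    case_id: str
    pet_uptake: float
    tdtomato: float
    asct2: float
    lectin: float | None
    tumor_volume: float
    gd_status: int

    def __post_init__(self) -> None:
        for name in ("pet_uptake", "tdtomato", "asct2", "tumor_volume"):
            v = getattr(self, name)
            if not (v > 0):
                raise ContractError(f"{name} must be > 0 for case {self.case_id!r}, got {v}")
        if self.lectin is not None and not (self.lectin > 0):
            raise ContractError(f"lectin must be > 0 or absent for case {self.case_id!r}")
        self.gd_status = int(bool(self.gd_status))


@dataclass
class RegressionFit:
    """Standardized OLS fit summary."""

    params: pd.Series
    pvalues: pd.Series
    r_squared: float
    residuals: np.ndarray = field(repr=False)
    n: int
    response: str = "pet_uptake"

    @property
    def coefficients(self) -> pd.Series:
        """Slope coefficients without the intercept."""
        return self.params.drop("const", errors="ignore")


def normalize_to_contralateral(tumor_stat: float, contralateral_mean: float) -> float:
    """Dimensionless ratio of a tumor summary to the contralateral normal mean."""
    if not (contralateral_mean > 0):
        raise ContractError(f"contralateral mean must be > 0, got {contralateral_mean}")
    return tumor_stat / contralateral_mean


def _masked(volume: ScalarVolume, mask: BinaryMask) -> np.ndarray:
    if volume.geometry != mask.geometry:
        raise ContractError("volume and mask geometries must match")
    return volume.values[mask.values]


def build_tumor_table(cases) -> list[CorrelateRecord]:
    """One record per tumor: max PET and mean fluorescence over the truth
    mask, each normalized to the mean over the contralateral normal mask.

    Each case must provide ``case_id``, ``gd_status``, a ``truth`` mask and
    ``contralateral`` mask per channel grid, and the channel volumes
    ``pet``, ``tdtomato``, ``asct2`` and optionally ``lectin`` (None when the
    tumor lacks a lectin measurement) — see ``phantom.PhantomCase``.
    """
    records = []
    for case in cases:
        if case.contralateral.count == 0:
            raise ContractError(f"case {case.case_id!r}: contralateral mask is empty")
        if case.contralateral_pet.count == 0:
            raise ContractError(f"case {case.case_id!r}: contralateral PET mask is empty")

        pet_vals = _masked(case.pet, case.truth_pet)
        pet = normalize_to_contralateral(
            float(pet_vals.max()), float(_masked(case.pet, case.contralateral_pet).mean())
        )

        def norm_mean(channel: ScalarVolume) -> float:
            return normalize_to_contralateral(
                float(_masked(channel, case.truth).mean()),
                float(_masked(channel, case.contralateral).mean()),
            )

        records.append(
            CorrelateRecord(
                case_id=case.case_id,
                pet_uptake=pet,
                tdtomato=norm_mean(case.tdtomato),
                asct2=norm_mean(case.asct2),
                lectin=None if case.lectin is None else norm_mean(case.lectin),
                tumor_volume=mask_volume_mm3(case.truth),
                gd_status=int(case.gd_status),
            )
        )
    return records


def records_to_frame(records: list[CorrelateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "pet_uptake": [r.pet_uptake for r in records],
            "tdtomato": [r.tdtomato for r in records],
            "asct2": [r.asct2 for r in records],
            "lectin": [math.nan if r.lectin is None else r.lectin for r in records],
            "tumor_volume": [r.tumor_volume for r in records],
            "gd_status": [r.gd_status for r in records],
        }
    ).set_index("case_id")


def build_voxel_table(case, pet_spacing=(0.5, 0.5, 1.0)) -> pd.DataFrame:
    """Per-voxel records on the PET grid for one tumor.

    Fluorescence channels are block-mean downsampled to the PET voxel size;
    records are restricted to tumor voxels on that grid, and each column is
    normalized to its contralateral mean on the same grid.
    """
    truth = case.truth_pet
    if truth.count == 0:
        raise ContractError(f"case {case.case_id!r}: no tumor voxels on the PET grid")

    def down(channel: ScalarVolume) -> ScalarVolume:
        if channel.geometry == case.pet.geometry:
            return channel
        vol = downsample_block_mean(channel, pet_spacing)
        if vol.geometry.shape != case.pet.geometry.shape:
            raise ContractError("downsampled fluorescence does not land on the PET grid")
        return ScalarVolume(geometry=case.pet.geometry, values=vol.values)

    contra = case.contralateral_pet
    columns: dict[str, np.ndarray] = {}
    for name in ("pet", "tdtomato", "asct2", "lectin"):
        channel = getattr(case, name)
        if channel is None:
            continue
        vol = channel if name == "pet" else down(channel)
        denom = float(vol.values[contra.values].mean())
        columns["pet_uptake" if name == "pet" else name] = (
            vol.values[truth.values] / denom if denom > 0 else np.nan
        )
    frame = pd.DataFrame(columns)
    frame["tumor_volume"] = mask_volume_mm3(case.truth)
    frame["gd_status"] = int(case.gd_status)
    frame["case_id"] = case.case_id
    return frame


def log_standardize(table: pd.DataFrame, standardize_response: bool = True) -> pd.DataFrame:
    """Natural-log transform the positive continuous columns, then z-score
    every model column (mean 0, sd 1 with the n-1 denominator).

    ``gd_status`` is binary: it is z-scored but never log-transformed.
    A nonpositive value or a zero-variance column is a contract violation
    naming the offender.  When ``standardize_response`` is false the
    response column (``pet_uptake``) is log-transformed but left unscaled.
    """
    out = table.copy()
    for col in out.columns:
        if col in ("case_id",):
            continue
        vals = out[col].astype(float)
        if col in LOG_COLUMNS:
            bad = vals <= 0
            if bad.any():
                offender = out.index[bad.to_numpy().nonzero()[0][0]]
                raise ContractError(f"column {col!r} has nonpositive value at record {offender!r}")
            vals = np.log(vals)
        if col == "pet_uptake" and not standardize_response:
            out[col] = vals
            continue
        sd = vals.std(ddof=1)
        if not (sd > 0):
            raise ContractError(f"column {col!r} has zero variance; cannot standardize")
        out[col] = (vals - vals.mean()) / sd
    return out


def _design(table: pd.DataFrame, response: str, regressors: list[str] | None) -> tuple[pd.Series, pd.DataFrame]:
    if regressors is None:
        regressors = [c for c in table.columns if c not in (response, "case_id")]
    sub = table[[response, *regressors]].dropna()
    y = sub[response]
    x = sm.add_constant(sub[regressors])
    return y, x


def fit_multivariate(table: pd.DataFrame, response: str = "pet_uptake",
                     regressors: list[str] | None = None) -> RegressionFit:
    """OLS of the (log-standardized) response on all regressors.

    Rows with any missing regressor (e.g. absent lectin) are dropped, so the
    full model runs on complete cases; pass ``regressors`` without "lectin"
    for the lectin-free model on every tumor.  Coefficient p-values are
    two-sided from the t distribution with n - k - 1 df.
    """
    y, x = _design(table, response, regressors)
    n, k = x.shape
    if n <= k:
        raise ContractError(f"need n > number of regressors + 1 (n={n}, columns={k})")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < k:
        corr = x.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise ContractError(f"rank-deficient design; most collinear columns: {pair}")
    res = sm.OLS(y, x).fit()
    return RegressionFit(
        params=res.params, pvalues=res.pvalues, r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid), n=n, response=response,
    )


def partial_regression(table: pd.DataFrame, regressor_of_interest: str,
                       response: str = "pet_uptake",
                       regressors: list[str] | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Added-variable plot coordinates and slope for one regressor.

    y-residuals: response regressed on all other regressors; x-residuals:
    the regressor of interest regressed on the others.  The slope of the
    through-origin regression of y-residuals on x-residuals equals the full
    multivariate coefficient (Frisch-Waugh-Lovell identity).
    """
    y, x = _design(table, response, regressors)
    if regressor_of_interest not in x.columns:
        raise ContractError(f"unknown regressor {regressor_of_interest!r}")
    others = x.drop(columns=[regressor_of_interest])
    if others.shape[1] == 1:  # only the intercept: degenerates to simple regression
        y_resid = (y - y.mean()).to_numpy()
        x_resid = (x[regressor_of_interest] - x[regressor_of_interest].mean()).to_numpy()
    else:
        y_resid = np.asarray(sm.OLS(y, others).fit().resid)
        x_resid = np.asarray(sm.OLS(x[regressor_of_interest], others).fit().resid)
    denom = float(x_resid @ x_resid)
    if denom == 0:
        raise ContractError("regressor of interest is fully explained by the others")
    slope = float(x_resid @ y_resid) / denom
    return x_resid, y_resid, slope
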