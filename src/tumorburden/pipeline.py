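"""End-to-end orchestration: simulate -> segment -> score -> summarize -> correlate.

The pipeline runs either on a synthetic phantom cohort (the package's test
bed) or, in fixture mode, on the packaged published per-tumor score table.
Outputs are plain TSV; every report starts with a provenance comment line
(package version, configuration hash, seed) and identical configuration plus
seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ContractError, write_mask, write_volume
from .correlates import (
    build_tumor_table,
    fit_multivariate,
    log_standardize,
    partial_regression,
    records_to_frame,
)
from .group_stats import format_p, results_to_frame, summarize_cohort
from .metrics import evaluate_case, round_half_up
from .phantom import PhantomSpec, generate_cohort, load_table1_scores
from .segmentation import SegmentationSpec, threshold_segment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "score_phantom_cohort"]

ALL_STAGES = ("simulate", "segment", "score", "summarize", "correlate")

#: Overall-median row as printed in the published per-tumor table, used only
#: to flag discrepancies between that row and the recomputed medians (the
#: recomputed value is canonical).  Keys: (modality, metric) -> printed value.
PRINTED_OVERALL = {
    ("Optical", "volume_mm3"): 95.0,
    ("T1", "volume_mm3"): 0.0,
    ("T2", "volume_mm3"): 60.0,
    ("T1+T2", "volume_mm3"): 67.0,
    ("PET", "volume_mm3"): 87.0,
    ("MRI+PET", "volume_mm3"): 110.0,
    ("T1", "sensitivity"): 0.0,
    ("T2", "sensitivity"): 0.56,
    ("T1+T2", "sensitivity"): 0.61,
    ("PET", "sensitivity"): 0.67,
    ("MRI+PET", "sensitivity"): 0.87,
    ("T1", "specificity"): 1.0,
    ("T2", "specificity"): 0.97,
    ("T1+T2", "specificity"): 0.97,
    ("PET", "specificity"): 0.93,
    ("MRI+PET", "specificity"): 0.92,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and case where relevant)."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    fixture_table1: bool = False
    n_gd_pos: int = 4
    n_gd_neg_pet_pos: int = 5
    n_gd_neg_pet_neg: int = 4
    n_missing_lectin: int = 2
    expansion_radius_mm: float = 2.0
    scoring_grid: str = "fine"  # score on the fine (tdTomato) grid
    write_volumes: bool = False  # also dump per-case NIfTI volumes
    phantom_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expansion_radius_mm < 0:
            raise ContractError("expansion radius must be >= 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ContractError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return f"# tumorburden v{__version__} config={config.digest()} seed={config.seed}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_report_tsv(path) -> pd.DataFrame:
    """Read a pipeline TSV, skipping the provenance comment line."""
    return pd.read_csv(path, sep="\t", comment="#")


def _reported_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Reporting layer: 2-decimal half-up rounding, integer volumes, 'nd' literals."""
    out = scores.copy()
    for col in ("sensitivity", "specificity", "dice"):
        out[col] = out[col].map(lambda v: f"{round_half_up(v, 2):.2f}" if np.isfinite(v) else "nd")
    out["volume_mm3"] = out["volume_mm3"].map(
        lambda v: f"{round_half_up(v):.0f}" if np.isfinite(v) else "nd"
    )
    out["max_surface_distance_mm"] = out["max_surface_distance_mm"].map(
        lambda v: f"{round_half_up(v, 1):.1f}" if np.isfinite(v) else "nd"
    )
    return out


def score_phantom_cohort(cases, expansion_radius_mm: float = 2.0):
    """Segment each phantom at its generative cutoffs and score all modalities.

    Returns (scores, case_info) in the same long form as the packaged
    fixture loader, ready for ``summarize_cohort``.
    """
    from .core import mask_volume_mm3

    results = []
    info_rows = []
    for case in cases:
        detections = {
            "T1": threshold_segment(case.t1, SegmentationSpec("T1", case.thresholds["T1"])),
            "T2": threshold_segment(case.t2, SegmentationSpec("T2", case.thresholds["T2"])),
            "PET": threshold_segment(case.pet, SegmentationSpec("PET", case.thresholds["PET"])),
        }
        results.extend(
            evaluate_case(
                case.case_id, case.truth, case.brain, detections, case.gd_status,
                expansion_radius_mm=expansion_radius_mm,
            )
        )
        info_rows.append(
            {
                "case_id": case.case_id,
                "gd_status": case.gd_status,
                "pet_detected": bool(detections["PET"].count > 0),
                "stratum": case.stratum,
                "optical_volume_mm3": mask_volume_mm3(case.truth),
            }
        )
    return results_to_frame(results), pd.DataFrame(info_rows)


def _check_printed_overall(summary: pd.DataFrame) -> list[str]:
    """Compare recomputed overall medians against the printed overall-median
    row and log any discrepancy (recomputed value is canonical)."""
    notes = []
    overall = summary[summary["group"] == "overall"]
    for (modality, metric), printed in PRINTED_OVERALL.items():
        row = overall[(overall["modality"] == modality) & (overall["metric"] == metric)]
        if row.empty:
            continue
        decimals = 0 if metric == "volume_mm3" else 2
        recomputed = round_half_up(float(row["median"].iloc[0]), decimals)
        if abs(recomputed - printed) > 10.0 ** (-decimals) / 2:
            msg = (
                f"printed overall median for {modality} {metric} is {printed} but the "
                f"13 printed rows give {recomputed}; keeping the recomputed value"
            )
            logger.warning(msg)
            notes.append(msg)
    return notes


def _correlate_reports(records_frame: pd.DataFrame, out: Path, config: PipelineConfig) -> None:
    table = log_standardize(records_frame.drop(columns=["case_id"], errors="ignore"))
    regressors_full = ["tdtomato", "asct2", "lectin", "tumor_volume", "gd_status"]
    fits = {
        "lectin-free (all cases)": fit_multivariate(
            table, regressors=[r for r in regressors_full if r != "lectin"]
        ),
    }
    n_complete = int(table[regressors_full].dropna().shape[0])
    if n_complete > len(regressors_full) + 1:
        fits["full (complete cases)"] = fit_multivariate(table, regressors=regressors_full)
    else:
        logger.warning(
            "only %d complete-lectin cases; skipping the full model (lectin-free model reported)",
            n_complete,
        )
    rows = []
    for label, fit in fits.items():
        for name, beta in fit.coefficients.items():
            rows.append(
                {"model": label, "regressor": name, "beta_standardized": beta,
                 "p": fit.pvalues[name], "p_reported": format_p(float(fit.pvalues[name])),
                 "r_squared": fit.r_squared, "n": fit.n}
            )
    _write_tsv(pd.DataFrame(rows), out / "correlate_model.tsv", config)

    points = []
    for regressor in regressors_full:
        x_res, y_res, slope = partial_regression(table, regressor, regressors=regressors_full)
        for x, y in zip(x_res, y_res):
            points.append({"regressor": regressor, "x_residual": x, "y_residual": y, "slope": slope})
    _write_tsv(pd.DataFrame(points), out / "partial_regression_points.tsv", config)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the reports.

    Returns a dict of the in-memory products (cases, scores, summary,
    comparisons, correlate records) for the stages that ran.  Any stage
    failure raises ``PipelineError`` naming the stage; outputs written by
    earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    products: dict = {}

    if config.fixture_table1:
        try:
            scores, case_info = load_table1_scores()
            summary, comparisons = summarize_cohort(scores, case_info)
            notes = _check_printed_overall(summary)
            _write_tsv(scores, out / "fixture_per_tumor.tsv", config)
            _write_tsv(summary, out / "fixture_summary.tsv", config)
            _write_tsv(comparisons, out / "fixture_comparisons.tsv", config)
            if notes:
                (out / "fixture_discrepancies.txt").write_text(
                    _provenance(config) + "\n".join(notes) + "\n"
                )
            products.update(scores=scores, case_info=case_info, summary=summary,
                            comparisons=comparisons, discrepancies=notes)
            return products
        except Exception as exc:  # noqa: BLE001 - report stage context
            raise PipelineError(f"fixture stage failed: {exc}") from exc

    stages = config.stages
    cases = None
    if "simulate" in stages:
        try:
            base = PhantomSpec(**config.phantom_overrides) if config.phantom_overrides else None
            cases = generate_cohort(
                config.n_gd_pos, config.n_gd_neg_pet_pos, config.n_gd_neg_pet_neg,
                base_spec=base, master_seed=config.seed,
                n_missing_lectin=config.n_missing_lectin,
            )
            manifest = pd.DataFrame(
                {"case_id": [c.case_id for c in cases],
                 "stratum": [c.stratum for c in cases],
                 "gd_status": [c.gd_status for c in cases],
                 "seed": [c.spec.seed for c in cases],
                 "has_lectin": [c.lectin is not None for c in cases]}
            )
            _write_tsv(manifest, out / "case_manifest.tsv", config)
            if config.write_volumes:
                case_dir = out / "cases"
                case_dir.mkdir(exist_ok=True)
                for c in cases:
                    write_volume(c.tdtomato, case_dir / f"{c.case_id}_tdtomato.nii.gz")
                    write_volume(c.t1, case_dir / f"{c.case_id}_t1.nii.gz")
                    write_volume(c.t2, case_dir / f"{c.case_id}_t2.nii.gz")
                    write_volume(c.pet, case_dir / f"{c.case_id}_pet.nii.gz")
                    write_mask(c.truth, case_dir / f"{c.case_id}_truth.nii.gz")
                    write_mask(c.brain, case_dir / f"{c.case_id}_brain.nii.gz")
            products["cases"] = cases
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"simulate stage failed: {exc}") from exc

    scores = case_info = None
    if {"segment", "score"} & set(stages):
        if cases is None:
            raise PipelineError("score stage requires the simulate stage (no case source given)")
        try:
            scores, case_info = score_phantom_cohort(cases, config.expansion_radius_mm)
            _write_tsv(scores, out / "per_tumor_raw.tsv", config)
            _write_tsv(_reported_scores(scores), out / "per_tumor.tsv", config)
            _write_tsv(case_info, out / "case_info.tsv", config)
            products.update(scores=scores, case_info=case_info)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"score stage failed: {exc}") from exc

    if "summarize" in stages and scores is not None:
        try:
            summary, comparisons = summarize_cohort(scores, case_info)
            _write_tsv(summary, out / "summary.tsv", config)
            _write_tsv(comparisons, out / "comparisons.tsv", config)
            products.update(summary=summary, comparisons=comparisons)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"summarize stage failed: {exc}") from exc

    if "correlate" in stages and cases is not None:
        try:
            records = build_tumor_table(cases)
            frame = records_to_frame(records)
            _write_tsv(frame.reset_index(), out / "correlate_records.tsv", config)
            _correlate_reports(frame, out, config)
            products["correlate_records"] = frame
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"correlate stage failed: {exc}") from exc

    return products
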