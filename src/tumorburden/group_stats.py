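"""Cohort summaries and exact nonparametric comparisons.

Per-tumor detection scores are summarized as median (min, max) by subgroup
— gadolinium enhancing (Gd+), non-enhancing (Gd-), and the Gd- strata that
are / are not visible on PET — and modalities are compared with exact
Wilcoxon tests suited to the small cohort (n = 13):

* paired modality-vs-modality contrasts on the same tumors use the exact
  signed-rank test, with zero differences discarded (the classical Wilcoxon
  convention) and midranks for tied absolute differences;
* unpaired Gd+ vs Gd- contrasts use the exact rank-sum test with midranks.

Both null distributions are enumerated exactly — over all 2^m sign
assignments, respectively all C(n1+n2, n1) group assignments — via dynamic
programming on doubled (hence integer) midranks, so tied data are handled
without normal approximation.  Undetected tumors contribute "nd" surface
distances, which are excluded from distance medians.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ContractError
from .metrics import DetectionResult, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "median_range",
    "percent_increase",
    "wilcoxon_signed_rank_exact",
    "wilcoxon_rank_sum_exact",
    "summarize_cohort",
    "results_to_frame",
    "format_p",
    "DegenerateDataWarning",
]

METRIC_COLUMNS = ("volume_mm3", "sensitivity", "specificity", "dice", "max_surface_distance_mm")

GROUPS = ("overall", "Gd+", "Gd-", "Gd- PET-visible", "Gd- PET-invisible")


class DegenerateDataWarning(UserWarning):
    """The test data admit no information (e.g. all paired differences zero)."""


def median_range(values) -> tuple[float, float, float]:
    """Sample median (midpoint of central order statistics for even n), min, max."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ContractError("median_range requires a non-empty list")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def percent_increase(new_median: float, ref_median: float) -> int:
    """Percent change of a median relative to a positive reference, rounded
    to the nearest integer percent for reporting."""
    if ref_median <= 0:
        raise ContractError(f"reference median must be > 0, got {ref_median}")
    return int(round_half_up(100.0 * (new_median - ref_median) / ref_median))


def _doubled_midranks(magnitudes: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so ties (.5 ranks) become exact integers."""
    return np.round(2 * rankdata(magnitudes)).astype(np.int64)


def wilcoxon_signed_rank_exact(paired_a, paired_b) -> float:
    """Exact two-sided p of the Wilcoxon signed-rank test on paired data.

    Differences a - b equal to zero are discarded; absolute differences are
    midranked; the exact two-sided p enumerates all 2^m sign assignments of
    the m nonzero pairs (p = 2 * min(P(W+ <= w), P(W+ >= w)), capped at 1).
    If every difference is zero the data are degenerate: returns 1.0 with a
    ``DegenerateDataWarning``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("paired samples must be equal-length 1-D sequences")
    diffs = a - b
    diffs = diffs[diffs != 0]
    m = diffs.size
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", DegenerateDataWarning)
        return 1.0
    if m > 25:
        raise ContractError(f"exact enumeration supported for <= 25 nonzero pairs, got {m}")
    ranks2 = _doubled_midranks(np.abs(diffs))
    w2 = int(ranks2[diffs > 0].sum())

    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:  # counts[s] = #sign assignments with doubled W+ = s
        counts[r:] += counts[:-r].copy() if r else counts.copy()
    n_assign = 2.0**m
    p_le = counts[: w2 + 1].sum() / n_assign
    p_ge = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum_exact(group_a, group_b) -> float:
    """Exact two-sided p of the Wilcoxon rank-sum (Mann-Whitney) test.

    Pooled values are midranked; the exact two-sided p enumerates all
    C(n1+n2, n1) assignments of pooled ranks to group A by dynamic
    programming (p = 2 * min(P(W <= w), P(W >= w)), capped at 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    if n1 + n2 > 25:
        raise ContractError(f"exact enumeration supported for combined n <= 25, got {n1 + n2}")
    pooled2 = _doubled_midranks(np.concatenate([a, b]))
    w2 = int(pooled2[:n1].sum())

    total = int(pooled2.sum())
    # counts[k, s] = #k-subsets of pooled doubled ranks with sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in pooled2:
        counts[1:, r:] += counts[:-1, :-r].copy()
    dist = counts[n1]
    n_assign = dist.sum()
    p_le = dist[: w2 + 1].sum() / n_assign
    p_ge = dist[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def format_p(p: float) -> str:
    """Report p to 1 significant figure at or below 0.01, else 2 decimals."""
    if p <= 0.01:
        return f"{p:.1g}"
    return f"{round_half_up(p, 2):.2f}"


def results_to_frame(results: list[DetectionResult]) -> pd.DataFrame:
    """Long per-tumor score table: one row per (case, modality)."""
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in results],
            "modality": [r.modality for r in results],
            "volume_mm3": [r.volume_mm3 for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "dice": [r.dice for r in results],
            "max_surface_distance_mm": [
                np.nan if r.max_surface_distance_mm is None else r.max_surface_distance_mm
                for r in results
            ],
            "gd_status": [r.gd_status for r in results],
        }
    )


def _group_masks(case_info: pd.DataFrame) -> dict[str, pd.Series]:
    gd = case_info["gd_status"].astype(bool)
    pet = case_info["pet_detected"].astype(bool)
    return {
        "overall": pd.Series(True, index=case_info.index),
        "Gd+": gd,
        "Gd-": ~gd,
        "Gd- PET-visible": ~gd & pet,
        "Gd- PET-invisible": ~gd & ~pet,
    }


def summarize_cohort(
    scores: pd.DataFrame,
    case_info: pd.DataFrame,
    paired_metrics: tuple[str, ...] = ("sensitivity", "specificity"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort summary and exact-test comparison tables.

    Parameters
    ----------
    scores
        Long table with columns case_id, modality and the metric columns
        (``results_to_frame`` output, or the packaged per-tumor fixture).
        "nd" surface distances must already be NaN.
    case_info
        One row per case: case_id, gd_status (bool), pet_detected (bool),
        optical_volume_mm3.

    Returns
    -------
    summary
        Tidy rows (group, modality, metric, median, min, max, n); "nd"
        distances are excluded from distance medians; the ground-truth
        optical volume appears under modality "Optical".
    comparisons
        Paired modality-vs-modality exact signed-rank contrasts for the
        requested metrics and for detected volumes (within all tumors and
        the PET-visible subset), plus unpaired Gd+ vs Gd- rank-sum
        contrasts, with exact two-sided p-values.
    """
    case_info = case_info.set_index("case_id", drop=False) if case_info.index.name != "case_id" else case_info
    groups = _group_masks(case_info)
    modalities = [m for m in scores["modality"].unique()]

    summary_rows = []
    for group, member in groups.items():
        ids = case_info.loc[member, "case_id"]
        if len(ids) == 0:
            logger.warning("grouping %r has no members; omitted from summary", group)
            continue
        sub = scores[scores["case_id"].isin(ids)]
        for modality in modalities:
            block = sub[sub["modality"] == modality]
            if block.empty:
                continue
            for metric in METRIC_COLUMNS:
                vals = block[metric].dropna()
                if vals.empty:
                    continue
                med, lo, hi = median_range(vals)
                summary_rows.append(
                    {"group": group, "modality": modality, "metric": metric,
                     "median": med, "min": lo, "max": hi, "n": len(vals)}
                )
        opt = case_info.loc[member, "optical_volume_mm3"].dropna()
        if not opt.empty:
            med, lo, hi = median_range(opt)
            summary_rows.append(
                {"group": group, "modality": "Optical", "metric": "volume_mm3",
                 "median": med, "min": lo, "max": hi, "n": len(opt)}
            )
    summary = pd.DataFrame(summary_rows)

    comparison_rows = []
    wide = {
        metric: scores.pivot(index="case_id", columns="modality", values=metric)
        for metric in ("sensitivity", "specificity", "volume_mm3")
    }
    order = case_info["case_id"]

    def paired(metric, mod_a, mod_b, group, member):
        tbl = wide[metric].loc[order[member]]
        if mod_a == "Optical":
            a = case_info.loc[member, "optical_volume_mm3"].to_numpy()
        else:
            a = tbl[mod_a].to_numpy()
        b = case_info.loc[member, "optical_volume_mm3"].to_numpy() if mod_b == "Optical" else tbl[mod_b].to_numpy()
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() < 1:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            p = wilcoxon_signed_rank_exact(a[keep], b[keep])
        med_a, med_b = float(np.median(a[keep])), float(np.median(b[keep]))
        comparison_rows.append(
            {"test": "signed-rank (paired)", "metric": metric, "group": group,
             "a": mod_a, "b": mod_b, "median_a": med_a, "median_b": med_b,
             "p": p, "p_reported": format_p(p), "n": int(keep.sum())}
        )

    score_mods = [m for m in ("T1+T2", "PET", "MRI+PET") if m in modalities]
    for metric in paired_metrics:
        for mod_a, mod_b in combinations(score_mods, 2):
            paired(metric, mod_b, mod_a, "overall", groups["overall"])
    # detected-volume contrasts: MRI vs truth overall; PET vs truth / PET vs MRI
    # within tumors visible on PET (Gd+ plus Gd- PET-visible)
    if "T1+T2" in modalities:
        paired("volume_mm3", "T1+T2", "Optical", "overall", groups["overall"])
    pet_visible = groups["Gd+"] | groups["Gd- PET-visible"]
    if "PET" in modalities and pet_visible.any():
        paired("volume_mm3", "PET", "Optical", "PET-visible", pet_visible)
        if "T1+T2" in modalities:
            paired("volume_mm3", "PET", "T1+T2", "PET-visible", pet_visible)

    gd_pos, gd_neg = groups["Gd+"], groups["Gd-"]
    if gd_pos.any() and gd_neg.any():
        for metric in paired_metrics:
            for modality in score_mods:
                tbl = wide[metric]
                a = tbl.loc[order[gd_pos], modality].dropna().to_numpy()
                b = tbl.loc[order[gd_neg], modality].dropna().to_numpy()
                if a.size == 0 or b.size == 0:
                    continue
                p = wilcoxon_rank_sum_exact(a, b)
                comparison_rows.append(
                    {"test": "rank-sum (unpaired)", "metric": metric, "group": "Gd+ vs Gd-",
                     "a": f"{modality} Gd+", "b": f"{modality} Gd-",
                     "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                     "p": p, "p_reported": format_p(p), "n": int(a.size + b.size)}
                )

    return summary, pd.DataFrame(comparison_rows)
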