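"""Head-size normalization and the hemispheric asymmetry index.

Regional volumes are normalized for skull size as

    relative volume = ROI volume / eTIV * 1000

and regional cortical thickness relative to the hemisphere:

    relative thickness = ROI thickness / mean cortical thickness (same hemisphere)

Lateralization is quantified by the asymmetry index

    AI = (Left - Right) / (Left + Right)

with positive values indicating left-ward asymmetry.  AI is invariant under a
common positive rescaling of both hemispheres, so eTIV normalization cancels
exactly in the volume AI.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import CohortTable

__all__ = [
    "relative_volume",
    "relative_thickness",
    "asymmetry_index",
    "hemisphere_mean_thickness",
    "normalize_cohort",
    "compute_asymmetry",
]

NORMALIZATION_MODES = ("relative", "absolute")


def relative_volume(roi_volume, etiv):
    """ROI volume scaled by estimated total intracranial volume, x1000."""
    roi_volume = np.asarray(roi_volume, dtype=float)
    etiv = np.asarray(etiv, dtype=float)
    if np.any(etiv <= 0):
        raise ValueError("etiv must be positive")
    if np.any(roi_volume < 0):
        raise ValueError("roi_volume must be non-negative")
    return roi_volume / etiv * 1000.0


def relative_thickness(roi_thickness, hemisphere_mean):
    """ROI thickness relative to the mean cortical thickness of its hemisphere."""
    roi_thickness = np.asarray(roi_thickness, dtype=float)
    hemisphere_mean = np.asarray(hemisphere_mean, dtype=float)
    if np.any(hemisphere_mean <= 0):
        raise ValueError("hemisphere mean thickness must be positive")
    return roi_thickness / hemisphere_mean


def asymmetry_index(left, right):
    """(L - R) / (L + R); positive = left-ward, negative = right-ward.

    Raises for L + R == 0 on scalar input (undefined AI).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    total = left + right
    if np.ndim(total) == 0:
        if total == 0:
            raise ValueError("asymmetry index undefined for left + right == 0")
        return float((left - right) / total)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(total != 0, (left - right) / np.where(total != 0, total, 1.0), np.nan)
    return ai


def hemisphere_mean_thickness(cohort: CohortTable,
                              provided: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (subject, hemisphere) mean cortical thickness.

    When the input carried a FreeSurfer-style MeanThickness summary (stored as
    region ``mean_thickness``), that value is used — it is FreeSurfer's
    surface-area-weighted hemisphere mean.  Otherwise the unweighted mean over
    the available cortical thickness ROIs stands in.
    """
    meas = cohort.measures
    thick = meas[meas["measure_kind"] == "thickness_mm"]
    summary = thick[thick["region_name"] == "mean_thickness"]
    roi = thick[thick["region_name"] != "mean_thickness"]
    means = (
        roi.groupby(["subject_id", "hemisphere"])["value"]
        .mean()
        .rename("mean_thickness")
        .reset_index()
    )
    if len(summary):
        prov = summary.rename(columns={"value": "mean_thickness"})[
            ["subject_id", "hemisphere", "mean_thickness"]
        ]
        means = (
            pd.concat([prov, means])
            .drop_duplicates(["subject_id", "hemisphere"], keep="first")
            .reset_index(drop=True)
        )
    return means


def normalize_cohort(cohort: CohortTable, mode: str = "relative",
                     max_failure_fraction: float = 0.05) -> pd.DataFrame:
    """Apply the selected normalization to every applicable measure.

    Returns a long DataFrame (subject_id, region_name, hemisphere,
    measure_kind, value) where measure_kind is ``relative_volume`` /
    ``relative_thickness`` in relative mode, or the native kinds in absolute
    mode (values pass through unchanged).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}")
    meas = cohort.measures[cohort.measures["region_name"] != "mean_thickness"]
    if mode == "absolute":
        return meas.reset_index(drop=True).copy()

    df = meas.merge(cohort.subjects[["subject_id", "etiv"]], on="subject_id")
    hm = hemisphere_mean_thickness(cohort)
    df = df.merge(hm, on=["subject_id", "hemisphere"], how="left")

    out = df.copy()
    is_vol = out["measure_kind"] == "volume_mm3"
    is_thk = out["measure_kind"] == "thickness_mm"
    out.loc[is_vol, "value"] = relative_volume(
        df.loc[is_vol, "value"], df.loc[is_vol, "etiv"]
    )
    out.loc[is_vol, "measure_kind"] = "relative_volume"

    bad_mean = is_thk & ~(df["mean_thickness"] > 0)
    n_bad = int(bad_mean.sum())
    if n_bad:
        warnings.warn(f"{n_bad} thickness rows lack a positive hemisphere mean; dropped")
        if n_bad > max_failure_fraction * max(len(out), 1):
            raise ValueError("too many normalization failures")
    ok_thk = is_thk & ~bad_mean
    out.loc[ok_thk, "value"] = relative_thickness(
        df.loc[ok_thk, "value"], df.loc[ok_thk, "mean_thickness"]
    )
    out.loc[is_thk, "measure_kind"] = "relative_thickness"
    out = out[~bad_mean]
    return out[["subject_id", "region_name", "hemisphere", "measure_kind", "value"]].reset_index(drop=True)


def compute_asymmetry(cohort: CohortTable, scale: str = "absolute") -> pd.DataFrame:
    """Per-subject, per-region asymmetry index for volume and thickness.

    ``scale`` selects the values fed to the AI: ``absolute`` (raw; default —
    the eTIV denominator cancels exactly for volume) or ``relative``.
    Subjects with an incomplete hemisphere pair are excluded for that region;
    rows with L + R == 0 are dropped with a warning.

    Returns a DataFrame (subject_id, region_name, measure_kind, left_value,
    right_value, ai).
    """
    if scale == "absolute":
        meas = cohort.measures[cohort.measures["region_name"] != "mean_thickness"].copy()
    else:
        meas = normalize_cohort(cohort, mode="relative")
        meas["measure_kind"] = meas["measure_kind"].map(
            {"relative_volume": "volume_mm3", "relative_thickness": "thickness_mm"}
        )
    wide = meas.pivot_table(
        index=["subject_id", "region_name", "measure_kind"],
        columns="hemisphere",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide = wide.dropna(subset=[c for c in ("left", "right") if c in wide.columns])
    if "left" not in wide.columns or "right" not in wide.columns:
        return pd.DataFrame(
            columns=["subject_id", "region_name", "measure_kind",
                     "left_value", "right_value", "ai"]
        )
    total = wide["left"] + wide["right"]
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} undefined AI rows (L+R==0) dropped")
        wide = wide[~degenerate]
        total = total[~degenerate]
    wide = wide.rename(columns={"left": "left_value", "right": "right_value"})
    wide["ai"] = (wide["left_value"] - wide["right_value"]) / total
    cols = ["subject_id", "region_name", "measure_kind", "left_value", "right_value", "ai"]
    return wide[cols].sort_values(["measure_kind", "region_name", "subject_id"]).reset_index(drop=True)
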