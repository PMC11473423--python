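"""Sliding-window detection of emerging hemispheric asymmetry.

Subjects are binned into fixed-width age windows (default 12 months) slid
across the cohort's age range.  Within each window the per-subject asymmetry
indices of a region are tested against a zero-asymmetry null with the
Wilcoxon signed-rank test; p-values are Benjamini-Hochberg adjusted across
the region family within each window.  A region's *initial point* of
lateralization is the midpoint of the earliest window whose adjusted p falls
below alpha, with direction given by the sign of that window's mean AI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import fdr_adjust

__all__ = [
    "AgeWindow",
    "build_windows",
    "wilcoxon_signed_rank",
    "test_windows",
    "detect_emergence",
    "population_average_asymmetry",
]

MIN_TESTABLE_N = 5  # exact two-sided signed-rank significance at 0.05 needs n >= 6
EXACT_N_MAX = 25


@dataclass
class AgeWindow:
    start_month: float
    end_month: float
    member_subject_ids: list
    testable: bool = True

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_month + self.end_month)

    @property
    def n(self) -> int:
        return len(self.member_subject_ids)


def build_windows(ages, subject_ids=None, width: float = 12.0, stride: float = 1.0,
                  min_n: int = MIN_TESTABLE_N, convention: str = "half_open"):
    """Construct sliding age windows over the observed age range.

    ``half_open`` membership is ``start <= age < start + width`` with the
    window spanning [start, start + width); the ``integer_inclusive``
    convention bins integer months ``start..start + width - 1`` (window end
    = start + width - 1), yielding x.5 midpoints for even widths.
    Windows with fewer than ``min_n`` members are emitted but flagged
    untestable.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty cohort")
    if width <= 0 or stride <= 0:
        raise ValueError("width and stride must be positive")
    if subject_ids is None:
        subject_ids = np.arange(len(ages))
    subject_ids = np.asarray(subject_ids)
    lo, hi = float(ages.min()), float(ages.max())
    windows = []
    start = lo
    while True:
        if convention == "half_open":
            mask = (ages >= start) & (ages < start + width)
            end = start + width
        elif convention == "integer_inclusive":
            mask = (ages >= start) & (ages <= start + width - 1)
            end = start + width - 1
        else:
            raise ValueError(f"unknown convention {convention!r}")
        members = subject_ids[mask].tolist()
        windows.append(
            AgeWindow(start, end, members, testable=len(members) >= min_n)
        )
        start += stride
        if start + width > hi + stride:
            break
    return windows


def wilcoxon_signed_rank(values, mu0: float = 0.0):
    """Two-sided Wilcoxon signed-rank test of ``values`` against ``mu0``.

    Zeros are dropped (classic convention); ties receive midranks.  The exact
    null distribution is used when the post-removal n <= 25 and there are no
    tied absolute values, otherwise a normal approximation with tie and
    continuity corrections.  Returns ``(W, p)``; ``(nan, nan)`` when every
    value equals ``mu0``.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all values equal the null location; test undefined")
        return np.nan, np.nan
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= EXACT_N_MAX and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    # report the positive-rank sum W+ (so negating the sample reflects W
    # about n(n+1)/4) regardless of the backend's statistic convention
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


def test_windows(ai_records: pd.DataFrame, windows, subjects: pd.DataFrame,
                 alpha: float = 0.05, family: list | None = None,
                 fdr_family: str = "per-window") -> pd.DataFrame:
    """Window-by-region Wilcoxon tests of the asymmetry index against zero.

    Parameters
    ----------
    ai_records
        DataFrame with columns subject_id, region_name, measure_kind, ai
        (one measure kind at a time).
    windows
        Output of :func:`build_windows` built on the same subjects.
    subjects
        Subject table (for bookkeeping only).
    family
        Region names forming the FDR family; defaults to the regions present.
    fdr_family
        ``per-window`` (default): BH across regions within each window —
        family sizes match the measure's region family.  ``per-region``:
        BH across windows within each region (experimental).

    Returns a long DataFrame with one row per (region, window).
    """
    kinds = ai_records["measure_kind"].unique()
    if len(kinds) > 1:
        raise ValueError("test_windows expects a single measure_kind")
    measure_kind = kinds[0] if len(kinds) else "unknown"
    if family is None:
        family = sorted(ai_records["region_name"].unique())
    rows = []
    for w_idx, w in enumerate(windows):
        members = set(w.member_subject_ids)
        sub = ai_records[ai_records["subject_id"].isin(members)]
        for region in family:
            ai = sub.loc[sub["region_name"] == region, "ai"].to_numpy()
            row = {
                "region_name": region,
                "measure_kind": measure_kind,
                "window_index": w_idx,
                "start_month": w.start_month,
                "end_month": w.end_month,
                "midpoint": w.midpoint,
                "n": len(ai),
                "mean_ai": float(np.mean(ai)) if len(ai) else np.nan,
                "w_statistic": np.nan,
                "p_value": np.nan,
            }
            if w.testable and len(ai) >= MIN_TESTABLE_N and np.any(ai != 0):
                W, p = wilcoxon_signed_rank(ai)
                row["w_statistic"], row["p_value"] = W, p
            rows.append(row)
    out = pd.DataFrame(rows)

    out["q_value"] = np.nan
    group_col = "window_index" if fdr_family == "per-window" else "region_name"
    for _, idx in out.groupby(group_col).groups.items():
        block = out.loc[idx]
        ok = block["p_value"].notna()
        if ok.any():
            out.loc[block.index[ok], "q_value"] = fdr_adjust(
                block.loc[ok, "p_value"].to_numpy()
            )
    sig = out["q_value"] <= alpha
    out["direction"] = "none"
    out.loc[sig & (out["mean_ai"] > 0), "direction"] = "left"
    out.loc[sig & (out["mean_ai"] < 0), "direction"] = "right"
    out.attrs["alpha"] = alpha
    return out


def detect_emergence(window_results: pd.DataFrame, alpha: float | None = None) -> pd.DataFrame:
    """Earliest significantly lateralized window per region.

    Scans windows in increasing midpoint order; the first window with
    ``q <= alpha`` sets the initial point (its midpoint) and the asymmetry
    direction (sign of its mean AI).  Regions with no significant window
    report NA.
    """
    if alpha is None:
        alpha = window_results.attrs.get("alpha", 0.05)
    rows = []
    for (region, kind), block in window_results.groupby(
        ["region_name", "measure_kind"], sort=True
    ):
        block = block.sort_values("midpoint")
        hit = block[(block["q_value"].notna()) & (block["q_value"] <= alpha)]
        if len(hit):
            first = hit.iloc[0]
            rows.append(
                {
                    "region_name": region,
                    "measure_kind": kind,
                    "asymmetry_direction": "left" if first["mean_ai"] > 0 else "right",
                    "initial_point_months": float(first["midpoint"]),
                    "q_at_initial_point": float(first["q_value"]),
                }
            )
        else:
            rows.append(
                {
                    "region_name": region,
                    "measure_kind": kind,
                    "asymmetry_direction": "NA",
                    "initial_point_months": np.nan,
                    "q_at_initial_point": np.nan,
                }
            )
    return pd.DataFrame(rows)


def population_average_asymmetry(ai_records: pd.DataFrame) -> pd.DataFrame:
    """Cohort-mean AI per region and measure with a left/right direction label."""
    out = (
        ai_records.groupby(["region_name", "measure_kind"])["ai"]
        .agg(mean_ai="mean", n="count")
        .reset_index()
    )
    out["direction"] = np.select(
        [out["mean_ai"] > 0, out["mean_ai"] < 0], ["left", "right"], default="none"
    )
    return out.sort_values(["measure_kind", "region_name"]).reset_index(drop=True)
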