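"""End-to-end orchestration: ingest -> QC -> normalize -> trajectories ->
asymmetry emergence -> report tables.

Every stage writes its artifact eagerly under the output directory as
tab-separated text, together with the resolved configuration, so runs are
reproducible byte-for-byte from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import CohortTable
from .gam import SmoothSpec, fit_all_regions, group_anova_lsd
from .io import qc_outlier_flags, read_cohort_table, read_freesurfer_tree, write_cohort_table
from .normalization import compute_asymmetry, normalize_cohort
from .simulate import GeneratorConfig, simulate_cohort
from .windows import build_windows, detect_emergence, population_average_asymmetry, test_windows

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_demographics"]

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    input_path: str | None = None  # long table or FreeSurfer tree; None -> simulate
    input_format: str = "long"  # long | freesurfer_tree | simulate
    generator: GeneratorConfig | None = None
    normalization: str = "relative"  # relative | absolute
    ai_scale: str = "absolute"
    smooth: SmoothSpec = field(default_factory=SmoothSpec)
    window_width: float = 12.0
    window_stride: float = 1.0
    window_min_n: int = 5
    window_convention: str = "half_open"
    alpha: float = 0.05
    fdr_family: str = "per-window"
    qc_z_threshold: float = 3.0
    qc_exclude: bool = False
    outdir: str = "frontolimbic_run"
    seed: int = 0
    fit_trajectories: bool = True

    def validate(self):
        if self.normalization not in ("relative", "absolute"):
            raise ValueError("normalization must be relative|absolute")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.window_width <= 0 or self.window_stride <= 0:
            raise ValueError("window width/stride must be positive")
        if self.input_format not in ("long", "freesurfer_tree", "simulate"):
            raise ValueError(f"unknown input_format {self.input_format!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    demographics: pd.DataFrame
    qc_flags: pd.DataFrame
    trajectory_fits: pd.DataFrame
    emergence: pd.DataFrame
    window_tests: pd.DataFrame
    population_asymmetry: pd.DataFrame
    config_fingerprint: str
    outdir: Path


def make_demographics(cohort: CohortTable) -> pd.DataFrame:
    """Per age-group descriptives with omnibus ANOVA and an LSD ordering string.

    One row per numeric variable (age, eTIV) plus a sex-count row; the
    ordering string (e.g. ``1 < 2 < 3``) is emitted when every adjacent
    age-ordered LSD comparison is significant in order.
    """
    subj = cohort.subjects
    groups = sorted(subj["age_group"].unique())
    rows = []
    for var in ("age_months", "etiv"):
        row = {"variable": var}
        for g in groups:
            vals = subj.loc[subj["age_group"] == g, var]
            row[f"group{g}"] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f} (n={len(vals)})"
        if len(groups) >= 2 and all(
            (subj["age_group"] == g).sum() >= 2 for g in groups
        ):
            F, p, pairwise = group_anova_lsd(subj[var], subj["age_group"])
            row["anova_p"] = f"{p:.4g}"
            ordered = all(
                pairwise[(a, b)]["p"] < 0.05 and pairwise[(a, b)]["diff"] < 0
                for a, b in zip(groups[:-1], groups[1:])
            )
            row["lsd_ordering"] = (
                " < ".join(str(g) for g in groups) if ordered else ""
            )
        else:
            row["anova_p"] = ""
            row["lsd_ordering"] = "tests suppressed (single group)"
        rows.append(row)
    sex_row = {"variable": "male_n_pct"}
    for g in groups:
        cell = subj[subj["age_group"] == g]
        nm = int((cell["sex"] == "male").sum())
        sex_row[f"group{g}"] = f"{nm} ({100 * nm / len(cell):.1f}%)"
    sex_row["anova_p"] = ""
    sex_row["lsd_ordering"] = ""
    rows.append(sex_row)
    return pd.DataFrame(rows)


def _load_cohort(cfg: PipelineConfig):
    if cfg.input_format == "simulate" or cfg.input_path is None:
        gen = cfg.generator if cfg.generator is not None else GeneratorConfig()
        cohort, truth = simulate_cohort(gen, seed=cfg.seed)
        return cohort, truth
    if cfg.input_format == "freesurfer_tree":
        return read_freesurfer_tree(cfg.input_path), None
    return read_cohort_table(cfg.input_path), None


def _fits_table(fits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_name": f.region_name,
                "hemisphere": f.hemisphere,
                "measure_kind": f.measure_kind,
                "n": f.n,
                "edf": round(f.edf, 4),
                "f_stat": round(f.f_stat, 4) if np.isfinite(f.f_stat) else np.inf,
                "p_value": f.p_value,
                "q_value": f.q_value,
                "selected_model": f.selected_model,
                "bic_intercept": round(f.bic_by_model["intercept"], 3),
                "bic_linear": round(f.bic_by_model["linear"], 3),
                "bic_smooth": round(f.bic_by_model["smooth"], 3),
                "sex_coefficient": f.sex_coefficient,
            }
            for f in fits
        ]
    ).sort_values(["measure_kind", "region_name", "hemisphere"]).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; artifacts land under ``config.outdir``."""
    cfg = config
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, truth = _load_cohort(cfg)
    write_cohort_table(cohort, outdir / "cohort.tsv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")

    qc = qc_outlier_flags(cohort, z_threshold=cfg.qc_z_threshold)
    qc.to_csv(outdir / "qc_flags.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    if cfg.qc_exclude and len(qc):
        keys = set(map(tuple, qc[["subject_id", "region_name", "hemisphere",
                                  "measure_kind"]].itertuples(index=False)))
        keep = ~cohort.measures.apply(
            lambda r: (r["subject_id"], r["region_name"], r["hemisphere"],
                       r["measure_kind"]) in keys, axis=1)
        cohort = CohortTable(cohort.subjects, cohort.measures[keep],
                             provenance=cohort.provenance + "+qc_excluded",
                             registry=cohort.registry)

    demo = make_demographics(cohort)
    demo.to_csv(outdir / "demographics.tsv", sep="\t", index=False)

    normalized = normalize_cohort(cohort, mode=cfg.normalization)
    normalized.to_csv(outdir / "normalized.tsv", sep="\t", index=False,
                      float_format="%.8g")

    all_fits = []
    if cfg.fit_trajectories:
        for kind in ("volume_mm3", "thickness_mm"):
            fits, failures = fit_all_regions(
                cohort, kind, spec=cfg.smooth, mode=cfg.normalization
            )
            all_fits.extend(fits)
    fits_tbl = _fits_table(all_fits) if all_fits else pd.DataFrame()
    fits_tbl.to_csv(outdir / "trajectory_fits.tsv", sep="\t", index=False,
                    float_format="%.6g")
    if all_fits:
        curves = pd.concat(
            [
                f.fitted_curve.assign(
                    region_name=f.region_name, hemisphere=f.hemisphere,
                    measure_kind=f.measure_kind
                )
                for f in all_fits
            ]
        )
        curves.to_csv(outdir / "trajectory_curves.tsv", sep="\t", index=False,
                      float_format="%.6g")

    ai = compute_asymmetry(cohort, scale=cfg.ai_scale)
    ai.to_csv(outdir / "asymmetry_index.tsv", sep="\t", index=False,
              float_format="%.8g")
    pop = population_average_asymmetry(ai)
    pop.to_csv(outdir / "population_asymmetry.tsv", sep="\t", index=False,
               float_format="%.6g")

    windows = build_windows(
        cohort.subjects["age_months"].to_numpy(),
        cohort.subjects["subject_id"].to_numpy(),
        width=cfg.window_width,
        stride=cfg.window_stride,
        min_n=cfg.window_min_n,
        convention=cfg.window_convention,
    )
    window_parts, emergence_parts = [], []
    for kind in ("volume_mm3", "thickness_mm"):
        block = ai[ai["measure_kind"] == kind]
        if not len(block):
            continue
        family = cohort.registry.family(kind)
        wt = test_windows(block, windows, cohort.subjects, alpha=cfg.alpha,
                          family=family, fdr_family=cfg.fdr_family)
        window_parts.append(wt)
        emergence_parts.append(detect_emergence(wt, alpha=cfg.alpha))
    window_tests = pd.concat(window_parts, ignore_index=True) if window_parts else pd.DataFrame()
    emergence = pd.concat(emergence_parts, ignore_index=True) if emergence_parts else pd.DataFrame()
    window_tests.to_csv(outdir / "window_tests.tsv", sep="\t", index=False,
                        float_format="%.6g")
    emergence.to_csv(outdir / "emergence.tsv", sep="\t", index=False,
                     float_format="%.6g")

    resolved = cfg.to_dict()
    resolved.pop("outdir", None)  # keep resolved config location-independent
    cfg_text = yaml.safe_dump(resolved, sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_text)
    fingerprint = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    (outdir / "run.json").write_text(
        json.dumps(
            {
                "package": "frontolimbic",
                "version": __version__,
                "config_fingerprint": fingerprint,
                "n_subjects": int(cohort.n_subjects),
                "n_measures": int(len(cohort.measures)),
                "n_qc_flags": int(len(qc)),
            },
            indent=1,
        )
    )
    return RunReport(
        demographics=demo,
        qc_flags=qc,
        trajectory_fits=fits_tbl,
        emergence=emergence,
        window_tests=window_tests,
        population_asymmetry=pop,
        config_fingerprint=fingerprint,
        outdir=outdir,
    )
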