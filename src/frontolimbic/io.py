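"""Readers and writers for FreeSurfer-style stats files and long cohort tables.

FreeSurfer regional statistics come as whitespace-delimited text with ``#``
comment headers: ``aseg.stats``-like files carry subcortical volumes
(``Volume_mm3`` column, hemisphere encoded in the label), ``aparc.stats``-like
files are per-hemisphere cortical tables with ``GrayVol`` and ``ThickAvg``
columns.  Cohorts also round-trip through a long-format delimited table with
columns (subject, age_months, sex, etiv, region, hemisphere, measure, value).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MEASURE_COLUMNS,
    SUBJECT_COLUMNS,
    CohortTable,
    RegionalMeasure,
)
from .regions import RegionRegistry, load_registry

__all__ = [
    "read_freesurfer_stats",
    "read_freesurfer_subject_dir",
    "read_freesurfer_tree",
    "read_cohort_table",
    "write_cohort_table",
    "qc_outlier_flags",
]

_ETIV_TOKEN = "EstimatedTotalIntraCranialVol"
_MEANTHICK_TOKEN = "MeanThickness"


def _parse_stats_text(path: Path):
    """Split a FreeSurfer stats file into header-measure lines, column names, rows."""
    header_measures: dict[str, float] = {}
    colheaders: list[str] | None = None
    hemi: str | None = None
    rows: list[list[str]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("ColHeaders"):
                colheaders = body.split()[1:]
            elif body.startswith("hemi"):
                token = body.split()[-1]
                hemi = {"lh": "left", "rh": "right"}.get(token, None)
            elif body.startswith("Measure"):
                parts = [p.strip() for p in body[len("Measure"):].split(",")]
                # e.g. Measure EstimatedTotalIntraCranialVol, eTIV, ..., 1.2e6, mm^3
                for numeric in parts[::-1]:
                    try:
                        val = float(numeric)
                    except ValueError:
                        continue
                    header_measures[body] = val
                    break
            continue
        if line.strip():
            rows.append(line.split())
    return header_measures, colheaders, hemi, rows


def read_freesurfer_stats(
    path,
    subject_id: str,
    hemisphere: str | None = None,
    registry: RegionRegistry | None = None,
):
    """Parse one aseg- or aparc-style stats file.

    Parameters
    ----------
    path
        Stats file ('#'-comment header, whitespace-delimited rows).
    subject_id
        Subject the file belongs to.
    hemisphere
        ``"left"``/``"right"`` for aparc-style files; inferred from a
        ``# hemi lh|rh`` header line when present.
    registry
        Region registry used for alias resolution; defaults to the packaged one.

    Returns
    -------
    (measures, header) : (list of RegionalMeasure, dict)
        ``header`` holds ``etiv`` and/or ``mean_thickness`` when the file
        declares them.  Rows whose label has no registry alias are skipped
        with a warning.
    """
    registry = registry if registry is not None else load_registry()
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    header_measures, colheaders, file_hemi, rows = _parse_stats_text(path)
    hemisphere = hemisphere or file_hemi
    if colheaders is None:
        raise ValueError(f"{path}: no '# ColHeaders' line")
    idx = {name: i for i, name in enumerate(colheaders)}

    header: dict[str, float] = {}
    for key, val in header_measures.items():
        if _ETIV_TOKEN in key:
            header["etiv"] = val
        elif _MEANTHICK_TOKEN in key:
            header["mean_thickness"] = val

    name_col = idx.get("StructName")
    if name_col is None:
        raise ValueError(f"{path}: no StructName column")

    measures: list[RegionalMeasure] = []
    for row in rows:
        label = row[name_col]
        resolved = None
        try:
            resolved = registry.resolve_alias(label, hemisphere)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        if resolved is None:
            warnings.warn(f"{path}: unmapped region label {label!r}, row skipped")
            continue
        name, hemi = resolved
        for col, kind in (("Volume_mm3", "volume_mm3"),
                          ("GrayVol", "volume_mm3"),
                          ("ThickAvg", "thickness_mm")):
            if col not in idx:
                continue
            value = float(row[idx[col]])
            if value < 0:
                raise ValueError(f"{path}: negative {col} for {label!r}")
            measures.append(RegionalMeasure(subject_id, name, hemi, kind, value))
    return measures, header


def read_freesurfer_subject_dir(subject_dir, subject_id: str | None = None,
                                registry: RegionRegistry | None = None):
    """Read ``aseg.stats``, ``lh.aparc.stats`` and ``rh.aparc.stats`` from one
    subject directory (``stats/`` subdirectory honoured when present).

    Returns ``(measures, header)`` with per-hemisphere mean thickness stored
    as ``mean_thickness_left`` / ``mean_thickness_right``.
    """
    subject_dir = Path(subject_dir)
    subject_id = subject_id or subject_dir.name
    stats_dir = subject_dir / "stats" if (subject_dir / "stats").is_dir() else subject_dir
    measures: list[RegionalMeasure] = []
    header: dict[str, float] = {}
    aseg = stats_dir / "aseg.stats"
    if aseg.is_file():
        m, h = read_freesurfer_stats(aseg, subject_id, registry=registry)
        measures += m
        header.update(h)
    for hemi, fname in (("left", "lh.aparc.stats"), ("right", "rh.aparc.stats")):
        f = stats_dir / fname
        if f.is_file():
            m, h = read_freesurfer_stats(f, subject_id, hemisphere=hemi, registry=registry)
            measures += m
            if "mean_thickness" in h:
                header[f"mean_thickness_{hemi}"] = h["mean_thickness"]
            if "etiv" in h:
                header.setdefault("etiv", h["etiv"])
    return measures, header


def read_freesurfer_tree(root, registry: RegionRegistry | None = None) -> CohortTable:
    """Assemble a cohort from a FreeSurfer-style output tree.

    ``root`` must contain a ``participants.tsv`` metadata table (subject_id,
    age_months, sex, etiv optional) plus one directory per subject with
    aseg/aparc stats files.  Per-hemisphere MeanThickness headers become
    ``mean_thickness`` measures; eTIV in participants.tsv takes precedence
    over the stats-file header.
    """
    root = Path(root)
    meta_path = root / "participants.tsv"
    if not meta_path.is_file():
        raise FileNotFoundError(f"{meta_path}: participants metadata required")
    meta = pd.read_csv(meta_path, sep="\t")
    all_measures = []
    etivs = {}
    for sid in meta["subject_id"]:
        sdir = root / str(sid)
        if not sdir.is_dir():
            warnings.warn(f"missing subject directory {sdir}, skipped")
            continue
        measures, header = read_freesurfer_subject_dir(sdir, str(sid), registry=registry)
        all_measures.extend(measures)
        for hemi in ("left", "right"):
            key = f"mean_thickness_{hemi}"
            if key in header:
                all_measures.append(
                    RegionalMeasure(str(sid), "mean_thickness", hemi,
                                    "thickness_mm", header[key])
                )
        if "etiv" in header:
            etivs[str(sid)] = header["etiv"]
    if "etiv" not in meta.columns:
        meta["etiv"] = meta["subject_id"].astype(str).map(etivs)
    subjects = meta[[c for c in SUBJECT_COLUMNS if c in meta.columns]]
    return CohortTable(subjects, all_measures, provenance=str(root), registry=registry)


_LONG_COLUMNS = ["subject_id", "age_months", "sex", "etiv", "age_group",
                 "region_name", "hemisphere", "measure_kind", "value"]


def read_cohort_table(path, sep: str = "\t",
                      registry: RegionRegistry | None = None) -> CohortTable:
    """Read a validated cohort from a long-format delimited file."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    required = set(_LONG_COLUMNS) - {"age_group"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    subj_cols = [c for c in SUBJECT_COLUMNS if c in df.columns]
    subjects = df[subj_cols].drop_duplicates("subject_id").reset_index(drop=True)
    measures = df[MEASURE_COLUMNS].reset_index(drop=True)
    return CohortTable(subjects, measures, provenance=str(path), registry=registry)


def write_cohort_table(cohort: CohortTable, path, sep: str = "\t") -> Path:
    """Write a cohort as one long-format delimited table (inverse of
    :func:`read_cohort_table`)."""
    path = Path(path)
    df = cohort.measures.merge(cohort.subjects, on="subject_id", how="left")
    df = df[_LONG_COLUMNS]
    df.to_csv(path, sep=sep, index=False)
    return path


def qc_outlier_flags(cohort: CohortTable, z_threshold: float = 3.0) -> pd.DataFrame:
    """Population-level outlier flags per (region, hemisphere, measure) cell.

    Every value whose absolute z-score against its cell's cohort mean/SD
    exceeds ``z_threshold`` is flagged.  Flags are advisory — reported, not
    auto-excluded.  Zero-variance cells produce no flags (with a warning).
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    out = []
    grouped = cohort.measures.groupby(["region_name", "hemisphere", "measure_kind"])
    for (region, hemi, kind), cell in grouped:
        if len(cell) < 3:
            warnings.warn(f"QC cell {region}/{hemi}/{kind}: <3 subjects, skipped")
            continue
        sd = cell["value"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"QC cell {region}/{hemi}/{kind}: zero variance, no flags")
            continue
        z = (cell["value"] - cell["value"].mean()) / sd
        hits = cell.loc[z.abs() > z_threshold]
        for i, row in hits.iterrows():
            out.append(
                {
                    "subject_id": row["subject_id"],
                    "region_name": region,
                    "hemisphere": hemi,
                    "measure_kind": kind,
                    "z_score": float(z.loc[i]),
                }
            )
    cols = ["subject_id", "region_name", "hemisphere", "measure_kind", "z_score"]
    return pd.DataFrame(out, columns=cols)
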