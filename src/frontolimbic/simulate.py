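"""Synthetic pediatric morphometry cohorts with known ground truth.

The generator emulates the structure of an MRI-derived regional morphometry
study of preschool-aged children: 57 subjects aged 14-71 months (41 male),
eTIV growing with age, 11 paired fronto-limbic regions with left/right volume
(plus thickness for the 8 cortical regions), regional mean trajectories that
are linear, logarithmic or quadratic in age, and hemisphere-lateralized
effects that switch on smoothly at a configurable onset age.

For a region with bilateral mean trajectory ``m(age)`` and lateralization
ramp ``a(age) = delta * smoothstep((age - T)/width)``::

    left  = m(age) * s_subj * (1 + a(age)) + eps_L
    right = m(age) * s_subj * (1 - a(age)) + eps_R

so the noiseless asymmetry index equals ``a(age)`` exactly; the per-subject
size factor ``s_subj`` cancels in the AI but contributes realistic
between-subject variance to trajectory fits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CohortTable, default_age_group
from .io import write_cohort_table

__all__ = [
    "TrajectorySpec",
    "LateralizationSpec",
    "RegionSim",
    "GeneratorConfig",
    "GroundTruth",
    "simulate_cohort",
    "write_fixture",
    "default_region_specs",
]

TABLE_GROUP_COUNTS = (7, 15, 14, 11, 10)  # year-of-age strata 1..5


@dataclass(frozen=True)
class TrajectorySpec:
    """Bilateral mean trajectory m(age) for one region/measure.

    forms: constant ``c``; linear ``c + b*age``; logarithmic ``c +
    b*log(age)``; quadratic ``c - curv*(age - peak)**2`` (peak in months).
    """

    form: str
    c: float
    b: float = 0.0
    peak: float = 0.0
    curv: float = 0.0

    def __post_init__(self):
        if self.form not in ("constant", "linear", "logarithmic", "quadratic"):
            raise ValueError(f"unknown trajectory form {self.form!r}")

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        if self.form == "constant":
            return np.full_like(age, self.c)
        if self.form == "linear":
            return self.c + self.b * age
        if self.form == "logarithmic":
            return self.c + self.b * np.log(age)
        return self.c - self.curv * (age - self.peak) ** 2

    @property
    def is_linear(self) -> bool:
        return self.form in ("constant", "linear")

    def typical(self, age: float = 40.0) -> float:
        """Representative magnitude (value at a mid-range age), used to scale
        proportional noise."""
        return float(abs(self(age)))


@dataclass(frozen=True)
class LateralizationSpec:
    """Smooth onset of asymmetry: AI ramps from 0 to ``delta`` over
    [onset, onset + width] via a cubic smoothstep."""

    onset: float  # months
    delta: float  # plateau AI; positive = left-ward
    width: float = 12.0

    def __post_init__(self):
        if not -1 < self.delta < 1:
            raise ValueError("delta must lie in (-1, 1)")
        if self.width <= 0:
            raise ValueError("ramp width must be positive")

    def __call__(self, age):
        t = np.clip((np.asarray(age, dtype=float) - self.onset) / self.width, 0.0, 1.0)
        return self.delta * t * t * (3.0 - 2.0 * t)


_NO_LAT = LateralizationSpec(onset=0.0, delta=0.0)


@dataclass(frozen=True)
class RegionSim:
    name: str
    volume: TrajectorySpec
    thickness: TrajectorySpec | None = None
    volume_lat: LateralizationSpec = _NO_LAT
    thickness_lat: LateralizationSpec = _NO_LAT


def default_region_specs() -> list[RegionSim]:
    """Eleven fronto-limbic regions with realistic magnitudes and mixed
    trajectory shapes; lateralization directions/onsets follow the observed
    childhood pattern (left-ward rostral ACC, STG, fusiform, thalamus;
    right-ward caudal ACC, PCC, medial OFC, IPC; none in lateral OFC,
    hippocampus, amygdala volume)."""

    def logv(scale):  # logarithmic volume growth, ~16% across the age range
        b = 0.10 * scale
        return TrajectorySpec("logarithmic", c=scale - b * math.log(40.0), b=b)

    def linv(scale):  # linear volume growth, ~20% across the age range
        b = 0.20 * scale / 57.0
        return TrajectorySpec("linear", c=scale - b * 40.0, b=b)

    def lint(level, total_change):  # linear thickness change across 14-71 mo
        b = total_change / 57.0
        return TrajectorySpec("linear", c=level - b * 40.0, b=b)

    def logt(level, total_change):  # logarithmic thickness change
        b = total_change / math.log(71.0 / 14.0)
        return TrajectorySpec("logarithmic", c=level - b * math.log(40.0), b=b)

    L = LateralizationSpec
    return [
        RegionSim("rostralanteriorcingulate", logv(2500),
                  thickness=logt(2.95, -0.15),
                  volume_lat=L(19.5, +0.10)),
        RegionSim("caudalanteriorcingulate",
                  TrajectorySpec("quadratic", c=2100, peak=66.0,
                                 curv=0.10 * 2100 / 52.0**2),
                  thickness=lint(2.85, -0.10),
                  volume_lat=L(25.5, -0.10)),
        RegionSim("posteriorcingulate", logv(3000),
                  thickness=lint(2.90, -0.10),
                  volume_lat=L(32.5, -0.10), thickness_lat=L(40.5, +0.05)),
        RegionSim("medialorbitofrontal", logv(4500),
                  thickness=logt(2.80, -0.20),
                  volume_lat=L(33.5, -0.10)),
        RegionSim("lateralorbitofrontal", logv(6500),
                  thickness=logt(2.75, -0.15)),
        RegionSim("superiortemporal", logv(10000),
                  thickness=lint(2.95, +0.10),
                  volume_lat=L(25.5, +0.10)),
        RegionSim("inferiorparietal", logv(11000),
                  thickness=lint(2.75, -0.10),
                  volume_lat=L(19.5, -0.10), thickness_lat=L(21.5, +0.05)),
        RegionSim("fusiform", logv(8500),
                  thickness=lint(2.85, -0.05),
                  volume_lat=L(28.5, +0.10), thickness_lat=L(27.5, +0.05)),
        RegionSim("thalamus", linv(6500), volume_lat=L(23.5, +0.10)),
        RegionSim("hippocampus", linv(3500)),
        RegionSim("amygdala", linv(1500)),
    ]


def planted_lateralization_config(onset: float, delta: float = 0.15,
                                  seed: int = 0, alternate_sign: bool = True,
                                  **kwargs) -> "GeneratorConfig":
    """Generator config with the same lateralization onset planted in every
    region (volume and thickness), for emergence-recovery experiments.

    With ``alternate_sign`` the planted direction alternates across regions so
    both left- and right-ward detection are exercised.
    """
    import dataclasses as _dc

    specs = []
    for i, rs in enumerate(default_region_specs()):
        d = delta if (not alternate_sign or i % 2 == 0) else -delta
        lat = LateralizationSpec(onset, d)
        specs.append(_dc.replace(rs, volume_lat=lat, thickness_lat=lat))
    return GeneratorConfig(region_specs=specs, seed=seed, **kwargs)


@dataclass
class GeneratorConfig:
    n_subjects: int = 57
    age_min: int = 14
    age_max: int = 71
    male_fraction: float = 41 / 57
    stratified_ages: bool = False  # year-of-age strata with counts 7/15/14/11/10
    etiv_baseline: float = 1.0e6  # mm^3 at age 0
    etiv_slope: float = 2500.0  # mm^3 per month
    etiv_sd: float = 5.0e4
    subject_scale_sd: float = 0.08  # lognormal per-subject size factor
    residual_frac: float = 0.05  # hemisphere noise SD as fraction of region scale
    thickness_residual_mm: float = 0.08
    mean_thickness: TrajectorySpec = field(
        default_factory=lambda: TrajectorySpec(
            "logarithmic", c=2.85 - (-0.25 / math.log(71 / 14)) * math.log(40.0),
            b=-0.25 / math.log(71 / 14))
    )
    region_specs: list = field(default_factory=default_region_specs)
    n_outliers: int = 0  # value-level outlier injection
    outlier_z: float = 8.0
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.age_min <= 0 or self.age_max <= self.age_min:
            raise ValueError("require 0 < age_min < age_max")
        if self.residual_frac < 0 or self.subject_scale_sd < 0 or self.etiv_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for rs in self.region_specs:
            if rs.volume.form == "quadratic":
                span = self.age_max - self.age_min
                if not (self.age_min - span <= rs.volume.peak <= self.age_max + span):
                    raise ValueError(f"{rs.name}: quadratic peak far outside age range")


@dataclass
class GroundTruth:
    """Serialized generator truth for recovery scoring."""

    regions: dict  # name -> {volume: {...}, thickness: {...}|None}
    config: dict

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"regions": self.regions, "config": self.config}, indent=1,
            default=str))

    def direction(self, region: str, measure_kind: str) -> str:
        key = "volume" if measure_kind.startswith("volume") else "thickness"
        delta = self.regions[region][key]["lat_delta"]
        return "left" if delta > 0 else ("right" if delta < 0 else "none")


def _draw_ages(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.stratified_ages:
        ages = []
        for g, count in enumerate(TABLE_GROUP_COUNTS, start=1):
            lo = max(cfg.age_min, 12 * g + 2) if g == 1 else 12 * g
            hi = min(cfg.age_max, 12 * (g + 1) - 1)
            ages.extend(rng.integers(lo, hi + 1, size=count))
        return np.array(sorted(ages))
    return np.sort(rng.integers(cfg.age_min, cfg.age_max + 1, size=cfg.n_subjects))


def simulate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None):
    """Generate one cohort; returns ``(CohortTable, GroundTruth)``.

    ``seed`` overrides ``config.seed``.  Identical seeds give identical
    cohorts; values are rounded to 4 decimals (eTIV to 2) so that the text
    fixture writers round-trip exactly.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    ages = _draw_ages(cfg, rng)
    n = len(ages)
    n_male = int(round(cfg.male_fraction * n))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    sex = sex[rng.permutation(n)]
    etiv = cfg.etiv_baseline + cfg.etiv_slope * ages + rng.normal(0, cfg.etiv_sd, n)
    etiv = np.maximum(etiv, 1e5).round(2)
    scale = np.exp(rng.normal(0.0, cfg.subject_scale_sd, n))
    ids = [f"sub-{i + 1:03d}" for i in range(n)]

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "age_months": ages.astype(float),
            "sex": sex,
            "etiv": etiv,
            "age_group": [default_age_group(a) for a in ages],
        }
    )

    rows = []
    truth_regions = {}
    for rs in cfg.region_specs:
        entry = {}
        for measure_kind, traj, lat, sd in (
            ("volume_mm3", rs.volume, rs.volume_lat,
             cfg.residual_frac * rs.volume.typical()),
            ("thickness_mm", rs.thickness, rs.thickness_lat, cfg.thickness_residual_mm),
        ):
            if traj is None:
                entry["thickness"] = None
                continue
            m = traj(ages) * scale
            a = lat(ages)
            left = m * (1 + a) + rng.normal(0, sd, n)
            right = m * (1 - a) + rng.normal(0, sd, n)
            left = np.maximum(left, 1e-4).round(4)
            right = np.maximum(right, 1e-4).round(4)
            for i in range(n):
                rows.append((ids[i], rs.name, "left", measure_kind, left[i]))
                rows.append((ids[i], rs.name, "right", measure_kind, right[i]))
            key = "volume" if measure_kind == "volume_mm3" else "thickness"
            entry[key] = {
                "form": traj.form,
                "params": asdict(traj),
                "is_linear": traj.is_linear,
                "lat_onset": lat.onset,
                "lat_delta": lat.delta,
                "lat_width": lat.width,
            }
        entry.setdefault("thickness", None)
        truth_regions[rs.name] = entry

    # hemisphere mean cortical thickness (FreeSurfer MeanThickness analogue)
    for hemi in ("left", "right"):
        mt = cfg.mean_thickness(ages) * 1.0 + rng.normal(0, 0.02, n)
        mt = np.maximum(mt, 0.5).round(4)
        for i in range(n):
            rows.append((ids[i], "mean_thickness", hemi, "thickness_mm", mt[i]))

    measures = pd.DataFrame(
        rows, columns=["subject_id", "region_name", "hemisphere", "measure_kind", "value"]
    )

    if cfg.n_outliers > 0:
        roi = measures.index[measures["region_name"] != "mean_thickness"]
        picks = rng.choice(roi, size=min(cfg.n_outliers, len(roi)), replace=False)
        for idx in picks:
            kind = measures.loc[idx, "measure_kind"]
            region = measures.loc[idx, "region_name"]
            spec = next(r for r in cfg.region_specs if r.name == region)
            sd = (cfg.residual_frac * spec.volume.typical() if kind == "volume_mm3"
                  else cfg.thickness_residual_mm)
            measures.loc[idx, "value"] = round(
                measures.loc[idx, "value"] + cfg.outlier_z * sd, 4)

    cohort = CohortTable(subjects, measures, provenance=f"synthetic(seed={cfg.seed if seed is None else seed})")
    truth = GroundTruth(regions=truth_regions, config={
        "n_subjects": n, "age_min": cfg.age_min, "age_max": cfg.age_max,
        "male_fraction": cfg.male_fraction, "seed": cfg.seed if seed is None else seed,
    })
    return cohort, truth


# ---------------------------------------------------------------------------
# fixture writers


def _aseg_text(cohort: CohortTable, subject_id: str) -> str:
    subj = cohort.subjects.set_index("subject_id").loc[subject_id]
    meas = cohort.measures
    sub = meas[
        (meas["subject_id"] == subject_id)
        & (meas["measure_kind"] == "volume_mm3")
        & (meas["region_name"].map(lambda r: cohort.registry[r].tissue_class == "subcortical"))
    ]
    lines = [
        "# Title Segmentation Statistics",
        f"# subjectname {subject_id}",
        f"# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, {subj['etiv']:.2f}, mm^3",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean",
    ]
    label = {"thalamus": "Thalamus-Proper", "amygdala": "Amygdala",
             "hippocampus": "Hippocampus"}
    idx = 1
    for _, row in sub.sort_values(["region_name", "hemisphere"]).iterrows():
        name = f"{'Left' if row['hemisphere'] == 'left' else 'Right'}-{label[row['region_name']]}"
        lines.append(
            f"{idx:3d} {10 + idx:4d} {int(row['value']):8d} {row['value']:12.4f} {name:<28s} 100.0"
        )
        idx += 1
    return "\n".join(lines) + "\n"


def _aparc_text(cohort: CohortTable, subject_id: str, hemi: str) -> str:
    meas = cohort.measures
    sub = meas[
        (meas["subject_id"] == subject_id)
        & (meas["hemisphere"] == hemi)
        & (meas["region_name"].map(lambda r: cohort.registry[r].tissue_class == "cortical"))
    ]
    wide = sub.pivot_table(index="region_name", columns="measure_kind",
                           values="value", aggfunc="first")
    mt = meas[
        (meas["subject_id"] == subject_id)
        & (meas["hemisphere"] == hemi)
        & (meas["region_name"] == "mean_thickness")
    ]["value"]
    lines = [
        "# Title Parcellation Statistics",
        f"# subjectname {subject_id}",
        f"# hemi {'lh' if hemi == 'left' else 'rh'}",
    ]
    if len(mt):
        lines.append(
            f"# Measure Cortex, MeanThickness, Mean Thickness, {float(mt.iloc[0]):.4f}, mm"
        )
    lines.append("# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd")
    for region, row in wide.sort_index().iterrows():
        vol = row.get("volume_mm3", np.nan)
        thk = row.get("thickness_mm", np.nan)
        nvert = max(int(vol / 3) if np.isfinite(vol) else 1000, 1)
        area = vol / 2.5 if np.isfinite(vol) else 400.0
        lines.append(
            f"{region:<28s} {nvert:7d} {area:9.1f} {vol:10.4f} {thk:7.4f} 0.500"
        )
    return "\n".join(lines) + "\n"


def write_fixture(cohort: CohortTable, outdir, format: str = "long_csv") -> Path:
    """Write a cohort as an on-disk fixture.

    ``long_csv``: one TSV (``cohort.tsv``).  ``freesurfer_stats_tree``: a
    per-subject tree of aseg/aparc-style stats files plus a
    ``participants.tsv`` metadata table.  Output is bit-stable for a fixed
    generator seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "long_csv":
        return write_cohort_table(cohort, outdir / "cohort.tsv")
    if format != "freesurfer_stats_tree":
        raise ValueError(f"unknown fixture format {format!r}")
    cohort.subjects.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    for sid in cohort.subjects["subject_id"]:
        stats_dir = outdir / sid / "stats"
        stats_dir.mkdir(parents=True, exist_ok=True)
        (stats_dir / "aseg.stats").write_text(_aseg_text(cohort, sid))
        (stats_dir / "lh.aparc.stats").write_text(_aparc_text(cohort, sid, "left"))
        (stats_dir / "rh.aparc.stats").write_text(_aparc_text(cohort, sid, "right"))
    return outdir
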