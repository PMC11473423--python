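"""Cohort data model: subject metadata and regional morphometry measures.

A cohort couples a subject table (id, age in months, sex, estimated total
intracranial volume, age group) with a long table of regional measurements,
one row per (subject, region, hemisphere, measure kind).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionRegistry, load_registry

__all__ = [
    "SubjectRecord",
    "RegionalMeasure",
    "CohortTable",
    "default_age_group",
    "MEASURE_KINDS",
    "HEMISPHERES",
]

MEASURE_KINDS = ("volume_mm3", "thickness_mm")
HEMISPHERES = ("left", "right")

MEASURE_COLUMNS = ["subject_id", "region_name", "hemisphere", "measure_kind", "value"]
SUBJECT_COLUMNS = ["subject_id", "age_months", "sex", "etiv", "age_group"]


def default_age_group(age_months: float) -> int:
    """Year-of-age group, clamped to 1..5 (14 months -> group 1, 71 -> group 5)."""
    return int(np.clip(np.floor(age_months / 12.0), 1, 5))


@dataclass(frozen=True)
class SubjectRecord:
    """One child's metadata."""

    subject_id: str
    age_months: float
    sex: str  # "male" | "female"
    etiv: float  # mm^3
    age_group: int | None = None

    def __post_init__(self):
        if self.age_months <= 0:
            raise ValueError(f"{self.subject_id}: age_months must be positive")
        if self.etiv <= 0:
            raise ValueError(f"{self.subject_id}: etiv must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.subject_id}: sex must be 'male' or 'female'")
        if self.age_group is None:
            object.__setattr__(self, "age_group", default_age_group(self.age_months))


@dataclass(frozen=True)
class RegionalMeasure:
    """One (subject, region, hemisphere, measure kind) value in native units."""

    subject_id: str
    region_name: str
    hemisphere: str
    measure_kind: str
    value: float

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if self.measure_kind not in MEASURE_KINDS:
            raise ValueError(f"bad measure_kind {self.measure_kind!r}")
        if self.value < 0:
            raise ValueError(
                f"negative value for {self.subject_id}/{self.region_name}"
                f"/{self.hemisphere}/{self.measure_kind}"
            )


class CohortTable:
    """Subjects plus their regional measures, with validated invariants.

    Parameters
    ----------
    subjects
        DataFrame with columns subject_id, age_months, sex, etiv, age_group —
        or a list of :class:`SubjectRecord`.
    measures
        DataFrame with columns subject_id, region_name, hemisphere,
        measure_kind, value — or a list of :class:`RegionalMeasure`.
    provenance
        Free-text description of where the table came from.
    """

    def __init__(self, subjects, measures, provenance: str = "",
                 registry: RegionRegistry | None = None):
        self.registry = registry if registry is not None else load_registry()
        self.provenance = provenance
        self.subjects = self._coerce_subjects(subjects)
        self.measures = self._coerce_measures(measures)
        self._validate()

    @staticmethod
    def _coerce_subjects(subjects) -> pd.DataFrame:
        if isinstance(subjects, pd.DataFrame):
            df = subjects.copy()
            if "age_group" not in df.columns:
                df["age_group"] = df["age_months"].map(default_age_group)
        else:
            df = pd.DataFrame(
                [
                    {
                        "subject_id": s.subject_id,
                        "age_months": s.age_months,
                        "sex": s.sex,
                        "etiv": s.etiv,
                        "age_group": s.age_group,
                    }
                    for s in subjects
                ]
            )
        return df[SUBJECT_COLUMNS].reset_index(drop=True)

    @staticmethod
    def _coerce_measures(measures) -> pd.DataFrame:
        if isinstance(measures, pd.DataFrame):
            df = measures.copy()
        else:
            df = pd.DataFrame(
                [
                    {
                        "subject_id": m.subject_id,
                        "region_name": m.region_name,
                        "hemisphere": m.hemisphere,
                        "measure_kind": m.measure_kind,
                        "value": m.value,
                    }
                    for m in measures
                ]
            )
        return df[MEASURE_COLUMNS].reset_index(drop=True)

    def _validate(self):
        subj = self.subjects
        if subj["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in subject table")
        if (subj["age_months"] <= 0).any() or (subj["etiv"] <= 0).any():
            raise ValueError("age_months and etiv must be positive")
        bad_sex = set(subj["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")

        meas = self.measures
        if len(meas):
            key = ["subject_id", "region_name", "hemisphere", "measure_kind"]
            dup = meas.duplicated(key)
            if dup.any():
                rows = meas.loc[dup, key].head(3).to_dict("records")
                raise ValueError(f"duplicate measure keys, e.g. {rows}")
            unknown_subj = set(meas["subject_id"]) - set(subj["subject_id"])
            if unknown_subj:
                raise ValueError(f"measures reference unknown subjects {sorted(unknown_subj)[:3]}")
            if (meas["value"] < 0).any():
                raise ValueError("negative measurement values")
            unknown_reg = {
                r for r in meas["region_name"].unique() if r not in self.registry
            }
            if unknown_reg:
                raise ValueError(f"regions not in registry: {sorted(unknown_reg)[:5]}")
            thick = meas[meas["measure_kind"] == "thickness_mm"]
            bad = {
                r
                for r in thick["region_name"].unique()
                if self.registry[r].tissue_class == "subcortical"
            }
            if bad:
                raise ValueError(f"thickness reported for subcortical regions: {sorted(bad)}")

    # -- convenience ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def incomplete_pairs(self) -> pd.DataFrame:
        """(subject, region, measure) cells present for only one hemisphere.

        Such subjects are excluded per-region from asymmetry-index computation
        but retained for unilateral trajectory fits.
        """
        counts = (
            self.measures.groupby(["subject_id", "region_name", "measure_kind"])[
                "hemisphere"
            ]
            .nunique()
            .reset_index(name="n_hemi")
        )
        return counts[counts["n_hemi"] < 2].reset_index(drop=True)

    def merged(self) -> pd.DataFrame:
        """Measures joined with subject metadata (one row per measurement)."""
        return self.measures.merge(self.subjects, on="subject_id", how="left")

    def __repr__(self):
        return (
            f"CohortTable(n_subjects={self.n_subjects}, "
            f"n_measures={len(self.measures)}, provenance={self.provenance!r})"
        )
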