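"""Desikan-Killiany region registry and the fronto-limbic region subset.

The cerebral cortex is parcellated into 34 gyral-based regions per hemisphere
(68 cortical labels).  The analyses in this package focus on 11 paired
fronto-limbic structures: three subcortical (thalamus, amygdala, hippocampus)
and eight cortical (rostral and caudal anterior cingulate, posterior
cingulate, medial and lateral orbitofrontal, superior temporal, inferior
parietal, fusiform).  The registry is shipped as a versioned TSV resource;
FreeSurfer output labels map onto canonical names through an alias table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ir

import pandas as pd

__all__ = ["RegionRegistry", "RegionEntry", "load_registry", "FRONTOLIMBIC_REGIONS"]

#: Canonical names of the 11 paired fronto-limbic regions (8 cortical + 3 subcortical).
FRONTOLIMBIC_REGIONS = (
    "rostralanteriorcingulate",
    "caudalanteriorcingulate",
    "posteriorcingulate",
    "medialorbitofrontal",
    "lateralorbitofrontal",
    "superiortemporal",
    "inferiorparietal",
    "fusiform",
    "thalamus",
    "amygdala",
    "hippocampus",
)

# FreeSurfer aseg.stats labels carry hemisphere in the label itself.
_ASEG_ALIASES = {
    "Left-Thalamus": ("thalamus", "left"),
    "Left-Thalamus-Proper": ("thalamus", "left"),
    "Right-Thalamus": ("thalamus", "right"),
    "Right-Thalamus-Proper": ("thalamus", "right"),
    "Left-Amygdala": ("amygdala", "left"),
    "Right-Amygdala": ("amygdala", "right"),
    "Left-Hippocampus": ("hippocampus", "left"),
    "Right-Hippocampus": ("hippocampus", "right"),
}


@dataclass(frozen=True)
class RegionEntry:
    name: str
    tissue_class: str  # cortical | subcortical | summary
    in_frontolimbic_set: bool


class RegionRegistry:
    """Lookup table of paired region names with tissue class and ROI membership.

    Each entry is a *paired* name resolving to exactly one left and one right
    measurement; hemisphere is carried by the measurement, not the registry.
    """

    def __init__(self, entries: list[RegionEntry]):
        self._entries = {e.name: e for e in entries}
        if len(self._entries) != len(entries):
            raise ValueError("duplicate region names in registry")

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> RegionEntry:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def cortical_names(self) -> list[str]:
        return [e.name for e in self if e.tissue_class == "cortical"]

    @property
    def subcortical_names(self) -> list[str]:
        return [e.name for e in self if e.tissue_class == "subcortical"]

    @property
    def n_cortical_labels(self) -> int:
        """Number of cortical labels counting both hemispheres (34 pairs -> 68)."""
        return 2 * len(self.cortical_names)

    def frontolimbic(self, tissue_class: str | None = None) -> list[str]:
        """Names in the fronto-limbic set, optionally restricted by tissue class."""
        return [
            e.name
            for e in self
            if e.in_frontolimbic_set
            and (tissue_class is None or e.tissue_class == tissue_class)
        ]

    def family(self, measure_kind: str) -> list[str]:
        """The multiple-testing family for a measure.

        Thickness is defined only on the cortex, so its family is the 8
        cortical fronto-limbic pairs; volume spans all 11 pairs.
        """
        if measure_kind == "thickness_mm":
            return self.frontolimbic("cortical")
        return self.frontolimbic()

    def resolve_alias(self, label: str, hemisphere: str | None = None):
        """Map a FreeSurfer stats label to ``(canonical_name, hemisphere)``.

        aseg labels (``Left-Thalamus-Proper``) encode hemisphere; aparc labels
        (``rostralanteriorcingulate``) rely on the caller-supplied hemisphere.
        Returns ``None`` for labels with no registry alias.
        """
        if label in _ASEG_ALIASES:
            return _ASEG_ALIASES[label]
        if label in self._entries and self._entries[label].tissue_class == "cortical":
            if hemisphere not in ("left", "right"):
                raise ValueError(f"cortical label {label!r} needs an explicit hemisphere")
            return label, hemisphere
        return None


def load_registry() -> RegionRegistry:
    """Load the packaged Desikan-Killiany registry (34 cortical pairs + subcortical)."""
    with _ir.files("frontolimbic.resources").joinpath("dk_registry.tsv").open() as fh:
        tbl = pd.read_csv(fh, sep="\t")
    entries = [
        RegionEntry(r["name"], r["tissue_class"], bool(r["frontolimbic"]))
        for _, r in tbl.iterrows()
    ]
    return RegionRegistry(entries)
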