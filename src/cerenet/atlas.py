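"""ROI template definition for amyloid-PET regional analysis.

The pipeline operates on two compartments of the AAL116 parcellation:

* ``cerebellar`` — the 26 cerebellar labels (9 bilateral lobule pairs plus
  8 vermis labels), the primary compartment of interest;
* ``cortical`` — 72 cerebral labels covering the frontal, temporal and
  parietal cortices plus the precuneus, i.e. the regions with the highest
  amyloid burden in Alzheimer's disease.

The cortical selection is expressed as exclusion rules on the cerebral
labels (occipital-proper regions and deep grey nuclei are dropped) so that
users with a different authoritative ROI list can override it while the
compartment counts stay validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AAL116_LABELS",
    "RoiTemplate",
    "build_roi_template",
    "default_template",
]

# Bilateral cerebral label stems in standard AAL order (L before R).
_CEREBRAL_STEMS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

_CEREBELLAR_STEMS = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]

_VERMIS_LABELS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]

#: The full ordered AAL116 label list (90 cerebral + 26 cerebellar labels).
AAL116_LABELS: tuple[str, ...] = tuple(
    [f"{stem}_{side}" for stem in _CEREBRAL_STEMS for side in ("L", "R")]
    + [f"{stem}_{side}" for stem in _CEREBELLAR_STEMS for side in ("L", "R")]
    + _VERMIS_LABELS
)

# Default cortical exclusion: occipital-proper cortex and deep grey nuclei.
# Lingual stays with the occipitotemporal group.  45 - 9 pairs -> 72 labels.
DEFAULT_CORTICAL_EXCLUDE: tuple[str, ...] = (
    "Calcarine", "Cuneus", "Occipital_Sup", "Occipital_Mid", "Occipital_Inf",
    "Caudate", "Putamen", "Pallidum", "Thalamus",
)

CEREBELLAR = "cerebellar"
CORTICAL = "cortical"


@dataclass(frozen=True)
class RoiTemplate:
    """Ordered ROI labels with their compartment tags.

    Parameters
    ----------
    names
        Unique ROI labels, order is significant and preserved everywhere.
    compartments
        Per-ROI tag, ``"cerebellar"`` or ``"cortical"``.
    atlas_source
        Free-text provenance of the parcellation.
    """

    names: tuple[str, ...]
    compartments: tuple[str, ...]
    atlas_source: str = "AAL116"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.compartments):
            raise ValueError("names and compartments must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI names must be unique")
        bad = set(self.compartments) - {CEREBELLAR, CORTICAL}
        if bad:
            raise ValueError(f"unknown compartment tags: {sorted(bad)}")
        # every compartment present must have at least 2 ROIs (correlation
        # networks need >= 2 nodes); single-compartment templates are fine
        for tag in set(self.compartments):
            if self.compartments.count(tag) < 2:
                raise ValueError(f"need at least 2 {tag} ROIs, "
                                 f"got {self.compartments.count(tag)}")
        if not self.compartments:
            raise ValueError("template is empty")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def cerebellar_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.compartments)
                     if c == CEREBELLAR)

    @property
    def cortical_names(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(self.names, self.compartments)
                     if c == CORTICAL)

    def compartment_names(self, compartment: str) -> tuple[str, ...]:
        if compartment == CEREBELLAR:
            return self.cerebellar_names
        if compartment == CORTICAL:
            return self.cortical_names
        raise ValueError(f"unknown compartment {compartment!r}")

    def subset(self, names: list[str] | tuple[str, ...]) -> "RoiTemplate":
        """Template restricted to *names*, keeping this template's order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"ROIs not in template: {sorted(missing)}")
        pairs = [(n, c) for n, c in zip(self.names, self.compartments)
                 if n in keep]
        return RoiTemplate(tuple(n for n, _ in pairs),
                           tuple(c for _, c in pairs),
                           atlas_source=self.atlas_source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.names,
                             "compartment": self.compartments})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, atlas_source: str = "file") -> "RoiTemplate":
        df = pd.read_csv(path)
        if not {"label", "compartment"} <= set(df.columns):
            raise ValueError("template CSV needs 'label' and 'compartment' "
                             "columns")
        return cls(tuple(df["label"].astype(str)),
                   tuple(df["compartment"].astype(str)),
                   atlas_source=atlas_source)


@dataclass
class SelectionRules:
    """Rules carving cerebellar/cortical compartments from an atlas list."""

    cerebellar_prefixes: tuple[str, ...] = ("Cerebelum_", "Vermis_")
    cortical_exclude_stems: tuple[str, ...] = DEFAULT_CORTICAL_EXCLUDE
    expected_counts: dict = field(
        default_factory=lambda: {CEREBELLAR: 26, CORTICAL: 72})
    enforce_counts: bool = True


def _stem(label: str) -> str:
    for side in ("_L", "_R"):
        if label.endswith(side):
            return label[: -len(side)]
    return label


def build_roi_template(
    atlas_labels: list[str] | tuple[str, ...] | None = None,
    rules: SelectionRules | None = None,
) -> RoiTemplate:
    """Build the two-compartment ROI template from a full atlas label list.

    With the default AAL116 labels and default rules this yields exactly
    26 cerebellar and 72 cortical ROIs.

    Raises
    ------
    ValueError
        If a rule matches zero labels, or (when ``enforce_counts``) the
        compartment sizes differ from the expected counts.
    """
    labels = list(atlas_labels) if atlas_labels is not None else list(AAL116_LABELS)
    if not labels:
        raise ValueError("atlas label list is empty")
    rules = rules or SelectionRules()
    if not rules.cerebellar_prefixes:
        raise ValueError("selection rules match zero cerebellar labels: "
                         "no cerebellar prefixes configured")

    exclude = set(rules.cortical_exclude_stems)
    names: list[str] = []
    tags: list[str] = []
    for lab in labels:
        if any(lab.startswith(p) for p in rules.cerebellar_prefixes):
            names.append(lab)
            tags.append(CEREBELLAR)
        elif _stem(lab) not in exclude:
            names.append(lab)
            tags.append(CORTICAL)
    for tag in (CEREBELLAR, CORTICAL):
        if tags.count(tag) == 0:
            raise ValueError(f"selection rules match zero {tag} labels")

    template = RoiTemplate(tuple(names), tuple(tags))
    if rules.enforce_counts:
        for tag, want in rules.expected_counts.items():
            got = tags.count(tag)
            if got != want:
                raise ValueError(
                    f"{tag} compartment has {got} ROIs, expected {want}; "
                    "adjust SelectionRules or set enforce_counts=False")
    return template


def default_template() -> RoiTemplate:
    """The standard 26-cerebellar + 72-cortical AAL116 template."""
    return build_roi_template()
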