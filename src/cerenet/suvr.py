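"""SUVR tables: computation from regional uptake, IO and group summaries.

The standardized uptake value ratio (SUVR) of a region is its mean tracer
uptake divided by the mean uptake of the whole pons, the reference region:

    SUVR[s, r] = SUV_roi[s, r] / SUV_whole_pons[s]

SUVR is dimensionless and strictly positive; values above 1 simply mean
higher uptake than the pons and are legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RoiTemplate

__all__ = ["SuvrMatrix", "UptakeTable", "compute_suvr", "load_suvr_table",
           "summarize_group_suvr"]

SUBJECT_COL = "subject_id"
VALID_CORRECTIONS = ("none", "PVEc-GTM")


@dataclass
class SuvrMatrix:
    """Subjects x ROIs table of SUVR values.

    ``values`` is a DataFrame indexed by subject ID with one column per ROI,
    columns aligned to ``template.names`` order.  ``correction`` is
    provenance only ("none" or "PVEc-GTM"); the package performs no
    partial-volume computation.
    """

    values: pd.DataFrame
    template: RoiTemplate
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.correction not in VALID_CORRECTIONS:
            raise ValueError(f"correction must be one of {VALID_CORRECTIONS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject IDs: {dups}")
        missing = set(self.template.names) - set(self.values.columns)
        if missing:
            raise ValueError(f"missing ROI columns: {sorted(missing)}")
        extra = set(self.values.columns) - set(self.template.names)
        if extra:
            raise ValueError(f"unknown ROI columns: {sorted(extra)}")
        # canonical column order
        self.values = self.values.loc[:, list(self.template.names)]
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite SUVR at subject {self.values.index[r]!r}, "
                f"ROI {self.values.columns[c]!r}")
        if (arr <= 0).any():
            r, c = np.argwhere(arr <= 0)[0]
            raise ValueError(
                f"non-positive SUVR at subject {self.values.index[r]!r}, "
                f"ROI {self.values.columns[c]!r}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def compartment_values(self, compartment: str) -> pd.DataFrame:
        return self.values.loc[:, list(self.template.compartment_names(compartment))]

    def subset_subjects(self, ids) -> "SuvrMatrix":
        return SuvrMatrix(self.values.loc[list(ids)].copy(), self.template,
                          self.correction)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = SUBJECT_COL
        out.to_csv(path)


@dataclass
class UptakeTable:
    """Regional mean uptake (SUV) plus the per-subject whole-pons SUV."""

    roi_uptake: pd.DataFrame           # subjects x ROIs mean SUV
    pons_uptake: pd.Series             # per-subject whole-pons mean SUV
    template: RoiTemplate = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.roi_uptake.index.equals(self.pons_uptake.index):
            raise ValueError("roi_uptake and pons_uptake subject IDs differ")
        if not np.isfinite(self.roi_uptake.to_numpy(dtype=float)).all():
            raise ValueError("non-finite regional uptake value")
        if not np.isfinite(self.pons_uptake.to_numpy(dtype=float)).all():
            raise ValueError("non-finite pons uptake value")


def compute_suvr(uptake: UptakeTable, correction: str = "none") -> SuvrMatrix:
    """Divide each subject's regional uptake by that subject's pons uptake.

    Raises
    ------
    ValueError
        Naming the subject, if a pons uptake is zero or negative.
    """
    pons = uptake.pons_uptake.astype(float)
    bad = pons[pons <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive pons uptake for subject {bad.index[0]!r}")
    values = uptake.roi_uptake.astype(float).div(pons, axis=0)
    template = uptake.template
    if template is None:
        raise ValueError("UptakeTable has no ROI template attached")
    return SuvrMatrix(values, template, correction=correction)


def load_suvr_table(path, template: RoiTemplate,
                    correction: str = "none") -> SuvrMatrix:
    """Read a SUVR CSV (``subject_id`` column + one column per ROI).

    Column order in the file is irrelevant; columns are reordered to the
    template.  Missing or unknown ROI columns, duplicate subjects and
    non-numeric or non-positive cells raise ``ValueError``.
    """
    df = pd.read_csv(path)
    if SUBJECT_COL not in df.columns:
        raise ValueError(f"SUVR table needs a {SUBJECT_COL!r} column")
    df = df.set_index(SUBJECT_COL)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric SUVR cell: {exc}") from exc
    return SuvrMatrix(df, template, correction=correction)


def summarize_group_suvr(suvr: SuvrMatrix, labels: pd.Series,
                         compartment: str = "cerebellar") -> pd.DataFrame:
    """Per-group summary of the per-subject compartment-mean SUVR.

    For each subject the mean SUVR over the compartment's ROIs is taken;
    the returned frame gives, per group, the mean, SD, median and quartiles
    of those per-subject means (the layout used for baseline tables).

    Raises
    ------
    ValueError
        If labels do not cover all subjects or a group has < 2 subjects.
    """
    labels = labels.reindex(suvr.values.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"no group label for subjects: {missing}")
    per_subject = suvr.compartment_values(compartment).mean(axis=1)
    rows = {}
    for group, vals in per_subject.groupby(labels):
        if len(vals) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects")
        rows[group] = {
            "n": len(vals),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1),
            "median": vals.median(),
            "q1": vals.quantile(0.25),
            "q3": vals.quantile(0.75),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out["n"] = out["n"].astype(int)
    return out
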