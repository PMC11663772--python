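"""Core tabular containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["FeatureSet", "Cohort", "CLINICAL_COLUMNS"]

CLINICAL_COLUMNS = ("subject_id", "group", "hdrs_baseline", "hdrs_followup")


@dataclass
class FeatureSet:
    """A named subjects x elements matrix.

    ``data`` is indexed by subject id; column names are element labels
    (region, region pair, or directed network pair).  Constructed tables
    contain no missing values and unique labels.
    """

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise SchemaError(f"feature set {self.name!r}: duplicate element label {dup!r}")
        if self.data.index.duplicated().any():
            raise SchemaError(f"feature set {self.name!r}: duplicate subject ids")
        if self.data.isna().any().any():
            col = self.data.columns[self.data.isna().any()][0]
            raise SchemaError(f"feature set {self.name!r}: missing values in element {col!r}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_elements(self) -> int:
        return self.data.shape[1]

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def element_labels(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    def loc_subjects(self, subject_ids) -> "FeatureSet":
        missing = [s for s in subject_ids if s not in self.data.index]
        if missing:
            raise SchemaError(
                f"feature set {self.name!r}: unknown subject id {missing[0]!r}"
            )
        return FeatureSet(self.name, self.data.loc[list(subject_ids)])


@dataclass
class Cohort:
    """Clinical table: one row per subject.

    Columns: ``subject_id``, ``group`` (two levels), ``hdrs_baseline`` and
    ``hdrs_followup`` on the 0-52 HDRS scale (follow-up may be missing,
    e.g. for controls that were only assessed at baseline).
    """

    clinical: pd.DataFrame
    groups: tuple = field(default=None)

    def __post_init__(self) -> None:
        for col in CLINICAL_COLUMNS:
            if col not in self.clinical.columns:
                raise SchemaError(f"clinical table is missing column {col!r}")
        ids = self.clinical["subject_id"]
        if ids.duplicated().any():
            raise SchemaError(
                f"clinical table: duplicate subject_id {ids[ids.duplicated()].iloc[0]!r}"
            )
        for col in ("hdrs_baseline", "hdrs_followup"):
            v = self.clinical[col].dropna()
            if ((v < 0) | (v > 52)).any():
                raise SchemaError(f"clinical table: {col} outside the 0-52 HDRS range")
        if self.groups is None:
            self.groups = tuple(pd.unique(self.clinical["group"]))

    @property
    def subject_ids(self) -> list:
        return list(self.clinical["subject_id"])

    def labels(self, positive_group: str) -> np.ndarray:
        """0/1 vector with 1 for ``positive_group``."""
        if positive_group not in set(self.clinical["group"]):
            raise SchemaError(f"unknown group {positive_group!r}")
        return (self.clinical["group"] == positive_group).to_numpy().astype(np.int64)
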