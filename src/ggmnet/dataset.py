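"""Subjects x (region, modality) feature tables.

A :class:`RegionalDataset` holds one continuous value per subject, region and
imaging modality (e.g. mean amyloid tracer uptake, glucose metabolism and gray
matter volume per atlas region), together with the per-subject covariates used
for normalization (age in years, gender coded 0/1, education in years) and a
diagnosis label.  Value columns are named ``<region>_<modality>`` and the
on-disk representation is a plain tab-separated table, one row per subject:

    subject_id  diagnosis  age  gender  education  roi01_amy  roi01_metab ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

COVARIATE_COLUMNS = ("age", "gender", "education")
META_COLUMNS = ("subject_id", "diagnosis") + COVARIATE_COLUMNS


def node_name(region: str, modality: str) -> str:
    return f"{region}_{modality}"


def split_node_name(name: str) -> tuple[str, str]:
    """Split ``<region>_<modality>`` on the last underscore."""
    region, _, modality = name.rpartition("_")
    if not region or not modality:
        raise SchemaError(f"value column {name!r} is not of the form <region>_<modality>")
    return region, modality


@dataclass
class RegionalDataset:
    """Subjects x nodes value table with covariates and diagnosis labels."""

    subject_ids: list[str]
    diagnosis: np.ndarray
    covariates: pd.DataFrame
    values: pd.DataFrame
    node_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(self.diagnosis) != n or len(self.covariates) != n or len(self.values) != n:
            raise SchemaError("subject_ids, diagnosis, covariates and values disagree in length")
        missing = [c for c in COVARIATE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise SchemaError(f"covariate table lacks columns {missing}")
        if not self.node_labels:
            self.node_labels = [split_node_name(c) for c in self.values.columns]
        if len(self.node_labels) != self.values.shape[1]:
            raise SchemaError("node_labels do not match the value-table column count")
        if self.values.isna().any().any() or self.covariates[list(COVARIATE_COLUMNS)].isna().any().any():
            raise SchemaError("dataset contains missing values")

    # ------------------------------------------------------------------ basic
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def node_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def modalities(self) -> list[str]:
        seen: list[str] = []
        for _, m in self.node_labels:
            if m not in seen:
                seen.append(m)
        return seen

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.diagnosis:
            if g not in seen:
                seen.append(g)
        return seen

    # -------------------------------------------------------------- selection
    def subset(self, labels: str | Sequence[str]) -> "RegionalDataset":
        """Rows whose diagnosis is in ``labels`` (order preserved)."""
        if isinstance(labels, str):
            labels = [labels]
        mask = np.isin(self.diagnosis, list(labels))
        if not mask.any():
            raise SchemaError(f"no subjects with diagnosis in {list(labels)}")
        return RegionalDataset(
            subject_ids=[s for s, m in zip(self.subject_ids, mask) if m],
            diagnosis=self.diagnosis[mask],
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            values=self.values.loc[mask].reset_index(drop=True),
            node_labels=list(self.node_labels),
        )

    def modality_columns(self, modality: str) -> list[str]:
        cols = [node_name(r, m) for r, m in self.node_labels if m == modality]
        if not cols:
            raise SchemaError(f"unknown modality {modality!r}; have {self.modalities}")
        return cols

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "RegionalDataset":
        """Same subjects/covariates with a replaced value table (e.g. W-scores)."""
        vals = pd.DataFrame(np.asarray(values), columns=self.values.columns)
        return RegionalDataset(
            subject_ids=list(self.subject_ids),
            diagnosis=self.diagnosis.copy(),
            covariates=self.covariates.copy().reset_index(drop=True),
            values=vals,
            node_labels=list(self.node_labels),
        )

    # --------------------------------------------------------------------- io
    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "diagnosis": self.diagnosis,
                "age": self.covariates["age"].to_numpy(),
                "gender": self.covariates["gender"].to_numpy(),
                "education": self.covariates["education"].to_numpy(),
            }
        )
        return pd.concat([meta, self.values.reset_index(drop=True)], axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RegionalDataset":
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"table lacks required columns {missing}")
        value_cols = [c for c in frame.columns if c not in META_COLUMNS]
        if not value_cols:
            raise SchemaError("table has no value columns")
        return cls(
            subject_ids=[str(s) for s in frame["subject_id"]],
            diagnosis=frame["diagnosis"].to_numpy(dtype=object),
            covariates=frame[list(COVARIATE_COLUMNS)].astype(float).reset_index(drop=True),
            values=frame[value_cols].astype(float).reset_index(drop=True),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionalDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def write_matrix_tsv(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Square labelled matrix as TSV (labels both as header and first column)."""
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t", index_label="node"
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise SchemaError(f"{path}: row and column labels differ")
    return frame.to_numpy(dtype=float), list(frame.columns)
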