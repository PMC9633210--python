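"""Core data containers shared across the pipeline.

Matrices are pandas DataFrames (samples in rows, features in columns) wrapped
with an omics ``kind`` tag; missing values are NaN.  Survival data live in a
validated per-sample table of follow-up time (days) and event indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: recognised omics kinds
KINDS = (
    "mrna_counts",
    "mirna_counts",
    "methylation_beta",
    "methylation_promoter",
    "expression_intensity",
    "latent",
    "stacked",
)

COUNT_KINDS = ("mrna_counts", "mirna_counts")
METHYLATION_KINDS = ("methylation_beta", "methylation_promoter")


class OmiprogError(ValueError):
    """Base error for invalid inputs or configuration."""


@dataclass
class OmicsMatrix:
    """Sample-by-feature numeric matrix for one omics layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are samples, columns are features.  NaN marks a missing cell.
    kind : str
        One of :data:`KINDS`.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise OmiprogError(f"unknown omics kind {self.kind!r}; expected one of {KINDS}")
        if self.values.index.has_duplicates:
            raise OmiprogError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise OmiprogError("duplicate feature ids")
        if self.kind in METHYLATION_KINDS:
            vals = self.values.to_numpy(dtype=float)
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed.min() < 0 or observed.max() > 1):
                raise OmiprogError(f"{self.kind} values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, kind: str | None = None) -> "OmicsMatrix":
        return OmicsMatrix(values=values, kind=self.kind if kind is None else kind)

    def to_numpy(self, dtype=float) -> np.ndarray:
        return self.values.to_numpy(dtype=dtype)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event status and optional clinical covariates."""

    data: pd.DataFrame  # index = sample ids; columns: time, event [, covariates]

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise OmiprogError("survival table needs 'time' and 'event' columns")
        if self.data.index.has_duplicates:
            raise OmiprogError("duplicate sample ids in survival table")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise OmiprogError("survival times must be positive and finite")
        if not np.all(np.isin(e, (0.0, 1.0))):
            raise OmiprogError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def loc(self, sample_ids: Iterable) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneAnnotation:
    """Gene TSS annotation: gene_id, chromosome, tss (1-based), strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "tss", "strand"}
        if not required.issubset(self.table.columns):
            raise OmiprogError(f"gene annotation needs columns {sorted(required)}")
        if (self.table["tss"] < 1).any():
            raise OmiprogError("tss positions must be >= 1")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise OmiprogError("strand must be '+' or '-'")


@dataclass
class CpGAnnotation:
    """CpG probe annotation: probe_id, chromosome, position (1-based)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chromosome", "position"}
        if not required.issubset(self.table.columns):
            raise OmiprogError(f"CpG annotation needs columns {sorted(required)}")
        if (self.table["position"] < 1).any():
            raise OmiprogError("positions must be >= 1")


@dataclass
class SyntheticCohort:
    """A simulated multiomics cohort with known subgroup ground truth."""

    mrna: OmicsMatrix
    mirna: OmicsMatrix
    methylation_cpg: OmicsMatrix
    gene_annotation: GeneAnnotation
    cpg_annotation: CpGAnnotation
    survival: SurvivalTable
    clinical: pd.DataFrame
    true_labels: pd.Series  # per-sample integer group
    #: generative parameters (per-gene means, signal offsets) kept for external-cohort
    #: simulation and for tests against ground truth
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.mrna.sample_ids
        for other in (self.mirna.sample_ids, self.methylation_cpg.sample_ids,
                      self.survival.sample_ids, self.true_labels.index):
            if not ids.equals(pd.Index(other)):
                raise OmiprogError("all cohort tables must share the same ordered sample ids")


def check_aligned(matrix: OmicsMatrix | pd.DataFrame, surv: SurvivalTable) -> None:
    ids = matrix.sample_ids if isinstance(matrix, OmicsMatrix) else matrix.index
    if not pd.Index(ids).equals(surv.sample_ids):
        raise OmiprogError("samples of matrix and survival table are not aligned")
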