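"""Core in-memory containers shared across the pipeline.

Expression and ratio matrices are thin wrappers around a pandas DataFrame
(rows = features, columns = subjects) carrying the transform state, so that
downstream stages can refuse inputs on the wrong scale.  Clinical cohorts are
plain DataFrames with a fixed column contract (see ``CLINICAL_COLUMNS``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RatioMatrix",
    "GeneSet",
    "GeneSetCollection",
    "NullCalibration",
    "GroupThresholds",
    "CLINICAL_COLUMNS",
    "SchemaError",
    "validate_cohort",
]

#: required columns of a clinical cohort table
CLINICAL_COLUMNS = ("subject_id", "days_to_death", "event", "stage")

NORMALIZED = "normalized"
LOG2P4 = "log2p4"


class SchemaError(ValueError):
    """An input table violates its declared schema."""


@dataclass
class ExpressionMatrix:
    """Features x subjects abundance matrix with a declared transform state.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with subject IDs as columns.
    transform_state
        ``"normalized"`` for non-negative normalized abundances, or
        ``"log2p4"`` after the log2(x+4) transform (all values >= 2).
    """

    values: pd.DataFrame
    transform_state: str = NORMALIZED

    def __post_init__(self) -> None:
        if self.transform_state not in (NORMALIZED, LOG2P4):
            raise SchemaError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate feature IDs")
        if self.values.columns.has_duplicates:
            raise SchemaError("duplicate subject IDs")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise SchemaError("expression values must be finite")
        if self.transform_state == NORMALIZED and arr.size and arr.min() < 0:
            raise SchemaError("negative values in a normalized expression matrix")
        if self.transform_state == LOG2P4 and arr.size and arr.min() < 2.0 - 1e-12:
            raise SchemaError("log2p4 matrix contains values below the 2.0 floor")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_subjects(self, subjects: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(subjects)])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, transform_state: str = NORMALIZED) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, transform_state=transform_state)


@dataclass
class RatioMatrix:
    """Anchor/gene ratio matrix on the log2(x+4) scale.

    Row ``i`` holds ``log2p4(anchor) / log2p4(gene_i)`` per subject; the anchor
    row itself is excluded.  All entries are strictly positive because the
    transform bounds both numerator and denominator below by 2.
    """

    values: pd.DataFrame
    anchor_feature_id: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.isfinite(arr).all() or arr.min() <= 0):
            raise SchemaError("ratio entries must be finite and > 0")
        if self.anchor_feature_id in self.values.index:
            raise SchemaError("anchor row must be excluded from the ratio matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = f"feature_id[anchor={self.anchor_feature_id}]"
        out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets, GMT-writable."""

    sets: list[GeneSet] = field(default_factory=list)
    universe: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate gene-set IDs")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class GroupThresholds:
    """HRz cut points separating the two significant tails from 'ns'."""

    lower: float
    upper: float
    source: str = "fixed_2"  # "empirical" | "fixed_2"

    def __post_init__(self) -> None:
        if not (self.lower < 0 < self.upper):
            raise ValueError("thresholds must satisfy lower < 0 < upper")


@dataclass
class NullCalibration:
    """Summary of the Monte Carlo HRz null distribution.

    ``hrz_samples`` pools the standardized statistics across all iterations;
    ``fp_rate_at_2`` is the pooled fraction with \\|HRz\\| > 2, while
    ``per_iteration_fp`` holds the per-replicate fractions whose mean is the
    quantity the screening procedure reports as its average false-positive
    rate at the fixed +/-2 boundaries.
    """

    n_iterations: int
    hrz_samples: np.ndarray
    q025: float
    q975: float
    fp_rate_at_2: float
    per_iteration_fp: np.ndarray
    normality_p: float
    seed: int

    @property
    def fp_rate_mean(self) -> float:
        return float(np.mean(self.per_iteration_fp))

    def thresholds(self, source: str = "empirical") -> GroupThresholds:
        if source == "empirical":
            return GroupThresholds(self.q025, self.q975, source="empirical")
        if source in ("fixed_2", "fixed2"):
            return GroupThresholds(-2.0, 2.0, source="fixed_2")
        raise ValueError(f"unknown threshold source {source!r}")

    def to_dict(self) -> dict:
        return {
            "n_iterations": int(self.n_iterations),
            "q025": float(self.q025),
            "q975": float(self.q975),
            "fp_rate_at_2": float(self.fp_rate_at_2),
            "fp_rate_mean": self.fp_rate_mean,
            "per_iteration_fp": [float(x) for x in self.per_iteration_fp],
            "normality_p": float(self.normality_p),
            "n_pooled": int(self.hrz_samples.size),
            "seed": int(self.seed),
        }


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical table contract and coerce dtypes.

    Requires columns ``subject_id``, ``days_to_death``, ``event``, ``stage``;
    days must be integers, events booleans, subject IDs unique.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    out = cohort.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    if out["subject_id"].duplicated().any():
        raise SchemaError("duplicate subject IDs in clinical table")
    days = pd.to_numeric(out["days_to_death"], errors="raise")
    if not np.allclose(days, np.round(days)):
        raise SchemaError("days_to_death must be integer-valued")
    out["days_to_death"] = days.astype(int)
    out["event"] = out["event"].astype(bool)
    out["stage"] = out["stage"].astype(str)
    return out
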