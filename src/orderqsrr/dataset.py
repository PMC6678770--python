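"""Retention–descriptor tables and elution ranks.

A retention dataset holds, for ``n`` analytes, an identifier, a vector of
``K`` molecular-descriptor values and an experimental retention time
``t_R`` (minutes, strictly positive — the relative-error metric divides by
it). Elution order is the rank of an analyte's retention time within the
set, 1 = earliest eluting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromatographicCondition",
    "RetentionDataset",
    "TableSchema",
    "read_retention_table",
    "sort_by_retention",
    "elution_ranks",
    "write_predictions",
]


class DatasetError(ValueError):
    """Raised when a retention table violates a dataset invariant."""


@dataclass(frozen=True)
class ChromatographicCondition:
    """Chromatographic run metadata: column, gradient time t_G, temperature T."""

    column_name: str = ""
    gradient_time_tG: float | None = None  # minutes
    temperature_T: float | None = None  # degrees Celsius

    def __post_init__(self) -> None:
        if self.gradient_time_tG is not None and not self.gradient_time_tG > 0:
            raise DatasetError("gradient_time_tG must be > 0 when given")
        if self.temperature_T is not None and not self.temperature_T > 0:
            raise DatasetError("temperature_T must be > 0 when given")

    def label(self) -> str:
        parts = []
        if self.gradient_time_tG is not None:
            parts.append(f"tG = {self.gradient_time_tG:g} min")
        if self.temperature_T is not None:
            parts.append(f"T = {self.temperature_T:g} C")
        return ", ".join(parts)


@dataclass(frozen=True)
class RetentionDataset:
    """Analyte ids, descriptor matrix ``X`` (n×K) and retention times ``y``."""

    ids: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    descriptor_names: tuple[str, ...]
    condition: ChromatographicCondition = field(
        default_factory=ChromatographicCondition
    )

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        n = len(self.ids)
        if n < 1:
            raise DatasetError("dataset must contain at least one analyte")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DatasetError(f"duplicate analyte ids: {dupes}")
        if X.ndim != 2 or X.shape[0] != n:
            raise DatasetError(f"X must be {n}×K, got shape {X.shape}")
        if X.shape[1] < 1 or X.shape[1] != len(self.descriptor_names):
            raise DatasetError(
                "descriptor_names must match the number of descriptor columns"
            )
        if not np.all(np.isfinite(X)):
            raise DatasetError("X contains missing or non-finite values")
        if y.shape != (n,):
            raise DatasetError(f"y must have length {n}")
        if not np.all(np.isfinite(y)):
            raise DatasetError("retention times contain non-finite values")
        if not np.all(y > 0):
            bad = [self.ids[i] for i in np.nonzero(~(y > 0))[0]]
            raise DatasetError(
                "retention times must be > 0 (relative %RMSE divides by t_R); "
                f"offending ids: {bad}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def subset(self, indices: Sequence[int]) -> "RetentionDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            ids=tuple(self.ids[i] for i in idx),
            X=self.X[idx],
            y=self.y[idx],
        )


@dataclass(frozen=True)
class TableSchema:
    """Column-name mapping for a retention CSV."""

    id_column: str = "id"
    retention_column: str = "tR"
    descriptor_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "descriptor_columns", tuple(self.descriptor_columns)
        )
        if len(self.descriptor_columns) < 1:
            raise DatasetError("schema needs at least one descriptor column")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "TableSchema":
        return cls(
            id_column=str(mapping.get("id", "id")),
            retention_column=str(mapping.get("retention", "tR")),
            descriptor_columns=tuple(mapping["descriptors"]),  # type: ignore[arg-type]
        )


def read_retention_table(
    path: str | Path,
    schema: TableSchema | Mapping[str, object],
    condition: ChromatographicCondition | None = None,
) -> RetentionDataset:
    """Read a retention–descriptor CSV into a validated dataset.

    Row order is preserved as read. The CSV must be comma-separated with a
    header row, ``.`` decimal separator, UTF-8.
    """
    if not isinstance(schema, TableSchema):
        schema = TableSchema.from_mapping(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    needed = (schema.id_column, schema.retention_column, *schema.descriptor_columns)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s) in {path.name}: {missing}")
    ids = df[schema.id_column].astype(str).tolist()
    numeric_cols = [schema.retention_column, *schema.descriptor_columns]
    numeric = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        bad_ids = [ids[i] for i in np.nonzero(bad.to_numpy())[0]]
        raise DatasetError(f"non-numeric or missing cell(s) for row id(s): {bad_ids}")
    return RetentionDataset(
        ids=tuple(ids),
        X=numeric[list(schema.descriptor_columns)].to_numpy(float),
        y=numeric[schema.retention_column].to_numpy(float),
        descriptor_names=schema.descriptor_columns,
        condition=condition or ChromatographicCondition(),
    )


def sort_by_retention(ds: RetentionDataset) -> RetentionDataset:
    """Permute rows so retention time is non-decreasing (stable on ties)."""
    order = np.argsort(ds.y, kind="stable")
    return ds.subset(order)


def elution_ranks(times: Sequence[float] | np.ndarray) -> np.ndarray:
    """1-based elution ranks: rank 1 = earliest eluting, ties kept stable.

    The output is always a permutation of ``1..n``; tied retention times are
    ranked in input order.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DatasetError("retention times must be finite for ranking")
    order = np.argsort(t, kind="stable")
    ranks = np.empty(t.shape[0], dtype=int)
    ranks[order] = np.arange(1, t.shape[0] + 1)
    return ranks


def write_predictions(
    ds: RetentionDataset, y_pred: Sequence[float] | np.ndarray, path: str | Path
) -> None:
    """Write id, experimental/predicted t_R and experimental/predicted ranks."""
    y_pred = np.asarray(y_pred, dtype=float)
    if y_pred.shape != (ds.n,):
        raise DatasetError(
            f"y_pred length {y_pred.shape} does not match n = {ds.n}"
        )
    out = pd.DataFrame(
        {
            "id": ds.ids,
            "tR_experimental": ds.y,
            "tR_predicted": y_pred,
            "rank_experimental": elution_ranks(ds.y),
            "rank_predicted": elution_ranks(y_pred),
        }
    )
    out.to_csv(path, index=False, float_format="%.6g")
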