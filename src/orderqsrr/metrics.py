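"""Performance metrics: relative %RMSE for retention time and elution order.

%RMSE is the root mean square of per-analyte *relative* errors,

    %RMSE = sqrt( (1/n) Σ_i ((ŷ_i − y_i)/y_i)² ) × 100 ,

so a late strongly-retained analyte does not dominate the score.  The
elution-order variant applies the same formula with the analyte's rank in
place of its retention time; values above 100% occur when early eluters
(small rank denominators) are misordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import RetentionDataset, elution_ranks, sort_by_retention
from .fit import QSRRModel, predict

__all__ = [
    "percent_rmse",
    "percent_rmse_order",
    "count_adjacent_inversions",
    "MetricsReport",
    "evaluate_model",
]


class MetricError(ValueError):
    pass


def percent_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise MetricError("y_true and y_pred must have equal length")
    if np.any(y_true == 0):
        raise MetricError("%RMSE is undefined when a true value is 0")
    rel = (y_pred - y_true) / y_true
    return float(np.sqrt(np.mean(rel**2)) * 100.0)


def _check_permutation(r: np.ndarray, name: str) -> np.ndarray:
    r = np.asarray(r)
    if not np.array_equal(np.sort(r), np.arange(1, r.shape[0] + 1)):
        raise MetricError(f"{name} is not a permutation of 1..n")
    return r.astype(float)


def percent_rmse_order(true_ranks: np.ndarray, pred_ranks: np.ndarray) -> float:
    """%RMSE with ranks substituted for retention times."""
    t = _check_permutation(true_ranks, "true_ranks")
    p = _check_permutation(pred_ranks, "pred_ranks")
    if t.shape != p.shape:
        raise MetricError("rank vectors must have equal length")
    return percent_rmse(t, p)


def count_adjacent_inversions(y_pred_on_sorted: np.ndarray) -> int:
    """Number of adjacent pairs with ŷ_j > ŷ_{j+1}, on the set ordered by
    ascending experimental retention time."""
    y = np.asarray(y_pred_on_sorted, dtype=float)
    return int(np.sum(y[:-1] > y[1:]))


@dataclass(frozen=True)
class MetricsReport:
    """%RMSE for retention time and order, per subset, plus inversion count.

    Keys of the per-subset dicts are "train", "validation", "combined".
    ``adjacent_inversions`` counts training adjacent pairs predicted out of
    order.
    """

    pct_rmse_tr: dict[str, float]
    pct_rmse_order: dict[str, float]
    adjacent_inversions: int
    n_per_subset: dict[str, int]


def _subset_metrics(ds: RetentionDataset, model: QSRRModel) -> tuple[float, float]:
    yhat = predict(model, ds.X)
    return (
        percent_rmse(ds.y, yhat),
        percent_rmse_order(elution_ranks(ds.y), elution_ranks(yhat)),
    )


def evaluate_model(
    model: QSRRModel,
    train: RetentionDataset,
    validation: RetentionDataset | None = None,
) -> MetricsReport:
    """Score a fitted model on training, validation and combined subsets.

    Ranks are set-relative: each subset is ranked within itself.
    """
    tr_time, tr_order = _subset_metrics(train, model)
    pct_tr = {"train": tr_time}
    pct_order = {"train": tr_order}
    counts = {"train": train.n}
    if validation is not None and validation.n > 0:
        va_time, va_order = _subset_metrics(validation, model)
        pct_tr["validation"] = va_time
        pct_order["validation"] = va_order
        counts["validation"] = validation.n
        combined = RetentionDataset(
            ids=train.ids + validation.ids,
            X=np.vstack([train.X, validation.X]),
            y=np.concatenate([train.y, validation.y]),
            descriptor_names=train.descriptor_names,
            condition=train.condition,
        )
        co_time, co_order = _subset_metrics(combined, model)
        pct_tr["combined"] = co_time
        pct_order["combined"] = co_order
        counts["combined"] = combined.n
    train_sorted = sort_by_retention(train)
    inversions = count_adjacent_inversions(predict(model, train_sorted.X))
    return MetricsReport(pct_tr, pct_order, inversions, counts)
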