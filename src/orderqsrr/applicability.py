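"""Leverage-based applicability domain and Williams-plot data.

An analyte lies inside the model's chemical applicability domain when its
leverage (hat-matrix diagonal, a measure of descriptor-space extrapolation
from the training cloud) does not exceed the critical leverage h* and its
standardized residual lies within ±3.  The leverage of a query row x is

    h = x (X₁ᵀ X₁)⁻¹ xᵀ

with X₁ the centered training descriptor matrix.  Two critical-leverage
conventions are offered: ``"printed"`` h* = 3(K−1)/N, and the textbook
``"conventional"`` h* = 3(K+1)/N, where N is the training count and K the
descriptor count.  Standardized residuals divide raw residuals by the
standard deviation of the training residuals (ddof = K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import RetentionDataset
from .fit import QSRRModel, predict

__all__ = [
    "leverages",
    "critical_leverage",
    "standardized_residuals",
    "williams_report",
    "ADReport",
]


class ApplicabilityError(ValueError):
    pass


def leverages(X_train: np.ndarray, X_query: np.ndarray) -> np.ndarray:
    """Hat-matrix diagonal of centered query rows against a centered
    training matrix."""
    X_train = np.asarray(X_train, dtype=float)
    X_query = np.asarray(X_query, dtype=float)
    if X_train.shape[1] != X_query.shape[1]:
        raise ApplicabilityError("descriptor counts differ")
    gram = X_train.T @ X_train
    try:
        inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise ApplicabilityError("singular training Gram matrix") from exc
    return np.einsum("ij,jk,ik->i", X_query, inv, X_query)


def critical_leverage(N: int, K: int, variant: str = "printed") -> float:
    """Warning limit h* for leverage; ``variant`` selects 3(K−1)/N
    ("printed") or 3(K+1)/N ("conventional")."""
    if N <= 0 or K < 1:
        raise ApplicabilityError("need N > 0 and K >= 1")
    if variant == "printed":
        return 3.0 * (K - 1) / N
    if variant == "conventional":
        return 3.0 * (K + 1) / N
    raise ApplicabilityError(f"unknown variant {variant!r}")


def standardized_residuals(
    model: QSRRModel,
    ds: RetentionDataset,
    train: RetentionDataset | None = None,
) -> np.ndarray:
    """Raw residuals divided by the training residual SD (ddof = K).

    ``train`` defaults to ``ds`` itself. A perfect fit (zero residual
    spread) yields all-zero standardized residuals rather than 0/0.
    """
    train = train or ds
    train_resid = train.y - predict(model, train.X)
    dof = max(train.n - model.k, 1)
    sd = float(np.sqrt(np.sum(train_resid**2) / dof))
    resid = ds.y - predict(model, ds.X)
    # a (numerically) perfect fit has no residual spread to standardize by
    if sd <= 1e-10 * float(np.sqrt(np.mean(train.y**2))):
        return np.zeros_like(resid)
    return resid / sd


@dataclass(frozen=True)
class ADReport:
    """Williams-plot data: per-analyte leverage, standardized residual and
    in-domain flag, plus the critical leverage h*."""

    table: pd.DataFrame  # columns: id, subset, leverage, std_residual, in_domain
    critical_leverage: float
    residual_limit: float = 3.0

    @property
    def all_in_domain(self) -> bool:
        return bool(self.table["in_domain"].all())


def williams_report(
    model: QSRRModel,
    train: RetentionDataset,
    validation: RetentionDataset | None = None,
    variant: str = "printed",
    residual_limit: float = 3.0,
) -> ADReport:
    """Assemble the applicability-domain report for training and validation
    analytes; out-of-domain means h > h* or |standardized residual| > 3."""
    Xt = train.X - model.x_means
    h_star = critical_leverage(train.n, model.k, variant)
    rows = []
    subsets: list[tuple[str, RetentionDataset]] = [("train", train)]
    if validation is not None and validation.n > 0:
        subsets.append(("validation", validation))
    for label, ds in subsets:
        h = leverages(Xt, ds.X - model.x_means)
        sr = standardized_residuals(model, ds, train=train)
        for i in range(ds.n):
            rows.append(
                {
                    "id": ds.ids[i],
                    "subset": label,
                    "leverage": h[i],
                    "std_residual": sr[i],
                    "in_domain": bool(
                        h[i] <= h_star and abs(sr[i]) <= residual_limit
                    ),
                }
            )
    return ADReport(pd.DataFrame(rows), h_star, residual_limit)
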