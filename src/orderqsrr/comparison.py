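"""Paired comparison of control vs. order-constrained model performance.

Works on a long-format result table with one row per (column, condition,
model) holding %RMSE of retention time and of elution order.  A packaged
benchmark of 19 reversed-phase LC column/condition pairs (small-organics
and synthetic-peptide case studies, values as published) ships with the
package for the paired t-test and the headline relative-change summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_benchmark_table",
    "validate_result_table",
    "TTestResult",
    "paired_t_test",
    "relative_difference_summary",
]

_KEY = ["case_study", "column_name", "condition"]
_REQUIRED = _KEY + ["model", "pct_rmse_tr", "pct_rmse_order"]


class ComparisonError(ValueError):
    pass


def load_benchmark_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a result table CSV; defaults to the packaged RP-LC benchmark."""
    if path is None:
        ref = resources.files("orderqsrr.data") / "rplc_benchmark.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    return validate_result_table(table)


def validate_result_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ComparisonError(f"result table missing column(s): {missing}")
    if (table[["pct_rmse_tr", "pct_rmse_order"]] < 0).any().any():
        raise ComparisonError("%RMSE values must be >= 0")
    models = table.groupby(_KEY)["model"].agg(lambda s: sorted(s))
    bad = models[models.apply(lambda m: m != ["MLR", "MLR-NLP"])]
    if len(bad):
        raise ComparisonError(
            "each (column, condition) needs exactly one MLR and one MLR-NLP "
            f"row; offending conditions: {list(bad.index)}"
        )
    return table


@dataclass(frozen=True)
class TTestResult:
    """Classic paired t-test with the descriptive statistics alongside."""

    mean_a: float
    mean_b: float
    var_a: float  # sample variance, ddof = 1
    var_b: float
    pearson_r: float
    n: int
    df: int
    t_stat: float
    p_one_tail: float
    p_two_tail: float
    t_crit_one_tail: float
    t_crit_two_tail: float
    alpha: float = 0.05


def paired_t_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> TTestResult:
    """Paired t-test of a vs. b: t = mean(a−b) / (SD(a−b)/√n)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.shape[0] < 2:
        raise ComparisonError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ComparisonError("zero variance of paired differences: t undefined")
    n = a.shape[0]
    t_stat = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p_one = float(stats.t.sf(abs(t_stat), df))
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(a.var(ddof=1)),
        var_b=float(b.var(ddof=1)),
        pearson_r=float(np.corrcoef(a, b)[0, 1]),
        n=n,
        df=df,
        t_stat=t_stat,
        p_one_tail=p_one,
        p_two_tail=2.0 * p_one,
        t_crit_one_tail=float(stats.t.ppf(1 - alpha, df)),
        t_crit_two_tail=float(stats.t.ppf(1 - alpha / 2, df)),
        alpha=alpha,
    )


def compare_models(
    table: pd.DataFrame, metric: str = "pct_rmse_tr", alpha: float = 0.05
) -> TTestResult:
    """Paired t-test of MLR vs. MLR-NLP over all conditions of a result table."""
    wide = _to_wide(table, metric)
    return paired_t_test(wide["MLR"].to_numpy(), wide["MLR-NLP"].to_numpy(), alpha)


def _to_wide(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    table = validate_result_table(table)
    return table.pivot_table(index=_KEY, columns="model", values=metric, sort=False)


def relative_difference_summary(table: pd.DataFrame) -> dict:
    """Per-condition relative change 100·(NLP − MLR)/MLR for both metrics,
    and the arithmetic means across conditions.

    The mean over conditions of the retention-time changes is the headline
    trade-off figure: how much retention accuracy is sacrificed on average
    for the gain in elution-order accuracy.
    """
    per_condition = {}
    means = {}
    for metric in ("pct_rmse_tr", "pct_rmse_order"):
        wide = _to_wide(table, metric)
        if (wide["MLR"] == 0).any():
            bad = list(wide.index[wide["MLR"] == 0])
            raise ComparisonError(
                f"MLR {metric} of 0 makes the relative change undefined "
                f"for condition(s): {bad}"
            )
        rel = 100.0 * (wide["MLR-NLP"] - wide["MLR"]) / wide["MLR"]
        per_condition[metric] = rel
        means[metric] = float(rel.mean())
    return {
        "per_condition": pd.DataFrame(per_condition).reset_index(),
        "mean_rel_change_pct_rmse_tr": means["pct_rmse_tr"],
        "mean_rel_change_pct_rmse_order": means["pct_rmse_order"],
    }
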