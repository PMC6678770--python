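"""QSRR model fitting: ordinary least squares and the order-constrained fit.

Two linear retention models share the predictor ŷ = (x − x̄)·ā + ȳ:

* the control model — mean-centered ordinary least squares (MLR);
* the order-constrained model — the same squared loss plus a relaxed
  elution-order constraint on every adjacent pair of the training set
  sorted by experimental retention time.  Each pair ``j`` carries a
  non-negative slack α_j with ŷ_j − ŷ_{j+1} ≤ α_j, and Σα_j enters the
  objective with weight λ.  Eliminating the slacks shows that the penalty
  is a hinge on adjacent order violations,

      minimize  Σ_j (y_j − x_j·ā)²  +  λ Σ_j max(0, ŷ_j − ŷ_{j+1}),

  a convex quadratic program solved here with an interior-point-style
  trust-region solver.  Retention-time accuracy is deliberately traded
  against elution-order accuracy: the optimum can only have SSE ≥ the OLS
  SSE and hinge ≤ the OLS hinge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, minimize

from .dataset import RetentionDataset, sort_by_retention

__all__ = [
    "QSRRModel",
    "NLPFitConfig",
    "fit_mlr",
    "fit_order_constrained",
    "predict",
    "hinge_order_penalty",
]


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class QSRRModel:
    """A fitted linear QSRR model (coefficients on centered descriptors)."""

    coefficients: np.ndarray  # length K
    x_means: np.ndarray  # length K centering means
    y_mean: float
    kind: str  # "MLR" or "MLR-NLP"
    alphas: np.ndarray = field(default_factory=lambda: np.empty(0))
    lambda_weight: float = 0.0
    converged: bool = True
    objective: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        object.__setattr__(self, "x_means", np.asarray(self.x_means, dtype=float))
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))

    @property
    def k(self) -> int:
        return self.coefficients.shape[0]


@dataclass(frozen=True)
class NLPFitConfig:
    """Settings for the order-constrained fit."""

    lambda_weight: float = 1.0  # weight on Σα (min vs. min² units differ)
    solver_tolerance: float = 1e-8
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if not self.solver_tolerance > 0:
            raise ValueError("solver_tolerance must be > 0")


def _center(train: RetentionDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    x_means = train.X.mean(axis=0)
    y_mean = float(train.y.mean())
    return train.X - x_means, train.y - y_mean, x_means, y_mean


def _check_rank(Xc: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(Xc, pivoting=True, mode="economic")
        dropped = [names[i] for i in piv[rank:]]
        raise FitError(
            f"descriptor matrix is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"collinear column(s): {dropped}"
        )


def fit_mlr(train: RetentionDataset) -> QSRRModel:
    """Ordinary-least-squares control model on mean-centered data."""
    if train.n < train.k + 2:
        raise FitError(f"need at least K + 2 = {train.k + 2} training analytes")
    Xc, yc, x_means, y_mean = _center(train)
    _check_rank(Xc, train.descriptor_names)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    sse = float(np.sum((yc - Xc @ coef) ** 2))
    return QSRRModel(
        coefficients=coef,
        x_means=x_means,
        y_mean=y_mean,
        kind="MLR",
        objective=sse,
    )


def fit_order_constrained(
    train: RetentionDataset, config: NLPFitConfig | None = None
) -> QSRRModel:
    """Fit the order-constrained model by convex quadratic programming.

    Training rows are sorted ascending by experimental retention time;
    constraints couple each adjacent pair.  Decision variables are the K
    coefficients and the m−1 slacks α_j ≥ 0.  After the solve, the slacks
    are tightened to their closed-form optimum max(0, ŷ_j − ŷ_{j+1}) for
    the returned coefficients.
    """
    config = config or NLPFitConfig()
    if train.n < train.k + 2:
        raise FitError(f"need at least K + 2 = {train.k + 2} training analytes")
    train = sort_by_retention(train)
    Xc, yc, x_means, y_mean = _center(train)
    _check_rank(Xc, train.descriptor_names)

    m, k = Xc.shape
    n_pairs = m - 1
    D = Xc[:-1] - Xc[1:]  # row j: x_j − x_{j+1} on the sorted set
    lam = config.lambda_weight

    # warm start at OLS with feasible slacks
    a0, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    alpha0 = np.maximum(D @ a0, 0.0) + 1e-6
    z0 = np.concatenate([a0, alpha0])

    H = np.zeros((k + n_pairs, k + n_pairs))
    H[:k, :k] = 2.0 * Xc.T @ Xc
    c_lin = np.concatenate([np.zeros(k), np.full(n_pairs, lam)])

    def obj(z: np.ndarray) -> float:
        r = yc - Xc @ z[:k]
        return float(r @ r + lam * z[k:].sum())

    def grad(z: np.ndarray) -> np.ndarray:
        g = np.empty_like(z)
        g[:k] = -2.0 * Xc.T @ (yc - Xc @ z[:k])
        g[k:] = lam
        return g

    # ŷ_j − ŷ_{j+1} − α_j ≤ 0  and  α_j ≥ 0
    A = np.hstack([D, -np.eye(n_pairs)])
    order_con = LinearConstraint(A, -np.inf, 0.0)
    bounds_lo = np.concatenate([np.full(k, -np.inf), np.zeros(n_pairs)])
    bound_con = LinearConstraint(
        np.eye(k + n_pairs), bounds_lo, np.full(k + n_pairs, np.inf)
    )

    res = minimize(
        obj,
        z0,
        jac=grad,
        hess=lambda z: H,
        method="trust-constr",
        constraints=[order_con, bound_con],
        options={
            "gtol": config.solver_tolerance,
            "xtol": config.solver_tolerance * 1e-2,
            "maxiter": config.max_iterations,
        },
    )
    if not res.success and res.status not in (1, 2):  # 1/2: tolerance reached
        raise FitError(f"order-constrained solve failed: {res.message}")

    coef = _polish_active_set(Xc, yc, D, lam, res.x[:k])
    alphas = np.maximum(D @ coef, 0.0)  # tight slacks for these coefficients
    sse = float(np.sum((yc - Xc @ coef) ** 2))
    return QSRRModel(
        coefficients=coef,
        x_means=x_means,
        y_mean=y_mean,
        kind="MLR-NLP",
        alphas=alphas,
        lambda_weight=lam,
        converged=bool(res.success or res.status in (1, 2)),
        objective=sse + lam * float(alphas.sum()),
    )


def _polish_active_set(
    Xc: np.ndarray, yc: np.ndarray, D: np.ndarray, lam: float, a0: np.ndarray
) -> np.ndarray:
    """Refine the interior-point solution on the reduced hinge objective.

    With the slacks eliminated, the objective J(a) = ‖y − Xa‖² + λΣmax(0, D a)
    is piecewise quadratic.  On the piece selected by the sign pattern of
    ``D a`` the minimizer has the closed form
    (XᵀX)⁻¹(Xᵀy − (λ/2)Σ_active d_j); iterating this to a fixed sign pattern
    recovers the optimum to machine precision whenever the optimum is not at
    a kink.  The best iterate by objective is kept, so the step can only
    improve on the solver's answer.
    """

    def objective(a: np.ndarray) -> float:
        r = yc - Xc @ a
        return float(r @ r + lam * np.maximum(D @ a, 0.0).sum())

    gram = Xc.T @ Xc
    xty = Xc.T @ yc

    def smooth_loop(a: np.ndarray) -> tuple[np.ndarray, float]:
        best_a, best_obj = a, objective(a)
        seen: set[bytes] = set()
        for _ in range(100):
            active = D @ a > 0
            key = np.packbits(active).tobytes()
            if key in seen:
                break
            seen.add(key)
            rhs = xty - 0.5 * lam * D[active].sum(axis=0)
            a = np.linalg.solve(gram, rhs)
            obj = objective(a)
            if obj <= best_obj:
                best_a, best_obj = a, obj
        return best_a, best_obj

    def pinned_candidate(a: np.ndarray, kink: np.ndarray) -> np.ndarray | None:
        """Minimize the smooth remainder subject to D_j a = 0 for j in kink."""
        active = (D @ a > 0) & ~kink
        null = _null_space(D[kink])
        if null.shape[1] == 0:
            return np.zeros_like(a)
        red_rhs = null.T @ (xty - 0.5 * lam * D[active].sum(axis=0))
        try:
            return null @ np.linalg.solve(null.T @ gram @ null, red_rhs)
        except np.linalg.LinAlgError:
            return None

    best_a, best_obj = smooth_loop(a0)
    # the optimum may sit at a kink (some D_j a = 0 exactly): pin candidate
    # pair sets to equality; candidates only count when they actually lower
    # the exactly-evaluated objective, so generous pin sets are harmless
    for _ in range(5):
        improved = False
        g = np.abs(D @ best_a)
        scale = max(float(g.max(initial=0.0)), 1e-300)
        pin_sets = [g <= tol * scale for tol in (1e-12, 1e-8, 1e-4, 1e-2, 1.0)]
        pin_sets += [
            np.arange(D.shape[0]) == j for j in range(D.shape[0])
        ]
        for kink in pin_sets:
            if not kink.any():
                continue
            cand = pinned_candidate(best_a, kink)
            if cand is None:
                continue
            cand, obj = smooth_loop(cand)
            if obj < best_obj - 1e-15:
                best_a, best_obj = cand, obj
                improved = True
        if not improved:
            break
    return best_a


def _null_space(A: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    if A.shape[0] == 0:
        return np.eye(A.shape[1])
    return null_space(A)


def predict(model: QSRRModel, X: np.ndarray) -> np.ndarray:
    """Predicted retention times on the original scale."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.k:
        raise FitError(
            f"descriptor matrix has {X.shape[1] if X.ndim == 2 else '?'} "
            f"columns, model expects {model.k}"
        )
    return (X - model.x_means) @ model.coefficients + model.y_mean


def hinge_order_penalty(model: QSRRModel, train_sorted: RetentionDataset) -> float:
    """Σ_j max(0, ŷ_j − ŷ_{j+1}): the minimal feasible Σα for the coefficients.

    The input must already be sorted ascending by experimental retention time.
    """
    y = train_sorted.y
    if np.any(np.diff(y) < 0):
        raise FitError("training set must be sorted ascending by retention time")
    yhat = predict(model, train_sorted.X)
    return float(np.sum(np.maximum(yhat[:-1] - yhat[1:], 0.0)))
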