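"""Fitting tests, including brute-force grid oracles for the hinge QP."""

import numpy as np
import pytest

from orderqsrr.dataset import RetentionDataset, sort_by_retention
from orderqsrr.fit import (
    FitError,
    NLPFitConfig,
    fit_mlr,
    fit_order_constrained,
    hinge_order_penalty,
    predict,
)
from orderqsrr.synthetic import SimulationConfig, simulate_dataset


def dataset_from_centered(x_c, y_c, shift=10.0):
    """Build a dataset whose centered form is exactly (x_c, y_c)."""
    x_c = np.asarray(x_c, float)
    if x_c.ndim == 1:
        x_c = x_c[:, None]
    y = np.asarray(y_c, float) + shift
    n, k = x_c.shape
    return RetentionDataset(
        ids=tuple(f"a{i}" for i in range(n)),
        X=x_c + 5.0,
        y=y,
        descriptor_names=tuple(f"d{j}" for j in range(k)),
    )


def centered(ds):
    return ds.X - ds.X.mean(0), ds.y - ds.y.mean()


def reduced_objective(Xc, yc, lam, a):
    """Slack-eliminated objective: SSE + λ·Σ hinge over adjacent pairs."""
    a = np.atleast_2d(a)
    D = Xc[:-1] - Xc[1:]
    sse = ((yc[:, None] - Xc @ a.T) ** 2).sum(axis=0)
    hinge = np.maximum(D @ a.T, 0.0).sum(axis=0)
    return sse + lam * hinge


class TestFitMLR:
    def test_identity_regression(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        model = fit_mlr(ds)
        np.testing.assert_allclose(model.coefficients, [1.0], atol=1e-12)

    def test_closed_form_slope(self):
        # a = Σ x_c y_c / Σ x_c²
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0])
        model = fit_mlr(ds)
        np.testing.assert_allclose(model.coefficients, [0.5], atol=1e-12)

    def test_constant_response_gives_zero_coefficients(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(fit_mlr(ds).coefficients, [0.0], atol=1e-12)

    def test_collinear_columns_named(self):
        x = np.arange(6.0)
        ds = RetentionDataset(
            ids=tuple("abcdef"),
            X=np.column_stack([x, 2 * x]),
            y=x + 1.0,
            descriptor_names=("base", "doubled"),
        )
        with pytest.raises(FitError, match="collinear"):
            fit_mlr(ds)

    def test_too_few_rows(self):
        ds = dataset_from_centered([[-1.0, 0.0], [1.0, 0.5], [0.0, -0.5]], [0.1, 0.2, 0.3])
        with pytest.raises(FitError):
            fit_mlr(ds)


class TestPredict:
    def test_training_predictions_reproduce_perfect_fit(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        model = fit_mlr(ds)
        np.testing.assert_allclose(predict(model, ds.X), ds.y, atol=1e-10)

    def test_zero_coefficients_predict_the_mean(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [0.0, 0.0, 0.0])
        model = fit_mlr(ds)
        np.testing.assert_allclose(predict(model, ds.X), ds.y.mean(), atol=1e-12)

    def test_hand_computed_two_by_two(self):
        from orderqsrr.fit import QSRRModel

        model = QSRRModel(
            coefficients=np.array([2.0, -1.0]),
            x_means=np.array([1.0, 1.0]),
            y_mean=5.0,
            kind="MLR",
        )
        X = np.array([[2.0, 0.0], [0.0, 3.0]])
        # rows: 5 + (1·2 + (−1)·(−1)) = 8; 5 + (−1·2 + 2·(−1)) = 1
        np.testing.assert_allclose(predict(model, X), [8.0, 1.0], atol=1e-12)

    def test_dimension_mismatch(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        model = fit_mlr(ds)
        with pytest.raises(FitError):
            predict(model, np.ones((2, 3)))


class TestOrderConstrainedFit:
    def test_worked_one_dimensional_instance(self):
        # J(a) = (a−1)² + a² + 1 + max(0,a) + max(0,−2a); smooth minimum at 1/4
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0])
        model = fit_order_constrained(ds, NLPFitConfig(lambda_weight=1.0))
        np.testing.assert_allclose(model.coefficients, [0.25], atol=1e-8)
        np.testing.assert_allclose(model.alphas, [0.0, 0.25], atol=1e-8)
        np.testing.assert_allclose(model.objective, 1.875, atol=1e-8)

    def test_worked_instance_matches_dense_grid(self):
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0])
        model = fit_order_constrained(ds)
        sds = sort_by_retention(ds)
        Xc, yc = centered(sds)
        grid = np.linspace(-2.0, 2.0, 400001)
        J = reduced_objective(Xc, yc, 1.0, grid[:, None])
        assert model.objective <= J.min() + 1e-9

    def test_inactive_constraints_recover_ols(self):
        # response already monotone in the descriptor: OLS is feasible
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        mlr = fit_mlr(ds)
        nlp = fit_order_constrained(ds)
        np.testing.assert_allclose(nlp.coefficients, mlr.coefficients, atol=1e-6)
        np.testing.assert_allclose(nlp.alphas, 0.0, atol=1e-8)

    def test_zero_penalty_weight_recovers_ols(self):
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0])
        mlr = fit_mlr(ds)
        nlp = fit_order_constrained(ds, NLPFitConfig(lambda_weight=0.0))
        np.testing.assert_allclose(nlp.coefficients, mlr.coefficients, atol=1e-8)

    def test_alphas_are_tight_hinges(self):
        ds = simulate_dataset(SimulationConfig(n_analytes=30, warp_strength=1.0, seed=5))
        model = fit_order_constrained(ds)
        sds = sort_by_retention(ds)
        yhat = predict(model, sds.X)
        np.testing.assert_allclose(
            model.alphas, np.maximum(yhat[:-1] - yhat[1:], 0.0), atol=1e-8
        )
        assert np.all(model.alphas >= 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle_on_random_1d_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        ds = RetentionDataset(
            ids=tuple(f"a{i}" for i in range(n)),
            X=rng.normal(0, 1, (n, 1)),
            y=np.sort(rng.normal(10, 2, n)),
            descriptor_names=("d0",),
        )
        model = fit_order_constrained(ds)
        Xc, yc = centered(ds)
        grid = np.linspace(-5.0, 5.0, 200001)[:, None]
        J = reduced_objective(Xc, yc, 1.0, grid)
        assert model.objective <= J.min() + 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_grid_oracle_on_random_2d_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 10
        ds = RetentionDataset(
            ids=tuple(f"a{i}" for i in range(n)),
            X=rng.normal(0, 1, (n, 2)),
            y=np.sort(rng.normal(10, 2, n)),
            descriptor_names=("d0", "d1"),
        )
        model = fit_order_constrained(ds)
        Xc, yc = centered(ds)
        g = np.linspace(-4.0, 4.0, 801)
        A1, A2 = np.meshgrid(g, g)
        grid = np.column_stack([A1.ravel(), A2.ravel()])
        J = reduced_objective(Xc, yc, 1.0, grid)
        assert model.objective <= J.min() + 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_trade_off_theorem(self, seed):
        # each model is optimal for its own objective, so the constrained
        # fit can only lose retention accuracy and gain order accuracy
        ds = simulate_dataset(
            SimulationConfig(n_analytes=40, warp_strength=0.8, noise_sd=0.5, seed=seed)
        )
        sds = sort_by_retention(ds)
        Xc, yc = centered(sds)
        mlr = fit_mlr(ds)
        nlp = fit_order_constrained(ds)
        sse = lambda m: float(np.sum((yc - Xc @ m.coefficients) ** 2))
        assert sse(nlp) >= sse(mlr) - 1e-8
        assert hinge_order_penalty(nlp, sds) <= hinge_order_penalty(mlr, sds) + 1e-8
        # and the optimum cannot be worse than just keeping the OLS point
        assert nlp.objective <= sse(mlr) + hinge_order_penalty(mlr, sds) + 1e-8

    def test_hinge_is_monotone_in_lambda(self):
        ds = simulate_dataset(
            SimulationConfig(n_analytes=30, warp_strength=1.0, noise_sd=0.5, seed=2)
        )
        sds = sort_by_retention(ds)
        hinges = [
            hinge_order_penalty(
                fit_order_constrained(ds, NLPFitConfig(lambda_weight=lam)), sds
            )
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(h2 <= h1 + 1e-7 for h1, h2 in zip(hinges, hinges[1:]))


class TestHingeOrderPenalty:
    def test_feasible_predictions_have_zero_penalty(self):
        ds = dataset_from_centered([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0])
        assert hinge_order_penalty(fit_mlr(ds), sort_by_retention(ds)) == 0.0

    def test_single_violation_of_the_worked_instance(self):
        # OLS slope 0.5 predicts [−0.5, 0.5, 0] on the sorted set: one hinge
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0])
        penalty = hinge_order_penalty(fit_mlr(ds), sort_by_retention(ds))
        np.testing.assert_allclose(penalty, 0.5, atol=1e-10)

    def test_reversed_ascending_predictions_telescope(self):
        # descriptor decreasing in y with slope 1 predicts the gaps reversed
        y = np.array([1.0, 2.0, 4.0, 7.0])
        ds = RetentionDataset(
            ids=tuple("abcd"),
            X=(-y)[:, None],
            y=y,
            descriptor_names=("neg",),
        )
        from orderqsrr.fit import QSRRModel

        model = QSRRModel(
            coefficients=np.array([-1.0]),
            x_means=ds.X.mean(0),
            y_mean=float(y.mean()),
            kind="MLR",
        )
        # predictions equal y exactly but built from a descending descriptor;
        # reversing the dataset ordering makes every gap a violation
        rev = ds.subset([3, 2, 1, 0])
        np.testing.assert_allclose(predict(model, ds.X), y, atol=1e-12)
        total_gap = float(y[-1] - y[0])
        yhat_rev = predict(model, rev.X)
        assert np.isclose(
            np.maximum(yhat_rev[:-1] - yhat_rev[1:], 0.0).sum(), total_gap
        )

    def test_unsorted_input_rejected(self):
        ds = dataset_from_centered([-1.0, 1.0, 0.0], [1.0, -1.0, 0.0])
        with pytest.raises(FitError):
            hinge_order_penalty(fit_mlr(ds), ds)
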