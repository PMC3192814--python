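"""Concentration models: published equation, stepwise MLR, ε-SVR, LOOCV."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.linear_model import LinearRegression

from chemtopo.regression import (
    ConcentrationSVR,
    LinearModel,
    PUBLISHED_CONCENTRATION_MODEL,
    StepwiseLinearRegression,
    apply_linear_model,
    descriptor_importance,
    fit_svr,
    grid_search,
    loocv,
    no_intercept_slope,
    stepwise_mlr,
)

ZERO = {"ClogP": 0.0, "FNSA3": 0.0, "FPSA3": 0.0, "RPCG": 0.0}


class TestLinearModel:
    def test_published_intercept_at_zero_descriptors(self):
        assert apply_linear_model(PUBLISHED_CONCENTRATION_MODEL, ZERO) == 6.105

    def test_published_single_term_contributions(self):
        assert math.isclose(
            apply_linear_model(PUBLISHED_CONCENTRATION_MODEL, {**ZERO, "ClogP": 1.0}), 6.536
        )
        assert math.isclose(
            apply_linear_model(PUBLISHED_CONCENTRATION_MODEL, {**ZERO, "RPCG": 1.0}), 0.772
        )

    def test_missing_descriptor_named_in_error(self):
        with pytest.raises(KeyError, match="FNSA3"):
            apply_linear_model(PUBLISHED_CONCENTRATION_MODEL, {"ClogP": 1.0})

    def test_linearity_up_to_intercept(self, rng):
        x = {k: rng.normal() for k in ZERO}
        y = {k: rng.normal() for k in ZERO}
        xy = {k: x[k] + y[k] for k in ZERO}
        m = PUBLISHED_CONCENTRATION_MODEL
        assert math.isclose(
            apply_linear_model(m, xy),
            apply_linear_model(m, x) + apply_linear_model(m, y) - m.intercept,
        )

    def test_json_round_trip(self):
        m = PUBLISHED_CONCENTRATION_MODEL
        assert LinearModel.from_json(m.to_json()) == m

    def test_duplicate_term_names_rejected(self):
        with pytest.raises(ValueError):
            LinearModel(0.0, (("a", 1.0), ("a", 2.0)))


class TestStepwise:
    def test_noiseless_single_predictor_recovered(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 10)), columns=[f"x{i}" for i in range(10)])
        y = 2.0 + 3.0 * X["x1"].to_numpy()
        model = stepwise_mlr(X, y)
        assert model.feature_names == ("x1",)
        assert math.isclose(model.intercept, 2.0, abs_tol=1e-8)
        assert math.isclose(model.terms[0][1], 3.0, abs_tol=1e-8)

    def test_null_data_entry_rate_consistent_with_threshold(self):
        # with k candidates and per-step entry at p<=alpha, the chance of a
        # non-empty model under the null is about 1-(1-alpha)^k
        k, alpha, n_seeds = 10, 0.05, 40
        nonempty = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (60, k))
            y = rng.normal(0, 1, 60)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = stepwise_mlr(X, y, f_enter=alpha, f_remove=2 * alpha)
            nonempty += bool(model.terms)
        expected = 1 - (1 - alpha) ** k  # ~0.40
        sd = math.sqrt(expected * (1 - expected) / n_seeds)
        assert abs(nonempty / n_seeds - expected) < 4 * sd

    def test_zero_variance_candidate_dropped_with_warning(self, rng):
        X = pd.DataFrame({"flat": np.ones(30), "x": rng.normal(0, 1, 30)})
        y = 1.0 + 2.0 * X["x"].to_numpy()
        with pytest.warns(UserWarning, match="flat"):
            model = stepwise_mlr(X, y)
        assert model.feature_names == ("x",)

    def test_estimator_is_sklearn_cloneable(self):
        est = StepwiseLinearRegression(p_enter=0.01, p_remove=0.02)
        cloned = clone(est)
        assert cloned.get_params() == {"p_enter": 0.01, "p_remove": 0.02}

    def test_invalid_threshold_order_rejected(self, rng):
        X = rng.normal(0, 1, (20, 2))
        with pytest.raises(ValueError):
            StepwiseLinearRegression(p_enter=0.10, p_remove=0.05).fit(X, rng.normal(0, 1, 20))


def _toy_svr_data():
    X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
    y = np.array([0.1, 0.9, 0.2, -0.7, 0.4])
    return X, y


def _dual_svr_oracle(X, y, gamma, epsilon, cost):
    """Solve the ε-SVR dual QP independently (split α/α* variables)."""
    n = len(y)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * d2)

    def objective(z):
        a, a_star = z[:n], z[n:]
        beta = a - a_star
        return 0.5 * beta @ K @ beta + epsilon * z.sum() - y @ beta

    def grad(z):
        a, a_star = z[:n], z[n:]
        Kb = K @ (a - a_star)
        return np.concatenate([Kb + epsilon - y, -Kb + epsilon + y])

    cons = {"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum()}
    res = minimize(
        objective,
        np.zeros(2 * n),
        jac=grad,
        bounds=[(0, cost)] * 2 * n,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    beta = res.x[:n] - res.x[n:]
    # intercept from KKT conditions at free (non-bound) support vectors
    tol = 1e-6 * cost
    b_vals = []
    for i in range(n):
        a_i, as_i = res.x[i], res.x[n + i]
        if tol < a_i < cost - tol:
            b_vals.append(y[i] - K[i] @ beta - epsilon)
        elif tol < as_i < cost - tol:
            b_vals.append(y[i] - K[i] @ beta + epsilon)
    b = float(np.mean(b_vals))

    def predict(Xq):
        d2q = ((Xq[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * d2q) @ beta + b

    return predict


class TestSvr:
    def test_single_point_predicted_within_epsilon(self):
        est = fit_svr(np.array([[1.0, 2.0]]), np.array([3.0]), gamma=0.5, epsilon=0.1, cost=10.0)
        assert abs(est.predict(np.array([[1.0, 2.0]]))[0] - 3.0) <= 0.1 + 1e-9

    def test_duplicated_training_set_leaves_predictions_unchanged(self):
        # cost large enough that no alpha sits at the box bound, where
        # duplicating the training set is an exact invariance of the solution
        X, y = _toy_svr_data()
        kw = dict(gamma=0.5, epsilon=0.05, cost=20.0, tol=1e-9)
        est1 = ConcentrationSVR(**kw).fit(X, y)
        est2 = ConcentrationSVR(**kw).fit(np.vstack([X, X]), np.concatenate([y, y]))
        q = np.linspace(0, 4, 9)[:, None]
        np.testing.assert_allclose(est1.predict(q), est2.predict(q), atol=1e-6)

    def test_matches_independent_dual_qp_solution(self):
        X, y = _toy_svr_data()
        gamma, epsilon, cost = 0.5, 0.1, 10.0
        est = ConcentrationSVR(
            gamma=gamma, epsilon=epsilon, cost=cost, standardize=False, tol=1e-10
        ).fit(X, y)
        oracle = _dual_svr_oracle(X, y, gamma, epsilon, cost)
        q = np.linspace(-0.5, 4.5, 11)[:, None]
        np.testing.assert_allclose(est.predict(q), oracle(q), atol=1e-4)

    def test_feature_order_permutation_invariance(self, rng):
        X = rng.normal(0, 1, (25, 4))
        y = rng.normal(0, 1, 25)
        perm = [2, 0, 3, 1]
        est1 = ConcentrationSVR().fit(X, y)
        est2 = ConcentrationSVR().fit(X[:, perm], y)
        q = rng.normal(0, 1, (6, 4))
        np.testing.assert_allclose(est1.predict(q), est2.predict(q[:, perm]), atol=1e-10)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationSVR().fit(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))


class TestLoocv:
    def test_perfect_predictor_scores_one(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        report = loocv(LinearRegression(), X, y)
        assert math.isclose(report.squared_correlation, 1.0, abs_tol=1e-9)
        assert report.total_mse < 1e-18

    def test_constant_predictor_reports_zero_with_warning(self, rng):
        X = rng.normal(0, 1, (8, 2))
        y = rng.normal(0, 1, 8)
        with pytest.warns(UserWarning):
            report = loocv(DummyRegressor(strategy="constant", constant=1.0), X, y)
        assert report.squared_correlation == 0.0

    @pytest.mark.parametrize("estimator", [LinearRegression(), ConcentrationSVR(gamma=0.3)])
    def test_equals_brute_force_refit_loop(self, estimator, rng):
        X = rng.normal(0, 1, (12, 3))
        y = rng.normal(0, 1, 12)
        report = loocv(estimator, X, y)
        for i in (0, 5, 11):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            est = clone(estimator).fit(X[mask], y[mask])
            assert report.predictions[i] == pytest.approx(est.predict(X[[i]])[0], abs=0)

    def test_metrics_recomputable_from_predictions(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 10)
        report = loocv(LinearRegression(), X, y)
        r = np.corrcoef(report.predictions, report.observed)[0, 1]
        assert math.isclose(report.squared_correlation, r * r, abs_tol=1e-12)
        assert math.isclose(
            report.total_mse, np.mean((report.predictions - report.observed) ** 2), abs_tol=1e-12
        )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            loocv(LinearRegression(), np.ones((2, 1)), np.ones(2))


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = rng.normal(0, 1, 10)
        est, report = grid_search(X, y, gamma_grid=[0.2], epsilon_grid=[0.1], cost_grid=[3.0])
        assert (est.gamma, est.epsilon, est.cost) == (0.2, 0.1, 3.0)

    def test_enlarging_grid_never_decreases_best_score(self, rng):
        X = rng.normal(0, 1, (15, 2))
        y = X[:, 0] ** 2 + rng.normal(0, 0.2, 15)
        _, small = grid_search(X, y, [0.1], [0.1], [1.0])
        _, big = grid_search(X, y, [0.1, 1.0], [0.1, 0.3], [1.0, 5.0])
        assert big.squared_correlation >= small.squared_correlation - 1e-12

    def test_recovers_generating_kernel_width_within_one_step(self, rng):
        # smooth target built from RBF bumps of width gamma=0.1
        X = rng.normal(0, 1, (24, 2))
        centers = X[:4]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        y = np.exp(-0.1 * d2) @ np.array([2.0, -1.5, 1.0, 2.5])
        grid = [0.001, 0.01, 0.1, 1.0, 10.0]
        est, _ = grid_search(
            X, y, grid, epsilon_grid=[0.01], cost_grid=[10.0], standardize=False
        )
        assert est.gamma in {0.01, 0.1, 1.0}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.ones((5, 1)), np.ones(5), [], [0.1], [1.0])


class TestImportance:
    def test_true_feature_deletion_hurts_most(self, rng):
        X = pd.DataFrame(
            {"A": rng.normal(0, 1, 25), "B": rng.normal(0, 1, 25)}
        )
        y = np.sin(2 * X["A"].to_numpy()) + rng.normal(0, 0.05, 25)
        table = descriptor_importance(X, y, [0.1, 1.0], [0.05], [5.0])
        assert len(table) == 2
        assert table.iloc[0]["deleted_feature"] == "A"
        assert (
            table.iloc[0]["squared_correlation"] < table.iloc[1]["squared_correlation"]
        )

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            descriptor_importance(pd.DataFrame({"A": [1.0, 2.0, 3.0]}), np.ones(3))


def test_no_intercept_slope_is_one_for_identical_vectors(rng):
    y = rng.normal(0, 1, 20)
    assert math.isclose(no_intercept_slope(y, y), 1.0)
    assert math.isclose(no_intercept_slope(2 * y, y), 2.0)
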