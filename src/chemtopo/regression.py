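"""Concentration models: stepwise multiple linear regression and ε-SVR.

Metabolite concentrations span several orders of magnitude, so models work
on the negative decadic logarithm −LogC. Two model families are provided as
scikit-learn-style estimators:

* :class:`StepwiseLinearRegression` — forward selection with backward
  elimination driven by partial-F probability thresholds, the classic
  stepwise procedure of mainstream statistics packages.
* :class:`ConcentrationSVR` — ε-insensitive support vector regression with
  an RBF kernel ``k(u, v) = exp(-gamma * ||u - v||^2)``; features are
  z-standardised inside the estimator (on the training data only) because an
  RBF over mixed-unit features is otherwise dominated by the widest-ranged
  one.

Model quality is scored by leave-one-out cross validation (LOOCV): the
squared Pearson correlation between held-out predictions and observations,
and the plain mean of squared held-out residuals. Descriptor importance is
measured by deletion: drop one feature, re-tune by grid search, and compare
the LOOCV squared correlation — the larger the drop, the more important the
deleted descriptor.

A reference multiple-linear-regression equation relating −LogC to polarity
descriptors is shipped as :data:`PUBLISHED_CONCENTRATION_MODEL`:

    −LogC = 6.105 + 0.431·ClogP + 15.595·FNSA3 + 16.727·FPSA3 − 5.333·RPCG

It is a fitted result for E. coli metabolite concentrations, shipped as a
constant evaluator (never refit here).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearModel",
    "PUBLISHED_CONCENTRATION_MODEL",
    "apply_linear_model",
    "StepwiseLinearRegression",
    "ConcentrationSVR",
    "CvReport",
    "loocv",
    "grid_search",
    "descriptor_importance",
    "stepwise_mlr",
    "fit_svr",
    "no_intercept_slope",
    "DEFAULT_GAMMA_GRID",
    "DEFAULT_EPSILON_GRID",
    "DEFAULT_COST_GRID",
]


# ---------------------------------------------------------------------------
# Linear model container


@dataclass(frozen=True)
class LinearModel:
    """An intercept plus an ordered list of (descriptor, coefficient) terms."""

    intercept: float
    terms: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("descriptor names must be unique")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def to_json(self) -> str:
        return json.dumps(
            {"intercept": self.intercept, "terms": [list(t) for t in self.terms]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        obj = json.loads(text)
        return cls(float(obj["intercept"]), tuple((n, float(c)) for n, c in obj["terms"]))


PUBLISHED_CONCENTRATION_MODEL = LinearModel(
    intercept=6.105,
    terms=(("ClogP", 0.431), ("FNSA3", 15.595), ("FPSA3", 16.727), ("RPCG", -5.333)),
)


def apply_linear_model(model: LinearModel, x: Mapping[str, float]) -> float:
    """Evaluate ``intercept + sum(coef * x[name])``; every term must be covered."""
    total = model.intercept
    for name, coef in model.terms:
        if name not in x:
            raise KeyError(f"descriptor {name!r} missing from input")
        total += coef * float(x[name])
    return total


# ---------------------------------------------------------------------------
# Stepwise MLR


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _ols_rss(Xm: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(Xm, y, rcond=None)
    if rank < Xm.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - Xm @ coef
    return coef, float(resid @ resid)


class StepwiseLinearRegression(BaseEstimator, RegressorMixin):
    """Stepwise multiple linear regression by partial-F probability.

    Forward steps add the candidate whose partial F (given the current model)
    has the smallest probability, provided it is at most ``p_enter``; after
    every addition, backward steps remove any included variable whose
    partial-F probability exceeds ``p_remove``. The defaults (0.05 / 0.10)
    follow the conventional stepwise defaults of mainstream statistical
    software. Zero-variance candidates are dropped with a warning; a
    candidate producing a singular design at a step is skipped with a
    warning.

    Attributes (after ``fit``)
    --------------------------
    model_ : LinearModel
        Intercept and selected terms, in entry order.
    selected_features_ : list of str
    coef_, intercept_ : ndarray, float
    trace_ : list of (action, feature, p) tuples documenting the selection.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X, y):
        if self.p_remove < self.p_enter:
            raise ValueError("p_remove must be >= p_enter to avoid entry/removal cycles")
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if Xf.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if not np.isfinite(Xf.to_numpy()).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")

        candidates = []
        for name in Xf.columns:
            if np.ptp(Xf[name].to_numpy()) == 0.0:
                warnings.warn(f"dropping zero-variance candidate {name!r}")
            else:
                candidates.append(name)

        selected: list[str] = []
        trace: list[tuple[str, str, float]] = []

        def design(names: Sequence[str]) -> np.ndarray:
            return np.column_stack([np.ones(n)] + [Xf[nm].to_numpy(dtype=float) for nm in names])

        _, rss_cur = _ols_rss(design(selected), y)
        # numerically saturated fit: nothing left for further terms to explain
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rss_floor = 1e-12 * max(ss_tot, 1e-30)

        while rss_cur > rss_floor:
            # forward step
            best: tuple[float, str, float] | None = None  # (p, name, rss_full)
            df_full = n - (len(selected) + 2)  # intercept + selected + candidate
            if df_full < 1:
                break
            for name in candidates:
                if name in selected:
                    continue
                try:
                    _, rss_full = _ols_rss(design(selected + [name]), y)
                except np.linalg.LinAlgError:
                    warnings.warn(f"candidate {name!r} makes the design singular; skipped")
                    continue
                if rss_full <= 0:
                    p = 0.0
                else:
                    f_stat = (rss_cur - rss_full) / (rss_full / df_full)
                    p = float(sps.f.sf(max(f_stat, 0.0), 1, df_full))
                if best is None or p < best[0]:
                    best = (p, name, rss_full)
            if best is None or best[0] > self.p_enter:
                break
            p_in, name_in, rss_cur = best
            selected.append(name_in)
            trace.append(("enter", name_in, p_in))

            # backward sweep
            removed = True
            while removed and len(selected) > 1:
                removed = False
                df_full = n - (len(selected) + 1)
                if df_full < 1:
                    break
                _, rss_full = _ols_rss(design(selected), y)
                worst: tuple[float, str] | None = None
                for name in selected:
                    reduced = [s for s in selected if s != name]
                    _, rss_red = _ols_rss(design(reduced), y)
                    if rss_full <= 0:
                        p = 0.0
                    else:
                        f_stat = (rss_red - rss_full) / (rss_full / df_full)
                        p = float(sps.f.sf(max(f_stat, 0.0), 1, df_full))
                    if worst is None or p > worst[0]:
                        worst = (p, name)
                if worst is not None and worst[0] > self.p_remove and worst[1] != name_in:
                    selected.remove(worst[1])
                    trace.append(("remove", worst[1], worst[0]))
                    _, rss_cur = _ols_rss(design(selected), y)
                    removed = True

        coef, _ = _ols_rss(design(selected), y)
        self.n_features_in_ = Xf.shape[1]
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.selected_features_ = list(selected)
        self.intercept_ = float(coef[0])
        self.coef_ = np.asarray(coef[1:], dtype=float)
        self.model_ = LinearModel(
            self.intercept_, tuple(zip(selected, (float(c) for c in coef[1:])))
        )
        self.trace_ = trace
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        Xf = _as_frame(X)
        out = np.full(len(Xf), self.intercept_, dtype=float)
        for name, c in self.model_.terms:
            out += c * Xf[name].to_numpy(dtype=float)
        return out


def stepwise_mlr(X, y, f_enter: float = 0.05, f_remove: float = 0.10) -> LinearModel:
    """Functional wrapper: run stepwise selection and return the LinearModel."""
    return StepwiseLinearRegression(p_enter=f_enter, p_remove=f_remove).fit(X, y).model_


# ---------------------------------------------------------------------------
# ε-SVR


class ConcentrationSVR(BaseEstimator, RegressorMixin):
    """ε-insensitive support vector regression with an RBF kernel.

    Parameters default to ``gamma=0.01, epsilon=0.22, cost=7.9``, the
    grid-search optimum reported for −LogC prediction from degree plus ten
    chemical descriptors. ``standardize=True`` z-scores features on the
    training data (recommended; RBF distances over raw mixed-unit features
    are degenerate).
    """

    def __init__(
        self,
        gamma: float = 0.01,
        epsilon: float = 0.22,
        cost: float = 7.9,
        standardize: bool = True,
        tol: float = 1e-3,
    ):
        self.gamma = gamma
        self.epsilon = epsilon
        self.cost = cost
        self.standardize = standardize
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(_as_frame(X), dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(
            (
                "svr",
                SVR(
                    kernel="rbf",
                    gamma=self.gamma,
                    epsilon=self.epsilon,
                    C=self.cost,
                    tol=self.tol,
                ),
            )
        )
        self.pipeline_ = Pipeline(steps).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = np.asarray(_as_frame(X), dtype=float)
        return self.pipeline_.predict(X)


def fit_svr(
    X, y, gamma: float = 0.01, epsilon: float = 0.22, cost: float = 7.9
) -> ConcentrationSVR:
    """Functional wrapper: fit an RBF ε-SVR with the given parameters."""
    return ConcentrationSVR(gamma=gamma, epsilon=epsilon, cost=cost).fit(X, y)


# ---------------------------------------------------------------------------
# LOOCV, grid search, importance


@dataclass
class CvReport:
    """Leave-one-out cross-validation report.

    ``squared_correlation`` is the squared Pearson r between held-out
    predictions and observations; ``total_mse`` the plain mean of squared
    held-out residuals. Both are recomputable from the stored predictions.
    """

    squared_correlation: float
    total_mse: float
    predictions: np.ndarray
    observed: np.ndarray


def _score(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mse = float(np.mean((pred - y) ** 2))
    if np.allclose(pred, pred[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance in LOOCV predictions or targets; r^2 reported as 0")
        return 0.0, mse
    r = float(np.corrcoef(pred, y)[0, 1])
    return r * r, mse


def loocv(estimator, X, y) -> CvReport:
    """Leave-one-out cross validation of any sklearn-style regressor.

    Each fold refits a clone of ``estimator`` on all-but-one samples and
    predicts the held-out one; equivalent by construction to the brute-force
    n-refit loop. ``X`` is passed through as given (DataFrame or array) so
    fold fits see exactly the rows the estimator would see in a manual loop.
    """
    is_frame = isinstance(X, pd.DataFrame)
    if not is_frame:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_X = X.iloc[mask] if is_frame else X[mask]
        test_X = X.iloc[[i]] if is_frame else X[[i]]
        est = clone(estimator).fit(train_X, y[mask])
        preds[i] = float(est.predict(test_X)[0])
    r2, mse = _score(preds, y)
    return CvReport(r2, mse, preds, y.copy())


DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(10.0**k for k in range(-3, 2))
DEFAULT_EPSILON_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.01, 0.50, 0.03), 2))
DEFAULT_COST_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 10.0, 0.3), 1))


def grid_search(
    X,
    y,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    standardize: bool = True,
) -> tuple[ConcentrationSVR, CvReport]:
    """Exhaustive LOOCV grid search over (gamma, epsilon, cost).

    Best cell maximises the squared correlation; ties break on lower MSE,
    then on smaller cost. Returns the winning (unfitted-clone refitted on the
    full data) estimator and its LOOCV report.
    """
    if not (len(gamma_grid) and len(epsilon_grid) and len(cost_grid)):
        raise ValueError("all grids must be non-empty")
    best_key = None
    best: tuple[ConcentrationSVR, CvReport] | None = None
    for gamma, epsilon, cost in itertools.product(gamma_grid, epsilon_grid, cost_grid):
        est = ConcentrationSVR(
            gamma=gamma, epsilon=epsilon, cost=cost, standardize=standardize
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = loocv(est, X, y)
        key = (-report.squared_correlation, report.total_mse, cost)
        if best_key is None or key < best_key:
            best_key = key
            best = (est, report)
    assert best is not None
    est, report = best
    return clone(est).fit(X, y), report


def descriptor_importance(
    X: pd.DataFrame,
    y,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
) -> pd.DataFrame:
    """Deletion-based descriptor importance for the SVR model.

    One feature is removed at a time; the reduced model is re-tuned by grid
    search and scored by LOOCV. Rows are sorted ascending by squared
    correlation, so the most important (most damaging to delete) descriptor
    comes first.
    """
    Xf = _as_frame(X)
    if Xf.shape[1] < 2:
        raise ValueError("need at least two features")
    rows = []
    for name in Xf.columns:
        reduced = Xf.drop(columns=[name])
        _, report = grid_search(reduced, y, gamma_grid, epsilon_grid, cost_grid)
        rows.append(
            {
                "deleted_feature": name,
                "squared_correlation": report.squared_correlation,
                "total_mse": report.total_mse,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("squared_correlation", kind="stable")
        .reset_index(drop=True)
    )


def no_intercept_slope(predictions: Sequence[float], observed: Sequence[float]) -> float:
    """Slope of the through-origin regression of predictions on observations,
    ``sum(yhat * y) / sum(y^2)`` — 1.0 for a perfectly calibrated model."""
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    return float(np.dot(yhat, y) / np.dot(y, y))
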