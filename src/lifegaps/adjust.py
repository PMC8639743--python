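"""Median (least-absolute-deviations) regression adjustment of YPLLG.

YPLLG is strongly left-skewed, so its conditional center is modeled with a
median regression rather than OLS: coefficients minimize
:math:`\\sum_i |y_i - x_i^\\top\\beta|` (quantile :math:`\\tau = 0.5`),
solved exactly as a linear program. Covariates are those not already used
in the LEB attribution: a Swiss-nationality indicator, neighborhood median
household income (rescaled to kCHF for conditioning; residuals are
invariant to this), and neighborhood median population age. The adjusted
YPLLG is the raw residual, not re-centered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

ADJUSTMENT_COVARIATES = ("swiss", "income_kchf", "nbh_median_age")


class RankDeficientDesignError(ValueError):
    """The design matrix is rank-deficient (collinear columns)."""


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that QR pivoting marks as linearly dependent."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in piv[rank:]]


class MedianRegressionAdjuster:
    """LAD (tau = 0.5) regression estimator producing adjusted values.

    Parameters
    ----------
    fit_intercept : bool, default True

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : (p,) array of covariate coefficients
    intercept_ : float
    residuals_ : (n,) array, the adjusted values ``y - X @ coef - intercept``
    converged_ : bool — LP solver success flag
    feature_names_in_ : list of str when X is a DataFrame
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def get_params(self, deep: bool = True) -> dict:
        return {"fit_intercept": self.fit_intercept}

    def set_params(self, **params) -> "MedianRegressionAdjuster":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for MedianRegressionAdjuster")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "MedianRegressionAdjuster":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.feature_names_in_ = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite with no missing values")

        names = list(self.feature_names_in_)
        if self.fit_intercept:
            design = np.column_stack([np.ones(n), X])
            names = ["intercept"] + names
        else:
            design = X
        n_coef = design.shape[1]
        if n <= n_coef:
            raise ValueError("need more observations than coefficients")
        if np.linalg.matrix_rank(design) < n_coef:
            bad = _collinear_columns(design, names)
            raise RankDeficientDesignError(f"collinear design columns: {bad}")

        # LP: min 1'(u + v)  s.t.  D beta + u - v = y,  u, v >= 0, beta free
        eye = sparse.eye(n, format="csc")
        a_eq = sparse.hstack([sparse.csc_matrix(design), eye, -eye], format="csc")
        c = np.concatenate([np.zeros(n_coef), np.ones(2 * n)])
        bounds = [(None, None)] * n_coef + [(0, None)] * (2 * n)
        result = linprog(c, A_eq=a_eq, b_eq=y, bounds=bounds, method="highs")
        if not result.success:
            raise RuntimeError(f"LAD linear program failed: {result.message}")

        beta = result.x[:n_coef]
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.residuals_ = y - design @ beta
        self.converged_ = bool(result.success)
        self.n_features_in_ = p
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("MedianRegressionAdjuster is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


def build_design(records: pd.DataFrame) -> pd.DataFrame:
    """Covariate table for the adjustment: swiss indicator, income (kCHF), age."""
    return pd.DataFrame(
        {
            "swiss": (records["nationality"].astype(str) == "swiss").astype(float),
            "income_kchf": records["income"].to_numpy(dtype=float) / 1000.0,
            "nbh_median_age": records["nbh_median_age"].to_numpy(dtype=float),
        },
        index=records.index,
    )


def fit_median_regression(y, X) -> MedianRegressionAdjuster:
    """Fit the tau = 0.5 LAD regression of y on X (intercept included)."""
    return MedianRegressionAdjuster().fit(X, y)


def adjusted_yplg(fit: MedianRegressionAdjuster) -> np.ndarray:
    """Adjusted YPLLG: raw residuals of the median-regression fit."""
    if not getattr(fit, "converged_", False):
        raise RuntimeError("median regression did not converge")
    return fit.residuals_.copy()
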