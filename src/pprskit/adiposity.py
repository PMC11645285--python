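"""Penalized-regression ranking of adiposity indices as liver-trait predictors.

Lasso, ridge and elastic net compete in a nested cross-validation: an
80/20 train/test split, inner CV tuning (mixing, shrinkage) by minimum
MSE within each outer fold, outer CV scoring each model family, then the
winner is re-tuned on the full training set, evaluated on the held-out
20% and finally refit on all data. Covariates enter unpenalized (they are
partialled out of response and predictors before the penalized fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge
from sklearn.model_selection import KFold, train_test_split


@dataclass(frozen=True)
class PenalizedFitResult:
    model_kind: str  # L1 | L2 | elastic-net
    alpha: float  # L1/L2 mixing (1 = lasso, 0 = ridge)
    shrinkage: float  # penalty strength
    standardized_coefficients: dict  # predictor -> coefficient, |.|-ranked
    cv_mse: float
    test_mse: float

    def ranking(self) -> list:
        return list(self.standardized_coefficients)


_FAMILIES = {"L1": [1.0], "L2": [0.0], "elastic-net": None}


def _lambda_grid(Xs, y, n_lambda):
    """Log-spaced grid from (almost) OLS to the all-zero lasso solution."""
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1e-4, lam_max * 1.2, n_lambda)


def _fit_one(Xs, y, l1_ratio, lam):
    if l1_ratio == 0.0:
        # sklearn's ElasticNet l1_ratio=0 is discouraged; use Ridge with the
        # matching objective scale (alpha = n * lam)
        model = Ridge(alpha=lam * len(y))
    else:
        model = ElasticNet(alpha=lam, l1_ratio=l1_ratio, max_iter=5000, tol=1e-6)
    model.fit(Xs, y)
    return model


def _cv_mse(Xs, y, l1_ratio, lam, folds, seed):
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, va in kf.split(Xs):
        model = _fit_one(Xs[tr], y[tr], l1_ratio, lam)
        errs.append(np.mean((y[va] - model.predict(Xs[va])) ** 2))
    return float(np.mean(errs))


def _tune(Xs, y, l1_ratios, lambdas, folds, seed):
    best = None
    for l1 in l1_ratios:
        for lam in lambdas:
            mse = _cv_mse(Xs, y, l1, lam, folds, seed)
            if best is None or mse < best[0]:
                best = (mse, l1, lam)
    return best


def nested_cv_penalized(predictors: pd.DataFrame, response, covariates=None,
                        outer_folds: int = 10, inner_folds: int = 10,
                        holdout: float = 0.2, seed: int = 0,
                        alpha_grid=None, n_lambda: int = 50) -> PenalizedFitResult:
    """Select and fit the best penalized model of the response on the predictors.

    Predictors are standardized; coefficients are reported on the
    standardized scale ranked by absolute value. Deterministic given
    ``seed``.
    """
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    y = np.asarray(response, dtype=float)
    C = np.asarray(covariates, dtype=float) if covariates is not None else None
    if C is not None and C.ndim == 1:
        C = C[:, None]
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    if C is not None:
        mask &= np.all(np.isfinite(C), axis=1)
    X, y = X[mask], y[mask]
    if C is not None:
        C = C[mask]
    n, p = X.shape
    if n < 10 * p:
        raise ValueError("need at least 10 samples per predictor")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor")
    if outer_folds > n or inner_folds > n:
        raise ValueError("more folds than samples")

    # covariates enter unpenalized: partial them out of response and predictors
    if C is not None:
        D = np.column_stack([np.ones(n), C])
        proj = lambda v: v - D @ np.linalg.lstsq(D, v, rcond=None)[0]
        y = proj(y)
        X = np.column_stack([proj(X[:, j]) for j in range(p)])

    idx_train, idx_test = train_test_split(np.arange(n), test_size=holdout,
                                           random_state=seed)
    mu, sd = X[idx_train].mean(axis=0), X[idx_train].std(axis=0)
    Xs = (X - mu) / sd
    Xtr, ytr = Xs[idx_train], y[idx_train]
    Xte, yte = Xs[idx_test], y[idx_test]

    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.1, 1.0, 0.1), 2)
    lambdas = _lambda_grid(Xtr, ytr, n_lambda)

    # outer CV scores each family (inner CV tunes hyperparameters per fold)
    family_scores = {}
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed + 1)
    for kind, l1s in _FAMILIES.items():
        l1s = list(alpha_grid) if l1s is None else l1s
        errs = []
        for tr, va in outer.split(Xtr):
            _, l1, lam = _tune(Xtr[tr], ytr[tr], l1s, lambdas, inner_folds, seed)
            model = _fit_one(Xtr[tr], ytr[tr], l1, lam)
            errs.append(np.mean((ytr[va] - model.predict(Xtr[va])) ** 2))
        family_scores[kind] = float(np.mean(errs))
    winner = min(family_scores, key=family_scores.get)

    # re-tune the winning family on the full training set, score on holdout
    l1s = list(alpha_grid) if _FAMILIES[winner] is None else _FAMILIES[winner]
    cv_mse, l1, lam = _tune(Xtr, ytr, l1s, lambdas, inner_folds, seed)
    held = _fit_one(Xtr, ytr, l1, lam)
    test_mse = float(np.mean((yte - held.predict(Xte)) ** 2))

    # final refit on all data at the selected hyperparameters
    final = _fit_one(Xs, y, l1, lam)
    coefs = dict(sorted(zip(names, final.coef_), key=lambda t: -abs(t[1])))
    return PenalizedFitResult(model_kind=winner, alpha=float(l1),
                              shrinkage=float(lam),
                              standardized_coefficients={k: float(v)
                                                         for k, v in coefs.items()},
                              cv_mse=cv_mse, test_mse=test_mse)


def ols_standardized(predictors: pd.DataFrame, response) -> dict:
    """OLS coefficients on standardized predictors (shrinkage -> 0 reference)."""
    X = predictors.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    y = np.asarray(response, dtype=float)
    fit = LinearRegression().fit(Xs, y)
    return dict(zip(predictors.columns, map(float, fit.coef_)))


def result_to_frame(res: PenalizedFitResult) -> pd.DataFrame:
    rows = [(res.model_kind, res.alpha, res.shrinkage, name, coef, res.cv_mse,
             res.test_mse)
            for name, coef in res.standardized_coefficients.items()]
    return pd.DataFrame(rows, columns=["model", "alpha", "lambda", "predictor",
                                       "standardized_beta", "cv_mse", "test_mse"])
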