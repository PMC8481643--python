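"""NIPALS partial least squares regression (single response).

For a single response the NIPALS weight vector per component has the closed
form w = X'y / ||X'y||, so each latent variable is extracted in one pass
(no inner iteration).  X and y are mean-centered internally; the regression
coefficient vector is expressed on the original (selected) variables so that
prediction is ``y_hat = y_mean + (X - x_mean) @ coef``.

The latent-variable count ("PC" in calibration reports) is chosen by
leave-one-out cross-validation with a 2% parsimony rule: the smallest count
whose RMSECV is within 1.02x of the curve minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class PLSModel:
    """Fitted PLS1 model on the original variable scale."""

    n_lv: int
    x_weights: np.ndarray   # (p, n_lv)
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    coef: np.ndarray        # (p,)
    x_mean: np.ndarray      # (p,)
    y_mean: float
    coef_path: np.ndarray | None = None  # (p, n_lv): coefficients after 1..n_lv LVs

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.coef.size:
            raise ValueError(
                f"model expects {self.coef.size} variables, got {X_new.shape[1]}"
            )
        return self.y_mean + (X_new - self.x_mean) @ self.coef


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Core NIPALS deflation on centered data; returns W, P, q."""
    n, p = Xc.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    X = Xc.copy()
    y = yc.copy()
    for k in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # y residual orthogonal to X residual: stop extracting
            W, P, q = W[:, :k], P[:, :k], q[:k]
            break
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-28:
            W, P, q = W[:, :k], P[:, :k], q[:k]
            break
        pk = X.T @ t / tt
        qk = float(y @ t) / tt
        X -= np.outer(t, pk)
        y -= qk * t
        W[:, k], P[:, k], q[k] = w, pk, qk
    return W, P, q


def fit_pls(X, y, n_lv: int, keep_path: bool = False) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables.

    ``keep_path`` additionally stores the coefficient vectors after each
    1..n_lv components (used for cross-validation curves at no extra cost).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y sample counts differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    k = W.shape[1]
    if k == 0:
        raise ValueError("no latent variable could be extracted")
    # beta after j components: W_j (P_j' W_j)^{-1} q_j ; solve incrementally
    R = np.linalg.solve(P.T @ W, np.eye(k))  # (P'W) is upper triangular for NIPALS
    coef_path = None
    if keep_path:
        coef_path = np.empty((X.shape[1], k))
        for j in range(1, k + 1):
            Rj = np.linalg.solve((P[:, :j].T @ W[:, :j]), q[:j])
            coef_path[:, j - 1] = W[:, :j] @ Rj
        coef = coef_path[:, -1]
    else:
        coef = W @ (R @ q)
    return PLSModel(
        n_lv=k, x_weights=W, x_loadings=P, y_loadings=q,
        coef=coef, x_mean=x_mean, y_mean=y_mean, coef_path=coef_path,
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predict with a fitted model (stored centering + coefficients only)."""
    return model.predict(X_new)


def cv_rmse_curve(X, y, max_lv: int, folds=None, seed: int = 0):
    """Cross-validated RMSE for every candidate 1..max_lv.

    ``folds=None`` means leave-one-out.  Returns ``(rmsecv, cv_pred)`` where
    ``cv_pred[i, j]`` is the held-out prediction of sample i with j+1 LVs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation")
    max_lv = min(max_lv, n - 2, X.shape[1])
    if max_lv < 1:
        raise ValueError("max_lv out of range")
    if folds is None or folds >= n:
        fold_ids = np.arange(n)
        n_folds = n
    else:
        rng = np.random.default_rng(seed)
        fold_ids = rng.permutation(np.arange(n) % folds)
        n_folds = folds
    cv_pred = np.empty((n, max_lv))
    for f in range(n_folds):
        test = fold_ids == f
        train = ~test
        model = fit_pls(X[train], y[train], max_lv, keep_path=True)
        Xc = X[test] - model.x_mean
        preds = model.y_mean + Xc @ model.coef_path  # (n_test, k)
        k = preds.shape[1]
        cv_pred[test, :k] = preds
        if k < max_lv:  # deflation exhausted early: later candidates identical
            cv_pred[test, k:] = preds[:, -1:]
    rmsecv = np.sqrt(np.mean((cv_pred - y[:, None]) ** 2, axis=0))
    return rmsecv, cv_pred


def loocv_select(X, y, max_lv: int = 15, tol: float = 0.02, folds=None, seed: int = 0):
    """Choose the latent-variable count by (leave-one-out) cross-validation.

    Returns ``(n_lv, rmsecv_curve, cv_pred)``; ``n_lv`` is the smallest
    candidate whose RMSECV is within ``(1 + tol)`` of the curve minimum.
    """
    rmsecv, cv_pred = cv_rmse_curve(X, y, max_lv, folds=folds, seed=seed)
    threshold = (1.0 + tol) * float(rmsecv.min())
    n_lv = int(np.flatnonzero(rmsecv <= threshold)[0]) + 1
    return n_lv, rmsecv, cv_pred


class NIPALSRegression(RegressorMixin, BaseEstimator):
    """scikit-learn estimator facade over :func:`fit_pls`.

    Parameters
    ----------
    n_components : int or "cv"
        Fixed latent-variable count, or ``"cv"`` to select by leave-one-out
        cross-validation up to ``max_components``.
    """

    def __init__(self, n_components=2, max_components: int = 15, cv_tol: float = 0.02):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_tol = cv_tol

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if self.n_components == "cv":
            n_lv, curve, _ = loocv_select(X, y, self.max_components, tol=self.cv_tol)
            self.rmsecv_curve_ = curve
        else:
            n_lv = int(self.n_components)
        model = fit_pls(X, y, n_lv)
        self.model_ = model
        self.n_components_ = model.n_lv
        self.coef_ = model.coef
        self.x_mean_ = model.x_mean
        self.y_mean_ = model.y_mean
        self.x_weights_ = model.x_weights
        self.x_loadings_ = model.x_loadings
        self.y_loadings_ = model.y_loadings
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("NIPALSRegression is not fitted")
        return self.model_.predict(X)
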