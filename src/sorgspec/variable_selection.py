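"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

Each of N Monte-Carlo runs fits a PLS model on a random subset of the
calibration samples using the currently retained wavelengths, then shrinks
the wavelength set in two moves: a *forced* reduction keeping the
ceil(r_i * p) variables with the largest absolute regression coefficients,
where r_i follows the exponentially decreasing function (EDF)

    r_i = a * exp(-k * i),  a = (p/2)^(1/(N-1)),  k = ln(p/2) / (N-1),

so r_1 = 1 and r_N = 2/p; and an *adaptive reweighted sampling* step that
resamples the survivors with probability proportional to |coefficient|.
Each run's wavelength set is scored by the cross-validated RMSE of a PLS
model on the full calibration set; the set with minimal RMSECV wins.  The
full-wavelength model is recorded as the run-0 baseline, so the winner never
scores worse than using every wavelength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pls import cv_rmse_curve, fit_pls


@dataclass(frozen=True)
class CARSConfig:
    n_runs: int = 50
    sample_fraction: float = 0.8
    cv_folds: int | None = 5  # None = leave-one-out
    max_components: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("need at least 2 sampling runs")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class CARSResult:
    selected: np.ndarray                 # winning wavelength indices (sorted)
    run_subsets: list[np.ndarray]        # retained set per run (index 0 = full set)
    run_rmsecv: np.ndarray               # RMSECV per run
    best_run: int

    def __post_init__(self):
        if self.selected.size == 0:
            raise ValueError("empty selection")
        if self.best_run != int(np.argmin(self.run_rmsecv)):
            raise ValueError("winning run must minimise RMSECV")


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Fraction of the p wavelengths retained by the forced reduction at run i."""
    if p < 2:
        raise ValueError("need at least 2 variables")
    if not 1 <= i <= n_runs:
        raise ValueError("run index out of range")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    return a * math.exp(-k * i)


def _subset_rmsecv(X, y, cols, config: CARSConfig) -> float:
    max_lv = min(config.max_components, len(cols), X.shape[0] - 2)
    curve, _ = cv_rmse_curve(X[:, cols], y, max_lv, folds=config.cv_folds, seed=config.seed)
    return float(curve[-1] if curve.size else np.inf)


def cars(X, y, config: CARSConfig | None = None) -> CARSResult:
    """Run CARS on calibration data only; seeded and reproducible."""
    config = config or CARSConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if np.std(y) == 0:
        raise ValueError("y is constant")
    rng = np.random.default_rng(config.seed)
    n_sub = max(3, int(round(config.sample_fraction * n)))
    n_sub = min(n_sub, n)

    retained = np.arange(p)
    run_subsets: list[np.ndarray] = [retained.copy()]
    run_scores = [_subset_rmsecv(X, y, retained, config)]
    for i in range(1, config.n_runs + 1):
        rows = rng.choice(n, size=n_sub, replace=False)
        max_lv = min(config.max_components, retained.size, n_sub - 2)
        model = fit_pls(X[np.ix_(rows, retained)], y[rows], max_lv)
        weights = np.abs(model.coef)
        # forced reduction by the EDF schedule (fraction of the original p)
        keep = max(2, min(retained.size, math.ceil(edf_ratio(i, config.n_runs, p) * p)))
        order = np.argsort(-weights, kind="stable")
        survivors = retained[np.sort(order[:keep])]
        surv_w = weights[np.sort(order[:keep])]
        # adaptive reweighted sampling: multinomial draw proportional to |coef|,
        # realised as the set of variables drawn at least once
        if surv_w.sum() > 0 and survivors.size > 2:
            probs = surv_w / surv_w.sum()
            counts = rng.multinomial(survivors.size, probs)
            sampled = survivors[counts > 0]
            if sampled.size >= 2:
                survivors = sampled
        retained = survivors
        run_subsets.append(retained.copy())
        run_scores.append(_subset_rmsecv(X, y, retained, config))

    run_rmsecv = np.asarray(run_scores)
    best = int(np.argmin(run_rmsecv))
    return CARSResult(
        selected=np.sort(run_subsets[best]),
        run_subsets=run_subsets,
        run_rmsecv=run_rmsecv,
        best_run=best,
    )


class CARSSelector:
    """Estimator-style facade: ``fit(X, y)`` then ``transform(X)`` keeps columns."""

    def __init__(self, n_runs: int = 50, sample_fraction: float = 0.8,
                 cv_folds: int | None = 5, max_components: int = 10, seed: int = 0):
        self.n_runs = n_runs
        self.sample_fraction = sample_fraction
        self.cv_folds = cv_folds
        self.max_components = max_components
        self.seed = seed

    def fit(self, X, y):
        config = CARSConfig(
            n_runs=self.n_runs, sample_fraction=self.sample_fraction,
            cv_folds=self.cv_folds, max_components=self.max_components, seed=self.seed,
        )
        result = cars(X, y, config)
        self.result_ = result
        self.support_ = np.zeros(np.atleast_2d(X).shape[1], dtype=bool)
        self.support_[result.selected] = True
        return self

    def transform(self, X):
        if not hasattr(self, "support_"):
            raise ValueError("CARSSelector is not fitted")
        return np.atleast_2d(np.asarray(X, dtype=float))[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
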