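"""PCA score-space outlier screening at a chi-square confidence ellipse.

Spectra are mean-centered, projected on the first two principal components,
and each score column standardised by its own standard deviation.  A sample
whose squared standardised score radius T^2 = z1^2 + z2^2 exceeds the
chi-square(2) quantile at the chosen confidence (5.991 at 95%) lies outside
the confidence ellipse.  Outliers are removed one at a time (the worst
offender), re-fitting PCA after each removal, until none remains or a cap is
reached; the screen never removes more than half the input samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class OutlierReport:
    kept: np.ndarray
    removed: list[tuple[int, float, int]] = field(default_factory=list)  # (index, T2, iteration)
    limit: float = 0.0

    @property
    def removed_indices(self) -> list[int]:
        return [idx for idx, _, _ in self.removed]


def pca_scores(X, n_components: int = 2):
    """Column-mean-centered PCA scores and explained-variance fractions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA screening needs at least 3 samples")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components must be <= {min(n - 1, p)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_


def _t2(scores: np.ndarray, per_axis: bool = False):
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = scores / sd
    if per_axis:
        return np.abs(z)  # caller compares each axis to a normal quantile
    return np.sum(z**2, axis=1)


def flag_outliers(X, alpha: float = 0.95):
    """One-pass flags: boolean mask of samples outside the CI(95%) ellipse."""
    scores, _ = pca_scores(X, 2)
    limit = stats.chi2.ppf(alpha, df=2)
    return _t2(scores) > limit, limit


def screen_outliers(
    X,
    alpha: float = 0.95,
    max_removals: int | None = None,
    ellipse: bool = True,
) -> OutlierReport:
    """Iterative individual removal of PCA score outliers.

    ``ellipse=True`` uses the chi-square(2) ellipse on standardised scores;
    ``ellipse=False`` uses two per-axis normal intervals instead (rectangle),
    flagging samples outside either axis interval.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = X.shape[0]
    if n < 10:
        warnings.warn("outlier screening on fewer than 10 samples is unreliable",
                      stacklevel=2)
    floor = n - n // 2  # never drop below 50% of the input
    if max_removals is None:
        max_removals = n
    limit = stats.chi2.ppf(alpha, df=2) if ellipse else stats.norm.ppf(0.5 + alpha / 2.0)
    kept = np.arange(n)
    removed: list[tuple[int, float, int]] = []
    iteration = 0
    while len(removed) < max_removals:
        if kept.size <= max(floor, 3):
            if kept.size <= floor and max_removals > 0:
                warnings.warn("outlier screen reached the 50% removal floor", stacklevel=2)
            break
        iteration += 1
        scores, _ = pca_scores(X[kept], 2)
        if ellipse:
            stat = _t2(scores)
        else:
            stat = _t2(scores, per_axis=True).max(axis=1)
        worst = int(np.argmax(stat))
        if stat[worst] <= limit:
            break
        removed.append((int(kept[worst]), float(stat[worst]), iteration))
        kept = np.delete(kept, worst)
    return OutlierReport(kept=kept, removed=removed, limit=float(limit))


class PCAOutlierScreen:
    """Estimator facade: ``fit(X)`` computes ``kept_``/``report_``."""

    def __init__(self, alpha: float = 0.95, max_removals: int | None = None,
                 ellipse: bool = True):
        self.alpha = alpha
        self.max_removals = max_removals
        self.ellipse = ellipse

    def fit(self, X, y=None):
        self.report_ = screen_outliers(X, self.alpha, self.max_removals, self.ellipse)
        self.kept_ = self.report_.kept
        return self

    def transform(self, X):
        if not hasattr(self, "kept_"):
            raise ValueError("PCAOutlierScreen is not fitted")
        return np.atleast_2d(np.asarray(X, dtype=float))[self.kept_]
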