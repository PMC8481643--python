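"""Shared independent oracles and benchmark builders for the test suite."""

import numpy as np


def make_cars_benchmark(rep: int, n: int = 150, p: int = 200, n_informative: int = 10,
                        snr: float = 20.0):
    """Seeded sparse-signal benchmark: 10 informative of 200 i.i.d. variables."""
    rs = np.random.default_rng(1000 + rep)
    X = rs.standard_normal((n, p))
    informative = rs.choice(p, n_informative, replace=False)
    beta = np.ones(n_informative) * rs.choice([-1.0, 1.0], n_informative)
    signal = X[:, informative] @ beta
    y = signal + (signal.std() / snr) * rs.standard_normal(n)
    return X, y, set(int(i) for i in informative)


def brute_force_maximin(D, n_cal):
    """Loop-based re-implementation of the greedy maximin selection rule."""
    n = D.shape[0]
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best:
                best, pair = D[i, j], (i, j)
    selected = list(pair)
    while len(selected) < n_cal:
        best_val, best_idx = -1.0, None
        for cand in range(n):
            if cand in selected:
                continue
            dmin = min(D[cand, s] for s in selected)
            if dmin > best_val:
                best_val, best_idx = dmin, cand
        selected.append(best_idx)
    return selected


def joint_distance(X, y):
    """SPXY joint distance matrix, written independently of the implementation."""
    DX = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    Dy = np.abs(y[:, None] - y[None, :])
    D = DX / DX.max()
    if Dy.max() > 0:
        D = D + Dy / Dy.max()
    return D


def ols_predictions(X, y, X_new):
    """Closed-form least-squares oracle with intercept."""
    Xc = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    return np.column_stack([np.ones(len(X_new)), X_new]) @ beta
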