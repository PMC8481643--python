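"""Deterministic calibration/validation splitting: Kennard-Stone and SPXY.

Both algorithms greedily build the calibration subset: start from the pair at
maximal distance, then repeatedly add the sample whose minimum distance to
the already-selected set is largest.  SPXY uses a joint distance combining
spectral (X) and analyte (y) distances, each normalised by its maximum, so
the split also spans the response range.  Ties are broken by lowest index.

The study ratio is 3:1, i.e. ``n_cal = floor(3n/4)``: 98 -> 73/25,
61 -> 45/16, 37 -> 27/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/validation index sets covering all samples."""

    calibration: np.ndarray
    validation: np.ndarray
    method: str
    selection_order: tuple[int, ...] = field(default=())

    def __post_init__(self):
        cal = np.asarray(self.calibration, dtype=int)
        val = np.asarray(self.validation, dtype=int)
        object.__setattr__(self, "calibration", cal)
        object.__setattr__(self, "validation", val)
        n = cal.size + val.size
        if set(cal) & set(val) or set(cal) | set(val) != set(range(n)):
            raise ValueError("calibration/validation must partition 0..n-1")


def calibration_size(n: int, ratio: float = 0.75) -> int:
    """Calibration size at the 3:1 ratio: floor(3n/4) by default."""
    return int(np.floor(n * ratio))


def _greedy_maximin(D: np.ndarray, n_cal: int, method: str) -> SplitResult:
    n = D.shape[0]
    if not 2 <= n_cal < n:
        raise ValueError(f"need 2 <= n_cal < n, got n_cal={n_cal}, n={n}")
    # seed pair: maximal distance, ties -> lexicographically smallest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    k = int(np.argmax(flat))  # argmax returns the first (lowest-index) maximum
    first, second = int(iu[0][k]), int(iu[1][k])
    selected = [first, second]
    in_set = np.zeros(n, dtype=bool)
    in_set[[first, second]] = True
    # min distance from every sample to the selected set
    mind = np.minimum(D[first], D[second])
    mind[in_set] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(mind))  # ties broken by lowest index
        selected.append(nxt)
        in_set[nxt] = True
        mind = np.minimum(mind, D[nxt])
        mind[in_set] = -np.inf
    validation = np.flatnonzero(~in_set)
    return SplitResult(
        calibration=np.array(sorted(selected)),
        validation=validation,
        method=method,
        selection_order=tuple(selected),
    )


def kennard_stone(X, n_cal: int) -> SplitResult:
    """Kennard-Stone maximin split on Euclidean distances in X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = squareform(pdist(X, metric="euclidean"))
    return _greedy_maximin(D, n_cal, "KS")


def spxy(X, y, n_cal: int) -> SplitResult:
    """SPXY split on d(i,j) = d_X(i,j)/max d_X + d_y(i,j)/max d_y.

    With constant y (max d_y = 0) the y-term is dropped and the result equals
    Kennard-Stone on X.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("y length must match the number of samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    DX = squareform(pdist(X, metric="euclidean"))
    Dy = np.abs(y[:, None] - y[None, :])
    D = DX / DX.max() if DX.max() > 0 else DX
    if Dy.max() > 0:
        D = D + Dy / Dy.max()
    return _greedy_maximin(D, n_cal, "SPXY")
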