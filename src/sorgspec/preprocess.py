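"""Spectral pretreatments: MSC, SNV, Savitzky-Golay smoothing/derivatives.

All operators are exposed both as scikit-learn transformers (so they compose
in ``sklearn.pipeline.Pipeline``) and as plain functions.  A
:class:`PreprocessRecipe` chains scatter correction followed by SG
smoothing/derivative, the order the calibration recipes list them; the
fitted state (the MSC reference spectrum) is retained so validation spectra
are corrected against the calibration reference.

Mean-centering is deliberately *not* part of a recipe — it happens inside
model fitting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multiplicative scatter correction


def msc(X, reference=None, return_coef: bool = False):
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference by ordinary least squares,
    x_i ~ a_i + b_i * ref, and corrected as (x_i - a_i) / b_i.  With no
    reference given, the column mean of ``X`` is used (requires >= 2 rows).

    Returns the corrected matrix, or ``(corrected, a, b, reference)`` when
    ``return_coef`` is true.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise PreprocessError("MSC needs >= 2 samples when no reference is given")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.shape[1],):
        raise PreprocessError("MSC reference length mismatch")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-24:
        raise PreprocessError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) < 1e-12)
    if bad.size:
        raise PreprocessError(f"MSC slope numerically zero for sample index {bad[0]}")
    a = X.mean(axis=1) - b * reference.mean()
    corrected = (X - a[:, None]) / b[:, None]
    if return_coef:
        return corrected, a, b, reference
    return corrected


class MultiplicativeScatterCorrection(TransformerMixin, BaseEstimator):
    """MSC as a transformer; ``fit`` stores the calibration mean spectrum."""

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
        else:
            if X.shape[0] < 2:
                raise PreprocessError("MSC needs >= 2 samples to fit a reference")
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise PreprocessError("MultiplicativeScatterCorrection is not fitted")
        return msc(X, reference=self.reference_)


# ---------------------------------------------------------------------------
# standard normal variate


def snv(X):
    """Row-wise centering to mean 0 and scaling to unit sd (n-1 denominator)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise PreprocessError("SNV needs >= 2 wavelengths")
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd < 1e-15)
    if bad.size:
        raise PreprocessError(f"SNV: constant spectrum at sample index {bad[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Stateless SNV transformer."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv(X)


# ---------------------------------------------------------------------------
# Savitzky-Golay


def savgol(X, window: int, polyorder: int, derivative_order: int = 0):
    """Savitzky-Golay smoothing / derivative, row-wise.

    Derivatives are per index step (not per cm^-1).  Edges are handled by
    polynomial extrapolation of the terminal window fits, so output length
    equals input length.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise PreprocessError("SG window must be odd")
    if window <= polyorder:
        raise PreprocessError("SG window must exceed the polynomial order")
    if derivative_order > polyorder:
        raise PreprocessError("SG derivative order cannot exceed the polynomial order")
    if X.shape[1] < window:
        raise PreprocessError("fewer wavelengths than the SG window")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=derivative_order,
        delta=1.0, axis=1, mode="interp",
    )


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Stateless SG smoothing/derivative transformer."""

    def __init__(self, window: int = 51, polyorder: int = 2, derivative_order: int = 0):
        self.window = window
        self.polyorder = polyorder
        self.derivative_order = derivative_order

    def fit(self, X, y=None):
        savgol(np.zeros((1, max(self.window, 1))), self.window, self.polyorder,
               self.derivative_order)  # validate parameters
        return self

    def transform(self, X):
        return savgol(X, self.window, self.polyorder, self.derivative_order)


def norris_derivative(X, gap: int = 5, segment: int = 5, order: int = 1):
    """Norris gap-segment derivative (optional alternative to SG).

    Segment-averaged finite differences with a gap, per index step.  Edges
    are padded by replicating the terminal values.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if gap < 1 or segment < 1 or segment % 2 == 0:
        raise PreprocessError("gap >= 1 and odd segment >= 1 required")
    if order not in (1, 2):
        raise PreprocessError("Norris derivative order must be 1 or 2")
    half = segment // 2
    pad = gap + half
    Xp = np.pad(X, ((0, 0), (pad, pad)), mode="edge")
    # segment (moving) average
    kernel = np.ones(segment) / segment
    avg = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, Xp)
    n = X.shape[1]
    center = slice(pad, pad + n)
    left = slice(pad - gap, pad - gap + n)
    right = slice(pad + gap, pad + gap + n)
    if order == 1:
        return (avg[:, right] - avg[:, left]) / (2.0 * gap)
    return (avg[:, right] - 2.0 * avg[:, center] + avg[:, left]) / (gap**2)


# ---------------------------------------------------------------------------
# recipes

_RECIPE_RE = re.compile(
    r"^(?:(MSC|SNV)\+)?SG(?P<window>\d+)p(?P<poly>\d+)d(?P<deriv>\d+)$", re.IGNORECASE
)


@dataclass(frozen=True)
class PreprocessRecipe:
    """Ordered pretreatment chain: scatter correction, then SG derivative.

    ``scatter_correction`` is one of ``"MSC"``, ``"SNV"``, ``"none"``.
    """

    scatter_correction: str = "none"
    smoothing_window: int = 51
    polyorder: int = 2
    derivative_order: int = 2

    def __post_init__(self):
        if self.scatter_correction not in ("MSC", "SNV", "none"):
            raise PreprocessError(f"unknown scatter correction {self.scatter_correction!r}")
        if self.smoothing_window % 2 == 0 or self.smoothing_window <= self.polyorder:
            raise PreprocessError("smoothing window must be odd and > polyorder")
        if self.derivative_order not in (0, 1, 2) or self.derivative_order > self.polyorder:
            raise PreprocessError("derivative order must be in {0,1,2} and <= polyorder")

    @classmethod
    def parse(cls, text: str) -> "PreprocessRecipe":
        """Parse a recipe string like ``"MSC+SG51p2d2"`` or ``"SG51p2d0"``."""
        m = _RECIPE_RE.match(text.strip())
        if not m:
            raise PreprocessError(f"cannot parse recipe {text!r}")
        scatter = (m.group(1) or "none").upper()
        if scatter == "NONE":
            scatter = "none"
        return cls(
            scatter_correction=scatter,
            smoothing_window=int(m.group("window")),
            polyorder=int(m.group("poly")),
            derivative_order=int(m.group("deriv")),
        )

    def __str__(self) -> str:
        prefix = "" if self.scatter_correction == "none" else self.scatter_correction + "+"
        return f"{prefix}SG{self.smoothing_window}p{self.polyorder}d{self.derivative_order}"


def apply_recipe(X, recipe: PreprocessRecipe, fitted_state: dict | None = None):
    """Apply a recipe; returns ``(treated, fitted_state)``.

    ``fitted_state`` carries the MSC reference spectrum fitted on calibration
    data so the identical transform applies to validation spectra.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    state = dict(fitted_state) if fitted_state else {}
    if recipe.scatter_correction == "MSC":
        ref = state.get("msc_reference")
        if ref is None:
            if X.shape[0] < 2:
                raise PreprocessError("MSC needs >= 2 samples to fit a reference")
            ref = X.mean(axis=0)
            state["msc_reference"] = ref
        X = msc(X, reference=np.asarray(ref, dtype=float))
    elif recipe.scatter_correction == "SNV":
        X = snv(X)
    X = savgol(X, recipe.smoothing_window, recipe.polyorder, recipe.derivative_order)
    return X, state
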