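"""Water-region masking and spectral preprocessing transforms.

Eight method ids are supported: RAW (identity), SNV, SG, SG1, SG2, S_SG,
S_SG1, S_SG2 — i.e. standard normal variate, an 11-point Savitzky-Golay
smoother, its first/second derivatives, and the SNV-then-SG compositions.
When both appear, SNV is applied first, then the SG smoothing/derivative.

The Savitzky-Golay filter fits a local least-squares polynomial in each
window; derivatives are the analytic derivatives of that polynomial, scaled
by the grid step.  At the boundaries the window is truncated to the
available points and the polynomial refit there (no padding), so no data
are fabricated at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "PreprocessMethod",
    "METHOD_IDS",
    "DEFAULT_OMIT",
    "mask_water_regions",
    "snv",
    "savitzky_golay",
    "apply_method",
]

#: method id -> (use SNV, SG derivative order or None)
_METHOD_TABLE: dict[str, tuple[bool, int | None]] = {
    "RAW": (False, None),
    "SNV": (True, None),
    "SG": (False, 0),
    "SG1": (False, 1),
    "SG2": (False, 2),
    "S_SG": (True, 0),
    "S_SG1": (True, 1),
    "S_SG2": (True, 2),
}

METHOD_IDS = tuple(_METHOD_TABLE)

#: omitted water windows: O-H bending and everything past the O-H stretch
#: onset; the retained grid is [926, 1618] U [1705, 3025] cm^-1.
DEFAULT_OMIT: tuple[tuple[float, float], ...] = ((1618.0, 1705.0), (3025.0, np.inf))


@dataclass(frozen=True)
class PreprocessMethod:
    """A named preprocessing recipe (see module docstring for the ids)."""

    id: str
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.id not in _METHOD_TABLE:
            raise ValueError(f"unknown method id {self.id!r}; valid: {METHOD_IDS}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.deriv_order is not None and self.deriv_order > self.sg_polyorder:
            raise ValueError("derivative order exceeds polynomial order")

    @property
    def use_snv(self) -> bool:
        return _METHOD_TABLE[self.id][0]

    @property
    def deriv_order(self) -> int | None:
        return _METHOD_TABLE[self.id][1]


def mask_water_regions(
    s: SpectraSet,
    omit: tuple[tuple[float, float], ...] = DEFAULT_OMIT,
) -> SpectraSet:
    """Drop grid points strictly inside any ``(lo, hi)`` omit window.

    Interval ends are kept (retained regions are closed), sample metadata is
    untouched.  An empty omit list is the identity.
    """
    keep = np.ones(s.n_points, dtype=bool)
    for lo, hi in omit:
        if lo >= hi:
            raise ValueError(f"invalid omit interval ({lo}, {hi})")
        keep &= ~((s.wavenumbers > lo) & (s.wavenumbers < hi))
    if not keep.any():
        raise ValueError("masking removed every grid point")
    return s.select_points(keep)


def snv(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to unit SD.

    Works on a single spectrum (1-D) or a matrix of spectra (2-D, one row
    per spectrum).  ``ddof=1`` (sample SD) by default.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero variance: SNV undefined for a constant spectrum")
    out = (X - mu) / sd
    return out[0] if one_d else out


def _factorial(d: int) -> int:
    out = 1
    for i in range(2, d + 1):
        out *= i
    return out


def savitzky_golay(
    x: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
    step: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation with truncated-window edges.

    ``step`` is the grid spacing in cm^-1; derivatives are returned per
    cm^-1 (scaled by 1/step^deriv).  Accepts a spectrum or a matrix of
    spectra (last axis = wavenumber).
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    half = window // 2
    out = savgol_filter(x, window, polyorder, deriv=deriv, delta=step, axis=-1)
    # boundary points: refit over the truncated window, no padding
    n = x.shape[-1]
    for i in range(half):
        # left edge point i: window covers indices 0 .. i+half (offsets -i .. +half)
        out[..., i] = x[..., 0 : i + half + 1] @ _trunc_weights(i, half, polyorder, deriv, step)
        # right edge point n-1-i: indices n-1-i-half .. n-1 (offsets -half .. +i)
        j = n - 1 - i
        out[..., j] = x[..., j - half : n] @ _trunc_weights(half, i, polyorder, deriv, step)
    return out


def _trunc_weights(
    n_left: int, n_right: int, polyorder: int, deriv: int, step: float
) -> np.ndarray:
    """Weights giving the ``deriv``-th derivative at offset 0 of the local
    least-squares polynomial fit over integer offsets [-n_left, n_right]."""
    t = np.arange(-n_left, n_right + 1) * step
    A = np.vander(t, polyorder + 1, increasing=True)
    return np.linalg.pinv(A)[deriv] * _factorial(deriv)


def apply_method(s: SpectraSet, m: PreprocessMethod) -> SpectraSet:
    """Apply a preprocessing recipe to every spectrum of a set."""
    X = s.absorbance
    if m.use_snv:
        X = snv(X)
    if m.deriv_order is not None:
        step = float(np.median(np.diff(s.wavenumbers)))
        X = savitzky_golay(X, m.sg_window, m.sg_polyorder, m.deriv_order, step)
    return s.with_absorbance(np.array(X))
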