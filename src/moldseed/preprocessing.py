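"""Chemometric spectral preprocessing.

All operations act row-wise on an (n_spectra, n_bands) matrix and are
row-separable: permuting rows commutes with every transform.

* ``snv`` — standard normal variate: per-row centering to mean 0, sd 1.
* ``msc`` — multiplicative scatter correction: per-row OLS fit against a
  reference spectrum (default: column mean), then inversion of the fitted
  gain/offset.
* ``smooth`` / ``derivative`` — Savitzky-Golay filtering; derivatives are
  scaled by the wavelength step so units are per-nm.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["snv", "msc", "smooth", "derivative"]


def _as_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D spectra matrix (rows = spectra)")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra matrix contains non-finite values")
    return X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample sd 1 (ddof=1)."""
    X = _as_matrix(X)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero-variance row(s) {zero.tolist()}: SNV undefined")
    return (X - mean) / sd


def msc(
    X: np.ndarray,
    reference: np.ndarray | None = None,
    *,
    a_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Fits x_i ≈ a_i * ref + b_i per row by OLS and returns
    ``((x_i - b_i) / a_i, a, b)``.  With ``reference=None`` the column mean
    of X is used (requires n >= 2).
    """
    X = _as_matrix(X)
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("MSC needs n >= 2 rows when no reference is given")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.shape[0] != X.shape[1]:
        raise ValueError("reference length != band count")

    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("constant reference spectrum: MSC undefined")
    a = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    b = X.mean(axis=1) - a * ref.mean()
    small = np.flatnonzero(np.abs(a) < a_tol)
    if small.size:
        raise ValueError(f"near-zero MSC gain in row(s) {small.tolist()}")
    corrected = (X - b[:, None]) / a[:, None]
    return corrected, a, b


def _check_sg(window: int, polyorder: int, n_bands: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window > n_bands:
        raise ValueError(f"window {window} exceeds band count {n_bands}")


def smooth(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Row-wise Savitzky-Golay smoothing (same-length output)."""
    X = _as_matrix(X)
    _check_sg(window, polyorder, X.shape[1])
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1)


def derivative(
    X: np.ndarray,
    wavelengths_nm: np.ndarray,
    order: int = 1,
    window: int = 11,
    polyorder: int = 2,
    *,
    grid_rtol: float = 1e-6,
) -> np.ndarray:
    """Savitzky-Golay derivative of order 1 or 2, in per-nm units.

    Requires a uniform wavelength grid (SG assumes even sampling).
    """
    X = _as_matrix(X)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    _check_sg(window, polyorder, X.shape[1])
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.shape[0] != X.shape[1]:
        raise ValueError("wavelength grid length != band count")
    steps = np.diff(wl)
    step = steps.mean()
    if step <= 0 or np.any(np.abs(steps - step) > grid_rtol * abs(step)):
        raise ValueError("wavelength grid must be uniform for SG derivatives")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=order,
        delta=step, axis=1,
    )
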