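"""Per-spectrum mathematical pre-treatments, applied in a fixed order.

The chain is: trim to the analysis window -> baseline offset correction ->
standard normal variate (SNV) -> Savitzky-Golay second derivative. Each stage
operates on one spectrum at a time, so the chain cannot leak information
between training and held-out spectra.

* Baseline offset subtracts each spectrum's own minimum, removing additive
  baseline shifts.
* SNV centres each spectrum and scales it to unit (n-1) standard deviation,
  removing multiplicative scatter.
* The Savitzky-Golay second derivative fits a local least-squares polynomial
  over a sliding window and reports its second derivative in AU/nm**2,
  sharpening overlapping vibrational bands. The configured "smoothing points"
  count is rounded up to the nearest odd window length; edge points without a
  full window are dropped, so all spectra shrink to a common interior grid.

The transformer classes follow the scikit-learn estimator API (stateless
``fit``, per-row ``transform``) and compose with sklearn pipelines; the
module-level functions are thin wrappers used by the dataset-level chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset, trim_wavelengths


class DegenerateSpectrumError(ValueError):
    """A spectrum cannot be preprocessed (zero variance, non-finite, too short)."""


@dataclass
class PreprocessConfig:
    """Configuration of the pre-treatment chain.

    ``sg_points`` counts the smoothing points of the derivative filter; an
    even count is widened to the next odd integer so the window is symmetric
    (24 -> effective window 25).
    """

    do_baseline: bool = True
    do_snv: bool = True
    derivative_order: int = 2
    sg_polyorder: int = 2
    sg_points: int = 24
    window_nm: tuple[float, float] | None = (900.0, 2400.0)
    baseline_mode: str = "offset"  # "offset" | "detrend"

    def __post_init__(self) -> None:
        if self.derivative_order not in (0, 2):
            raise ValueError("derivative_order must be 0 (off) or 2")
        if self.baseline_mode not in ("offset", "detrend"):
            raise ValueError("baseline_mode must be 'offset' or 'detrend'")
        if self.derivative_order == 2:
            if self.sg_polyorder < 2:
                raise ValueError("second derivative needs sg_polyorder >= 2")
            if self.effective_window < self.sg_polyorder + 1:
                raise ValueError("SG window shorter than polyorder + 1")

    @property
    def effective_window(self) -> int:
        """Odd window length actually used by the derivative filter."""
        w = int(self.sg_points)
        return w if w % 2 == 1 else w + 1


# ---------------------------------------------------------------------------
# stage functions (operate on 1-D spectra or 2-D row-stacked matrices)


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DegenerateSpectrumError("spectrum contains non-finite values")
    was_1d = x.ndim == 1
    return np.atleast_2d(x), was_1d


def baseline_offset(spectrum: np.ndarray) -> np.ndarray:
    """Subtract each spectrum's own minimum; the output minimum is exactly 0."""
    x, was_1d = _as_matrix(spectrum)
    out = x - x.min(axis=1, keepdims=True)
    return out[0] if was_1d else out


def baseline_detrend(spectrum: np.ndarray, wavelengths_nm: np.ndarray) -> np.ndarray:
    """Remove a least-squares straight line per spectrum (optional variant)."""
    x, was_1d = _as_matrix(spectrum)
    wl = np.asarray(wavelengths_nm, dtype=float)
    design = np.column_stack([np.ones_like(wl), wl - wl.mean()])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    out = x - (design @ coef).T
    return out[0] if was_1d else out


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum mean 0, (n-1) standard deviation 1."""
    x, was_1d = _as_matrix(spectrum)
    if x.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs at least two points per spectrum")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd[:, 0] == 0.0)
    if degenerate.size:
        raise DegenerateSpectrumError(
            f"zero-variance spectrum at row {degenerate[0]}: SNV undefined"
        )
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out[0] if was_1d else out


def savgol_second_derivative(
    spectrum: np.ndarray,
    wavelengths_nm: np.ndarray,
    polyorder: int = 2,
    window_points: int = 24,
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay second derivative in AU/nm**2 on the interior grid.

    Fits a degree-``polyorder`` polynomial over each odd-length window (an
    even ``window_points`` is widened by one). The filter is evaluated in
    index space and rescaled by the squared local mean grid step, which on a
    uniform grid equals the exact SG derivative and on a mildly non-uniform
    grid uses the window's mean spacing. Returns ``(interior_wavelengths,
    derivative)``; the ``window//2`` edge points on each side are dropped.
    """
    x, was_1d = _as_matrix(spectrum)
    wl = np.asarray(wavelengths_nm, dtype=float)
    w = int(window_points)
    if w % 2 == 0:
        w += 1
    if polyorder < 2:
        raise ValueError("second derivative needs polyorder >= 2")
    if w > x.shape[1]:
        raise DegenerateSpectrumError(
            f"spectrum has {x.shape[1]} points, shorter than the {w}-point window"
        )
    half = w // 2
    coeffs = savgol_coeffs(w, polyorder, deriv=2, delta=1.0, use="dot")
    windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)
    d2_index = windows @ coeffs  # d2/d(index)2 at each window centre
    # local mean step across each window (exact for uniform grids)
    local_step = (wl[2 * half :] - wl[: wl.size - 2 * half]) / (w - 1)
    out = d2_index / local_step**2
    wl_out = wl[half : wl.size - half]
    return wl_out, (out[0] if was_1d else out)


# ---------------------------------------------------------------------------
# sklearn-style transformers


class BaselineOffset(TransformerMixin, BaseEstimator):
    """Per-spectrum baseline offset removal (subtract the row minimum)."""

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X):
        return baseline_offset(np.asarray(X, dtype=float))


class StandardNormalVariate(TransformerMixin, BaseEstimator):
    """Per-spectrum SNV scatter correction (row mean 0, row sd 1)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv(np.asarray(X, dtype=float))


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Second-derivative SG filter; output drops the half-window edges.

    Parameters
    ----------
    window_points : int
        Smoothing points; even values widen to the next odd window.
    polyorder : int
        Degree of the local polynomial (>= 2).
    wavelengths_nm : array-like or None
        Grid used for nm scaling. When None, unit spacing is assumed and the
        output is in AU/index**2.
    """

    def __init__(self, window_points: int = 24, polyorder: int = 2, wavelengths_nm=None):
        self.window_points = window_points
        self.polyorder = polyorder
        self.wavelengths_nm = wavelengths_nm

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        wl = (
            np.arange(X.shape[-1], dtype=float)
            if self.wavelengths_nm is None
            else np.asarray(self.wavelengths_nm, dtype=float)
        )
        _, out = savgol_second_derivative(X, wl, self.polyorder, self.window_points)
        return out


# ---------------------------------------------------------------------------
# dataset-level chain


def preprocess_chain(ds: SpectralDataset, cfg: PreprocessConfig) -> SpectralDataset:
    """Apply trim -> baseline -> SNV -> 2nd derivative to every spectrum.

    Stage order is fixed. Metadata passes through untouched; stage errors are
    re-raised with the offending spectrum_id.
    """
    if cfg.window_nm is not None:
        ds = trim_wavelengths(ds, *cfg.window_nm)
    wl, X = ds.wavelengths_nm, ds.absorbance
    try:
        if cfg.do_baseline:
            X = (
                baseline_offset(X)
                if cfg.baseline_mode == "offset"
                else baseline_detrend(X, wl)
            )
        if cfg.do_snv:
            X = snv(X)
        if cfg.derivative_order == 2:
            wl, X = savgol_second_derivative(X, wl, cfg.sg_polyorder, cfg.sg_points)
    except DegenerateSpectrumError as exc:
        # identify the first offending spectrum for the error message
        sid = _first_bad_spectrum(ds, cfg)
        raise DegenerateSpectrumError(f"spectrum {sid!r}: {exc}") from exc
    return SpectralDataset(wl, X, ds.meta.reset_index(drop=True))


def _first_bad_spectrum(ds: SpectralDataset, cfg: PreprocessConfig) -> str:
    for i in range(ds.n_spectra):
        row = ds.absorbance[i]
        try:
            if cfg.do_baseline:
                row = baseline_offset(row)
            if cfg.do_snv:
                row = snv(row)
            if cfg.derivative_order == 2:
                savgol_second_derivative(
                    row, ds.wavelengths_nm, cfg.sg_polyorder, cfg.sg_points
                )
        except DegenerateSpectrumError:
            return str(ds.meta["spectrum_id"].iloc[i])
    return "<unknown>"
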