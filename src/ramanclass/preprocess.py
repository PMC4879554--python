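"""Spectral preprocessing: the two standard paths used throughout.

Classification path (multivariate analysis):
    optional background subtraction -> Savitzky-Golay first derivative
    (window 3, polynomial order 1) -> linear interpolation onto a uniform
    region grid -> vector (unit Euclidean norm) normalization.

Mean-spectrum path (band comparison):
    background subtraction -> interpolation -> pointwise averaging ->
    fifth-order polynomial baseline correction -> Savitzky-Golay smoothing
    (window 3) -> vector normalization.

The first derivative suppresses the slowly varying fluorescence
background that dominates raw biological Raman spectra; vector
normalization removes acquisition-to-acquisition intensity scaling
(laser power, focus, pellet density).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .spectra_io import REGIONS, Spectrum, SpectrumSet, SpectrumValidationError

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "sg_first_derivative",
    "sg_smooth",
    "interpolate_region",
    "vector_normalize",
    "baseline_correct",
    "classification_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of both preprocessing paths.

    Attributes
    ----------
    sg_window : int
        Savitzky-Golay window length in points; odd, >= 3. Default 3.
    sg_polyorder : int
        Polynomial order of the SG fit; must be < sg_window.  At window 3
        only orders <= 2 exist; order 1 makes the first derivative the
        central-difference estimate.
    region : str
        One of ``fingerprint`` (700-1800), ``high_wavenumber`` (2800-3100)
        or ``tissue`` (1200-1800 cm^-1).
    interp_step : float
        Uniform grid step for region interpolation, cm^-1.
    baseline_poly_order : int
        Order of the polynomial baseline fit on the mean-spectrum path.
    normalize : str
        ``vector`` (unit Euclidean norm) or ``none``.
    """

    sg_window: int = 3
    sg_polyorder: int = 1
    deriv_order: int = 1
    region: str = "fingerprint"
    interp_step: float = 1.0
    baseline_poly_order: int = 5
    normalize: str = "vector"
    background: Spectrum | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd and >= 3, got {self.sg_window}")
        if not (0 <= self.sg_polyorder < self.sg_window):
            raise ValueError("sg_polyorder must satisfy 0 <= order < window")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; choose from {sorted(REGIONS)}")
        if self.interp_step <= 0:
            raise ValueError("interp_step must be positive")
        if self.normalize not in ("vector", "none"):
            raise ValueError("normalize must be 'vector' or 'none'")

    @property
    def region_bounds(self) -> tuple[float, float]:
        return REGIONS[self.region]

    def with_region(self, region: str) -> "PreprocessConfig":
        return replace(self, region=region)


def _uniform_step(w: np.ndarray, rtol: float = 1e-6) -> float | None:
    """Return the grid step if the axis is uniform (to relative tol), else None."""
    dw = np.diff(w)
    step = dw.mean()
    if np.all(np.abs(dw - step) <= rtol * abs(step)):
        return float(step)
    return None


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Subtract an instrument/substrate background, pointwise.

    The background is linearly interpolated onto the spectrum's axis; it
    must cover the spectrum's full support.  Negative results are allowed
    — the derivative path is shift- and sign-tolerant.
    """
    w = spectrum.wavenumbers
    bw = background.wavenumbers
    if bw[0] > w[0] or bw[-1] < w[-1]:
        raise SpectrumValidationError(
            f"background support [{bw[0]:g}, {bw[-1]:g}] does not cover "
            f"spectrum support [{w[0]:g}, {w[-1]:g}]"
        )
    bg = np.interp(w, bw, background.intensities)
    return spectrum.copy_with(intensities=spectrum.intensities - bg)


def _savgol(spectrum: Spectrum, window: int, polyorder: int, deriv: int) -> Spectrum:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window >= len(spectrum):
        raise ValueError(f"window {window} >= spectrum length {len(spectrum)}")
    step = _uniform_step(spectrum.wavenumbers)
    if step is None:
        raise SpectrumValidationError(
            "Savitzky-Golay filtering requires a uniform wavenumber axis; "
            "interpolate the spectrum onto a uniform grid first"
        )
    # mode='interp' fits a one-sided polynomial of the same order at the ends.
    y = savgol_filter(
        spectrum.intensities, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=step, mode="interp",
    )
    return spectrum.copy_with(intensities=y)


def sg_first_derivative(spectrum: Spectrum, window: int = 3, polyorder: int = 1) -> Spectrum:
    """Savitzky-Golay first derivative (units: intensity per cm^-1).

    Exact on polynomials up to ``polyorder``; a linear ramp a*nu + b maps
    to the constant a.
    """
    if polyorder < 1:
        raise ValueError("first derivative needs polyorder >= 1")
    return _savgol(spectrum, window, polyorder, deriv=1)


def sg_smooth(spectrum: Spectrum, window: int = 3, polyorder: int = 1) -> Spectrum:
    """Savitzky-Golay smoothing; preserves polynomials up to ``polyorder`` exactly."""
    return _savgol(spectrum, window, polyorder, deriv=0)


def region_grid(region: str, step: float = 1.0) -> np.ndarray:
    """The uniform analysis grid for a named region (endpoints inclusive)."""
    lo, hi = REGIONS[region]
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def interpolate_region(spectrum: Spectrum, region: str, step: float = 1.0) -> Spectrum:
    """Linearly interpolate onto the uniform grid of a named region.

    The region must lie within the spectrum's support; the error message
    states the achievable bounds otherwise.
    """
    lo, hi = REGIONS[region]
    w = spectrum.wavenumbers
    if lo < w[0] or hi > w[-1]:
        raise SpectrumValidationError(
            f"region {region} [{lo:g}, {hi:g}] outside spectrum support; "
            f"achievable bounds are [{w[0]:g}, {w[-1]:g}]"
        )
    grid = region_grid(region, step)
    y = np.interp(grid, w, spectrum.intensities)
    return spectrum.copy_with(wavenumbers=grid, intensities=y, region=region)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise SpectrumValidationError("cannot vector-normalize an all-zero spectrum")
    return spectrum.copy_with(intensities=spectrum.intensities / norm)


def baseline_correct(spectrum: Spectrum, poly_order: int = 5) -> Spectrum:
    """Subtract a least-squares polynomial baseline of the given order.

    The fit uses the whole spectrum without peak masking.  The residual
    has (numerically) zero projection onto the polynomial basis, so a
    pure polynomial input of the same order is annihilated and the
    operation is idempotent.
    """
    if len(spectrum) <= poly_order + 1:
        raise SpectrumValidationError(
            f"need more than {poly_order + 1} points for an order-{poly_order} baseline"
        )
    # Polynomial.fit maps the axis to [-1, 1] internally, which keeps the
    # order-5 fit well conditioned over e.g. 700-1800 cm^-1.
    fit = Polynomial.fit(spectrum.wavenumbers, spectrum.intensities, deg=poly_order)
    baseline = fit(spectrum.wavenumbers)
    return spectrum.copy_with(intensities=spectrum.intensities - baseline)


def _resample_uniform(spectrum: Spectrum, step: float) -> Spectrum:
    """Resample the full support onto a uniform grid (pre-derivative helper)."""
    w = spectrum.wavenumbers
    n = int(np.floor((w[-1] - w[0]) / step))
    grid = w[0] + step * np.arange(n + 1)
    return spectrum.copy_with(wavenumbers=grid, intensities=np.interp(grid, w, spectrum.intensities))


def classification_pipeline(sset: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Run the classification preprocessing path over a whole set.

    Per spectrum: optional background subtraction -> SG first derivative ->
    region interpolation -> vector normalization.  The returned set has a
    common axis (the uniform region grid) and is ready for PCA.  Spectra
    not on a uniform native grid are first resampled at ``interp_step``
    so the derivative is well defined.
    """
    processed: list[Spectrum] = []
    for s in sset.spectra:
        try:
            if cfg.background is not None:
                s = subtract_background(s, cfg.background)
            if _uniform_step(s.wavenumbers) is None:
                s = _resample_uniform(s, cfg.interp_step)
            s = sg_first_derivative(s, cfg.sg_window, cfg.sg_polyorder)
            s = interpolate_region(s, cfg.region, cfg.interp_step)
            if cfg.normalize == "vector":
                s = vector_normalize(s)
        except (ValueError, SpectrumValidationError) as exc:
            raise type(exc)(f"spectrum {s.spectrum_id!r}: {exc}") from exc
        processed.append(s)
    return SpectrumSet(processed, common_axis=region_grid(cfg.region, cfg.interp_step))
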