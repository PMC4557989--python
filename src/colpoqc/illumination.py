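"""Spectral shape (peak +/- FWHM) and beam-uniformity FWHM diameter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core_io import LuminanceMap, RasterImage, luma_601
from .errors import AmbiguousPeakError, CalibrationError, InputError, TruncationError

__all__ = [
    "SpectralShape",
    "BeamReport",
    "spectrum_peak_fwhm",
    "beam_fwhm_diameter",
    "calibrate_scale_from_grid",
]

_SMOOTH_WINDOW = 5  # samples; suppresses shot noise, biases a 30-nm band < 1 nm

#: luminance fractions reported for contour-map rendering
CONTOUR_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SpectralShape:
    """Peak wavelength and full width at half maximum of a spectrum."""

    central_nm: float
    fwhm_nm: float
    multimodal: bool = False

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise InputError("fwhm_nm must be positive")


@dataclass(frozen=True)
class BeamReport:
    """Equivalent-area diameter of the >= half-max region of a beam."""

    fwhm_diameter_mm: float
    contour_levels: tuple[float, ...] = field(default=CONTOUR_LEVELS)

    def __post_init__(self) -> None:
        if not self.fwhm_diameter_mm > 0:
            raise InputError("fwhm_diameter_mm must be positive")
        if 0.5 not in self.contour_levels or not all(0 < c <= 1 for c in self.contour_levels):
            raise InputError("contour levels must lie in (0, 1] and include 0.5")


def _smooth(y: np.ndarray) -> np.ndarray:
    kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
    return np.convolve(y, kernel, mode="same")


def _half_crossing(wl, y, half, i_lo, i_hi):
    """Linear interpolation of the half-max crossing between two samples."""
    y0, y1 = y[i_lo], y[i_hi]
    if y1 == y0:
        return float(wl[i_lo])
    t = (half - y0) / (y1 - y0)
    return float(wl[i_lo] + t * (wl[i_hi] - wl[i_lo]))


def spectrum_peak_fwhm(s) -> SpectralShape:
    """Peak wavelength and FWHM after 5-sample moving-average smoothing.

    The central wavelength is the midpoint of the max plateau of the
    smoothed curve; the FWHM spans the outermost half-max crossings found
    by linear interpolation.  A maximum at the grid edge, or a curve that
    never falls below half maximum on one side (e.g. a broad plateau
    running off the grid), has no definable peak and raises
    :class:`AmbiguousPeakError`.  Multiple disjoint half-max regions are
    flagged via ``multimodal`` while still reporting the outermost
    crossings.
    """
    wl = s.wavelength_nm
    y = _smooth(s.intensity)
    peak = float(y.max())
    if peak <= 0:
        raise AmbiguousPeakError("spectrum is identically zero")
    at_max = y >= peak * (1.0 - 1e-9)
    idx = np.flatnonzero(at_max)
    if idx[0] == 0 or idx[-1] == len(y) - 1:
        raise AmbiguousPeakError("maximum lies at the grid boundary (no peak)")
    central = float((wl[idx[0]] + wl[idx[-1]]) / 2.0)

    half = peak / 2.0
    above = y >= half
    if above[0] or above[-1]:
        raise AmbiguousPeakError("spectrum does not fall below half maximum at the grid edges")
    rising = np.flatnonzero(~above[:-1] & above[1:])  # crossing between i and i+1
    falling = np.flatnonzero(above[:-1] & ~above[1:])
    left = _half_crossing(wl, y, half, rising[0], rising[0] + 1)
    right = _half_crossing(wl, y, half, falling[-1], falling[-1] + 1)
    multimodal = len(rising) > 1
    return SpectralShape(central_nm=central, fwhm_nm=right - left, multimodal=multimodal)


def beam_fwhm_diameter(map: LuminanceMap) -> BeamReport:
    """Equivalent-area circular diameter of the >= 50%-luminance region.

    diameter = 2 * sqrt(area / pi) * mm_per_px, rotation-invariant and
    exact for a circular beam.
    """
    if map.mm_per_px is None:
        raise InputError("beam_fwhm_diameter needs a physical scale (mm_per_px)")
    mask = map.values >= 0.5
    if not mask.any():
        raise InputError("no pixel reaches half maximum")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise TruncationError("half-max region touches the frame border; beam larger than frame")
    area_px = float(mask.sum())
    diameter = 2.0 * np.sqrt(area_px / np.pi) * map.mm_per_px
    return BeamReport(fwhm_diameter_mm=diameter)


def _line_positions(profile: np.ndarray) -> np.ndarray:
    """Sub-pixel positions of dark grid lines in a 1-D luminance profile."""
    inverted = profile.max() - profile
    span = inverted.max() - inverted.min()
    if span <= 0:
        return np.array([])
    peaks, _ = find_peaks(inverted, prominence=0.25 * span, distance=3)
    refined = []
    for p in peaks:
        if 0 < p < len(inverted) - 1:  # parabolic sub-pixel refinement
            y0, y1, y2 = inverted[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            refined.append(p + (0.5 * (y0 - y2) / denom if denom != 0 else 0.0))
        else:
            refined.append(float(p))
    return np.asarray(refined)


def calibrate_scale_from_grid(image: RasterImage, pitch_mm: float) -> float:
    """mm-per-px from a known-pitch grid overlaid on the diffuser.

    Dark grid lines are located as prominence peaks of the row/column
    projection profiles; the scale is ``pitch_mm`` over the median line
    spacing, averaged over the two directions.
    """
    if not pitch_mm > 0:
        raise InputError("pitch_mm must be positive")
    y = luma_601(image)
    estimates = []
    for profile in (y.mean(axis=0), y.mean(axis=1)):
        lines = _line_positions(profile)
        if len(lines) < 3:
            raise CalibrationError(
                f"only {len(lines)} grid lines detected (need >= 3 in each direction)"
            )
        spacing = float(np.median(np.diff(lines)))
        estimates.append(pitch_mm / spacing)
    return float(np.mean(estimates))
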