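"""ANSI/IESNA RP-27-style maximum-permissible-emission assessment.

Blue-light (L_B) and retinal-thermal (L_R) weighted radiances are
rectangle-rule sums  sum( L_lambda * w(lambda) * delta_lambda )  over the
weighting's support, compared against the exempt-group limits:
10 W cm^-2 sr^-1 for L_B (10,000 s) and 2.8/alpha W cm^-2 sr^-1 for L_R
(10 s), with the angular subtense alpha clamped to [0.011, 0.11] rad.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .core_io import EmissionSpectrum
from .errors import InputError, UnitsError

__all__ = [
    "HazardWeighting",
    "SourceGeometry",
    "HazardAssessment",
    "load_blue_light_weighting",
    "load_retinal_thermal_weighting",
    "angular_subtense",
    "weighted_radiance",
    "assess_hazard",
    "ALPHA_MIN_RAD",
    "ALPHA_MAX_RAD",
    "LIMIT_B",
]

ALPHA_MIN_RAD = 0.011
ALPHA_MAX_RAD = 0.11
#: blue-light exempt limit, W cm^-2 sr^-1 at 10,000 s exposure
LIMIT_B = 10.0
#: retinal-thermal exempt limit numerator (limit = 2.8 / alpha), 10 s exposure
LIMIT_R_NUMERATOR = 2.8


@dataclass(frozen=True)
class HazardWeighting:
    """Tabulated spectral hazard weighting with linear interpolation.

    Zero outside the tabulated support.
    """

    wavelength_nm: np.ndarray
    weight: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        wt = np.asarray(self.weight, dtype=float)
        if wl.ndim != 1 or wt.shape != wl.shape or wl.size < 2:
            raise InputError("weighting needs matching 1-D wavelength/weight tables")
        if np.any(np.diff(wl) <= 0):
            raise InputError("weighting wavelengths must be strictly increasing")
        if np.any(wt < 0):
            raise InputError("weights must be non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "weight", wt)

    def __call__(self, wavelength_nm: np.ndarray) -> np.ndarray:
        return np.interp(
            np.asarray(wavelength_nm, dtype=float),
            self.wavelength_nm,
            self.weight,
            left=0.0,
            right=0.0,
        )


def _load_table(filename: str, name: str) -> HazardWeighting:
    text = resources.files("colpoqc.data").joinpath(filename).read_text()
    rows = [
        line.split(",")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#") and not line.startswith("wavelength")
    ]
    data = np.array([[float(a), float(b)] for a, b in rows])
    return HazardWeighting(data[:, 0], data[:, 1], name=name)


def load_blue_light_weighting() -> HazardWeighting:
    """B(lambda), 300-700 nm; maximum 1.0 in the 435-440 nm region."""
    w = _load_table("blue_light_hazard.csv", "B")
    peak_band = w(np.arange(435.0, 441.0))
    assert np.isclose(w.weight.max(), 1.0) and np.isclose(peak_band.max(), 1.0), (
        "B(lambda) table must peak at 1.0 in 435-440 nm"
    )
    assert w.wavelength_nm[0] >= 300 and w.wavelength_nm[-1] <= 700
    return w


def load_retinal_thermal_weighting() -> HazardWeighting:
    """R(lambda), 400-1400 nm burn-hazard weighting."""
    w = _load_table("retinal_thermal_hazard.csv", "R")
    assert w.wavelength_nm[0] >= 400 and w.wavelength_nm[-1] <= 1400
    return w


@dataclass(frozen=True)
class SourceGeometry:
    """Beam extent L, working distance R and the clamped subtense alpha."""

    beam_diameter_mm: float
    working_distance_mm: float
    alpha_rad: float

    def __post_init__(self) -> None:
        if not ALPHA_MIN_RAD <= self.alpha_rad <= ALPHA_MAX_RAD:
            raise InputError(
                f"alpha_rad must lie in [{ALPHA_MIN_RAD}, {ALPHA_MAX_RAD}], got {self.alpha_rad}"
            )


@dataclass(frozen=True)
class HazardAssessment:
    """Weighted radiances, limits and exempt/non-exempt verdicts."""

    l_b: float  # W cm^-2 sr^-1
    l_r: float  # W cm^-2 sr^-1
    limit_b: float
    limit_r: float
    exempt_b: bool
    exempt_r: bool

    @property
    def l_b_mw(self) -> float:
        """L_B in the display units of the comparison table (mW cm^-2 sr^-1)."""
        return self.l_b * 1000.0

    @property
    def exempt(self) -> bool:
        return self.exempt_b and self.exempt_r


def angular_subtense(L_mm: float, R_mm: float) -> SourceGeometry:
    """alpha = L/R clamped to [0.011, 0.11] rad per the RP-27 rule."""
    if not (L_mm > 0 and R_mm > 0):
        raise InputError("beam diameter and working distance must be positive")
    alpha = float(np.clip(L_mm / R_mm, ALPHA_MIN_RAD, ALPHA_MAX_RAD))
    return SourceGeometry(beam_diameter_mm=L_mm, working_distance_mm=R_mm, alpha_rad=alpha)


def weighted_radiance(s: EmissionSpectrum, w: HazardWeighting) -> float:
    """Rectangle-rule weighted sum over the weighting's support.

    Requires an absolutely calibrated spectrum (W cm^-2 nm^-1 sr^-1).
    """
    if not s.absolute:
        raise UnitsError(
            "weighted_radiance needs absolute spectral radiance; calibrate via "
            "EmissionSpectrum.scaled(factor, absolute=True)"
        )
    return float(np.sum(s.intensity * w(s.wavelength_nm) * s.delta_lambda_nm))


def retinal_thermal_limit(alpha_rad: float) -> float:
    """Exempt-group L_R limit 2.8/alpha (25.45 W cm^-2 sr^-1 at alpha = 0.11)."""
    if not ALPHA_MIN_RAD <= alpha_rad <= ALPHA_MAX_RAD:
        raise InputError(f"alpha_rad {alpha_rad} outside the clamp band")
    return LIMIT_R_NUMERATOR / alpha_rad


def assess_hazard(
    s: EmissionSpectrum,
    geom: SourceGeometry,
    weighting_b: HazardWeighting | None = None,
    weighting_r: HazardWeighting | None = None,
) -> HazardAssessment:
    """Compute L_B, L_R and the exempt verdicts for one source."""
    wb = weighting_b if weighting_b is not None else load_blue_light_weighting()
    wr = weighting_r if weighting_r is not None else load_retinal_thermal_weighting()
    l_b = weighted_radiance(s, wb)
    l_r = weighted_radiance(s, wr)
    limit_r = retinal_thermal_limit(geom.alpha_rad)
    return HazardAssessment(
        l_b=l_b,
        l_r=l_r,
        limit_b=LIMIT_B,
        limit_r=limit_r,
        exempt_b=l_b <= LIMIT_B,
        exempt_r=l_r <= limit_r,
    )
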