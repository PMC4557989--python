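"""Hot-pixel specular fraction and the maximum safe illumination power.

A "hot pixel" has un-normalized Rec.601 luma strictly greater than 250.
Threshold presets follow the acceptance regimes in use: 1.0% (legacy),
0.5% for white-field and 0.05% for green-field illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import RasterImage, luma_601
from .errors import DataQualityError, InputError, NoSafePowerError
from .synthetic import SceneSpec, gen_cervix_scene

__all__ = [
    "SpecularSweep",
    "PowerLimit",
    "specular_fraction",
    "power_limit",
    "sweep_fractions",
    "run_sweep",
    "HOT_PIXEL_LUMA",
    "THRESHOLD_PRESETS",
]

HOT_PIXEL_LUMA = 250.0
THRESHOLD_PRESETS = {"legacy": 1.0, "white": 0.5, "green": 0.05}

#: tolerated non-monotonicity (percentage points) in a measured sweep
_MONOTONE_TOL = 0.02


@dataclass(frozen=True)
class SpecularSweep:
    """(optical power, specular fraction) series with an acceptance bound."""

    powers_mw: np.ndarray
    fractions_percent: np.ndarray
    threshold_percent: float = 0.5

    def __post_init__(self) -> None:
        p = np.asarray(self.powers_mw, dtype=float)
        f = np.asarray(self.fractions_percent, dtype=float)
        if p.ndim != 1 or f.shape != p.shape or p.size < 2:
            raise InputError("a sweep needs matching 1-D series of at least 2 points")
        if np.any(p < 0) or np.any(np.diff(p) <= 0):
            raise InputError("powers must be non-negative and strictly increasing")
        if np.any(f < 0) or np.any(f > 100):
            raise InputError("fractions must lie in [0, 100]")
        if not self.threshold_percent > 0:
            raise InputError("threshold_percent must be positive")
        object.__setattr__(self, "powers_mw", p)
        object.__setattr__(self, "fractions_percent", f)


@dataclass(frozen=True)
class PowerLimit:
    """Largest power meeting the threshold; at_boundary marks 'all passed'."""

    power_mw: float
    at_boundary: bool = False


def specular_fraction(image: RasterImage) -> float:
    """Percentage of pixels with Rec.601 luma strictly greater than 250."""
    y = luma_601(image)
    return float(100.0 * np.count_nonzero(y > HOT_PIXEL_LUMA) / y.size)


def power_limit(sweep: SpecularSweep) -> PowerLimit:
    """Maximum permissible power under the sweep's specular threshold.

    The limit is the largest sampled power with fraction <= threshold; when
    the threshold falls between samples the crossing power is found by
    linear interpolation between the bracketing points.
    """
    p, f, thr = sweep.powers_mw, sweep.fractions_percent, sweep.threshold_percent
    drops = np.diff(f)
    if np.any(drops < -_MONOTONE_TOL):
        worst = float(drops.min())
        raise DataQualityError(
            f"specular fractions decrease by {-worst:.3g} points with increasing power "
            f"(tolerance {_MONOTONE_TOL})"
        )
    passing = np.flatnonzero(f <= thr)
    if passing.size == 0:
        raise NoSafePowerError(
            f"all {p.size} sampled powers exceed the {thr}% specular threshold"
        )
    i = int(passing[-1])
    if i == p.size - 1:
        return PowerLimit(power_mw=float(p[-1]), at_boundary=True)
    # interpolate the crossing between the bracketing samples
    t = (thr - f[i]) / (f[i + 1] - f[i])
    return PowerLimit(power_mw=float(p[i] + t * (p[i + 1] - p[i])), at_boundary=False)


def sweep_fractions(image: RasterImage, gains: np.ndarray) -> np.ndarray:
    """Specular fraction of ``image`` with intensities scaled by each gain."""
    gains = np.asarray(gains, dtype=float)
    px = image.pixels.astype(float)
    out = np.empty(gains.shape)
    for i, g in enumerate(gains):
        scaled = np.clip(px * g, 0, 255).round().astype(np.uint8)
        out[i] = specular_fraction(RasterImage(scaled, mm_per_px=image.mm_per_px))
    return out


def run_sweep(
    spec: SceneSpec,
    gains: np.ndarray,
    threshold_percent: float = 0.5,
    specular_fraction_base: float = 0.0,
    green_mode: bool = False,
) -> SpecularSweep:
    """Simulated power sweep on a synthetic cervix scene.

    Renders the scene once, scales pixel intensities by each gain (clipped
    at 255) and records the hot-pixel fraction; fractions are non-decreasing
    in gain by the clipping argument.
    """
    gains = np.asarray(gains, dtype=float)
    if gains.ndim != 1 or gains.size < 2 or np.any(np.diff(gains) <= 0):
        raise InputError("gains must be a strictly increasing 1-D series of >= 2 values")
    scene = gen_cervix_scene(spec, specular_fraction=specular_fraction_base, green_mode=green_mode)
    fractions = sweep_fractions(scene, gains)
    return SpecularSweep(gains, fractions, threshold_percent=threshold_percent)
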