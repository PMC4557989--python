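"""Seeded generators for every input class the metric modules consume.

Each generator is a pure function of its parameters and the scene seed:
identical calls give byte-identical images.  Where a metric needs ground
truth (checkerboard corners, color-patch boxes) the generator returns it
alongside the rendered frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import lab_to_srgb, srgb_decode, srgb_encode
from .core_io import EmissionSpectrum, RasterImage, luma_601
from .errors import InputError, ResolutionError

__all__ = [
    "DistortionModel",
    "SceneSpec",
    "gen_checkerboard",
    "gen_usaf_bars",
    "gen_color_chart",
    "gen_beam",
    "gen_spectrum",
    "gen_cervix_scene",
    "warp_points",
    "DEFAULT_CHART_LAB",
]

# Planck-law constants for the halogen template, SI units.
_H = 6.62607015e-34
_C = 2.99792458e8
_KB = 1.380649e-23


@dataclass(frozen=True)
class DistortionModel:
    """Single-coefficient Brown radial distortion.

    ``k1 < 0`` produces barrel, ``k1 > 0`` pincushion.  Radii are
    normalized to the half-diagonal of the frame; ``center`` is the
    principal point in normalized image coordinates.
    """

    k1: float = 0.0
    center: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if abs(self.k1) > 0.5:
            raise InputError(f"|k1| must be <= 0.5, got {self.k1}")


@dataclass(frozen=True)
class SceneSpec:
    """Size, seed and physical scale of a synthetic scene."""

    width_px: int
    height_px: int
    seed: int = 0
    mm_per_px: float = 0.1

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise InputError("scene dimensions must be at least 64 px")
        if not self.mm_per_px > 0:
            raise InputError("mm_per_px must be positive")


def _principal_point(model: DistortionModel, w: int, h: int) -> tuple[float, float]:
    cx = model.center[0] * (w - 1)
    cy = model.center[1] * (h - 1)
    return cx, cy


def _half_diagonal(w: int, h: int) -> float:
    return float(np.hypot((w - 1) / 2.0, (h - 1) / 2.0))


def warp_points(points: np.ndarray, model: DistortionModel, width_px: int, height_px: int) -> np.ndarray:
    """Forward-warp undistorted (x, y) points: r' = r (1 + k1 r^2).

    Radii are normalized to the frame half-diagonal.  This is the analytic
    oracle used to place true checkerboard corners.
    """
    pts = np.asarray(points, dtype=float)
    cx, cy = _principal_point(model, width_px, height_px)
    rd = _half_diagonal(width_px, height_px)
    dx = (pts[..., 0] - cx) / rd
    dy = (pts[..., 1] - cy) / rd
    r = np.hypot(dx, dy)
    scale = 1.0 + model.k1 * r**2
    out = np.empty_like(pts)
    out[..., 0] = cx + dx * scale * rd
    out[..., 1] = cy + dy * scale * rd
    return out


def _unwarp_radii(r_dist: np.ndarray, k1: float) -> np.ndarray:
    """Invert r' = r (1 + k1 r^2) by Newton iteration (vectorized)."""
    r = r_dist.copy()
    for _ in range(20):
        f = r * (1.0 + k1 * r**2) - r_dist
        fp = 1.0 + 3.0 * k1 * r**2
        r = r - f / fp
    return r


def gen_checkerboard(
    spec: SceneSpec,
    square_mm: float,
    model: DistortionModel = DistortionModel(),
) -> tuple[RasterImage, np.ndarray]:
    """Render a black/white checkerboard warped by a radial-distortion model.

    Returns ``(image, corners)`` where ``corners`` is an (R, C, 2) array of
    the true (forward-warped) interior corner coordinates in pixel units,
    row-major from the top-left.

    Raises
    ------
    InputError
        If fewer than 6x6 full squares fit in the frame.
    """
    if not square_mm > 0:
        raise InputError("square_mm must be positive")
    w, h = spec.width_px, spec.height_px
    sq_px = square_mm / spec.mm_per_px
    # pincushion pushes the periphery outward; shrink the board so the
    # warped outer corners stay inside the frame.  |k1| (not k1) keeps the
    # board geometry identical for both distortion signs.
    fill = 0.94 / (1.0 + abs(model.k1))
    nx = int(np.floor(w * fill / sq_px))
    ny = int(np.floor(h * fill / sq_px))
    if nx < 6 or ny < 6:
        raise InputError(
            f"checkerboard does not fit: only {nx}x{ny} squares of {square_mm} mm "
            f"fit in {w}x{h} px at {spec.mm_per_px} mm/px (need 6x6)"
        )
    x0 = (w - 1 - nx * sq_px) / 2.0
    y0 = (h - 1 - ny * sq_px) / 2.0

    # Inverse-map a 3x3 supersampled pixel grid through the distortion, then
    # sample the ideal board; averaging the subsamples gives the antialiasing.
    cx, cy = _principal_point(model, w, h)
    rd = _half_diagonal(w, h)
    offsets = (-1.0 / 3.0, 0.0, 1.0 / 3.0)
    acc = np.zeros((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for oy in offsets:
        for ox in offsets:
            px = xx + ox
            py = yy + oy
            dx = (px - cx) / rd
            dy = (py - cy) / rd
            r_dist = np.hypot(dx, dy)
            if model.k1 != 0.0:
                r_und = _unwarp_radii(r_dist, model.k1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = np.where(r_dist > 0, r_und / r_dist, 1.0)
            else:
                ratio = 1.0
            sx = cx + dx * ratio * rd
            sy = cy + dy * ratio * rd
            u = (sx - x0) / sq_px
            v = (sy - y0) / sq_px
            inside = (u >= 0) & (u < nx) & (v >= 0) & (v < ny)
            parity = (np.floor(u).astype(int) + np.floor(v).astype(int)) % 2
            # mid-gray surround keeps the board's perimeter junctions weaker
            # than the interior saddle corners the detector is after
            acc += np.where(inside, parity.astype(float), 0.5)
    gray = np.clip(acc / 9.0 * 255.0, 0, 255).round().astype(np.uint8)
    image = RasterImage(np.repeat(gray[:, :, None], 3, axis=2), mm_per_px=spec.mm_per_px)

    ix, iy = np.meshgrid(np.arange(1, nx), np.arange(1, ny))
    corners_und = np.stack([x0 + ix * sq_px, y0 + iy * sq_px], axis=-1)
    corners = warp_points(corners_und, model, w, h)
    return image, corners


def usaf_bar_width_px(group: int, element: int, mm_per_px: float) -> float:
    """Bar width in pixels of a USAF-1951 (group, element) at a given scale."""
    freq = 2.0 ** (group + (element - 1) / 6.0)  # line pairs per mm
    return (500.0 / freq) / (mm_per_px * 1000.0)


def gen_usaf_bars(spec: SceneSpec, group: int, element: int) -> RasterImage:
    """Render the standard tri-bar USAF-1951 pattern for one (group, element).

    Three horizontal and three vertical dark bars on white; bar length is
    5x the bar width, gaps equal the width (the chart's 1:1 duty cycle).
    """
    if not (-2 <= group <= 7):
        raise InputError(f"group must be in [-2, 7], got {group}")
    if not (1 <= element <= 6):
        raise InputError(f"element must be in [1, 6], got {element}")
    wpx = usaf_bar_width_px(group, element, spec.mm_per_px)
    if wpx < 2.0:
        raise ResolutionError(
            f"bar width {wpx:.2f} px is under 2 px; use a finer mm_per_px scale"
        )
    w, h = spec.width_px, spec.height_px
    length = 5.0 * wpx
    if 5.0 * wpx + length + 3 * wpx > min(w, h):
        raise ResolutionError("bar pattern does not fit in the frame")
    canvas = np.full((h, w), 255.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def draw_bar(x_lo, x_hi, y_lo, y_hi):
        # Coverage-based antialiasing: overlap of the pixel with the bar.
        covx = np.clip(np.minimum(x_hi, xx + 0.5) - np.maximum(x_lo, xx - 0.5), 0, 1)
        covy = np.clip(np.minimum(y_hi, yy + 0.5) - np.maximum(y_lo, yy - 0.5), 0, 1)
        np.minimum(canvas, 255.0 * (1.0 - covx * covy), out=canvas)

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    gap = 1.5 * wpx
    # horizontal bars, left of center
    x_lo = cx - gap - length
    for i in range(3):
        y_lo = cy - 2.5 * wpx + i * 2.0 * wpx
        draw_bar(x_lo, x_lo + length, y_lo, y_lo + wpx)
    # vertical bars, right of center
    y_lo = cy - length / 2.0
    for i in range(3):
        x_b = cx + gap + i * 2.0 * wpx
        draw_bar(x_b, x_b + wpx, y_lo, y_lo + length)
    gray = np.clip(canvas, 0, 255).round().astype(np.uint8)
    return RasterImage(np.repeat(gray[:, :, None], 3, axis=2), mm_per_px=spec.mm_per_px)


# Plausible 6x5 chart reference, spanning grays, primaries, skin/tissue tones.
# NOT vendor-certified values; supply the certified CSV for real chart work.
DEFAULT_CHART_LAB: tuple[tuple[float, float, float], ...] = (
    (96.0, 0.0, 0.5), (81.0, 0.0, 0.3), (66.0, 0.0, 0.2), (51.0, 0.0, 0.0),
    (36.0, 0.0, -0.2), (21.0, 0.0, -0.4),
    (40.0, 55.0, 30.0), (52.0, 45.0, 48.0), (62.0, 30.0, 58.0), (72.0, 10.0, 70.0),
    (84.0, -5.0, 80.0), (55.0, -38.0, 32.0),
    (45.0, -24.0, -10.0), (35.0, 10.0, -45.0), (30.0, 25.0, -30.0), (45.0, 48.0, -12.0),
    (55.0, 60.0, 5.0), (50.0, 50.0, 20.0),
    (66.0, 18.0, 18.0), (58.0, 25.0, 20.0), (70.0, 14.0, 16.0), (76.0, 10.0, 14.0),
    (63.0, 22.0, 12.0), (48.0, 28.0, 16.0),
    (88.0, -2.0, 6.0), (74.0, -14.0, 40.0), (38.0, -20.0, 22.0), (28.0, 8.0, -20.0),
    (60.0, 35.0, -5.0), (44.0, -8.0, -28.0),
)


def gen_color_chart(
    spec: SceneSpec,
    reference: list[tuple[float, float, float]] | None = None,
    cast: np.ndarray | None = None,
    noise_sd: float = 0.0,
    layout: tuple[int, int] = (5, 6),
) -> tuple[RasterImage, list[tuple[int, int, int, int]]]:
    """Render a patch chart from reference CIELAB values (D50).

    Each patch is filled with the sRGB rendering of its reference Lab value,
    pushed through the linear-RGB ``cast`` matrix, and perturbed by seeded
    Gaussian noise.  Returns ``(image, boxes)`` with per-patch bounding boxes
    ``(row0, col0, row1, col1)`` (half-open).
    """
    rows, cols = layout
    if (rows, cols) not in ((4, 6), (5, 6)):
        raise InputError(f"layout must be 6x4 or 6x5 patches, got {cols}x{rows}")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    ref = list(reference) if reference is not None else list(DEFAULT_CHART_LAB[: rows * cols])
    if len(ref) != rows * cols:
        raise InputError(f"reference has {len(ref)} patches, layout needs {rows * cols}")
    cast = np.eye(3) if cast is None else np.asarray(cast, dtype=float)
    if cast.shape != (3, 3):
        raise InputError("cast must be a 3x3 matrix")

    lab = np.asarray(ref, dtype=float).reshape(rows, cols, 3)
    srgb = lab_to_srgb(lab, white="D50")  # floats in [0, 1]
    linear = srgb_decode(srgb)
    linear = np.clip(np.einsum("ij,rcj->rci", cast, linear), 0.0, 1.0)
    fills = np.clip(srgb_encode(linear) * 255.0, 0, 255)

    h, w = spec.height_px, spec.width_px
    img = np.zeros((h, w, 3), dtype=float)
    boxes: list[tuple[int, int, int, int]] = []
    r_edges = np.linspace(0, h, rows + 1).round().astype(int)
    c_edges = np.linspace(0, w, cols + 1).round().astype(int)
    for r in range(rows):
        for c in range(cols):
            r0, r1 = r_edges[r], r_edges[r + 1]
            c0, c1 = c_edges[c], c_edges[c + 1]
            img[r0:r1, c0:c1] = fills[r, c]
            boxes.append((r0, c0, r1, c1))
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(img, 0, 255).round().astype(np.uint8)
    return RasterImage(pixels, mm_per_px=spec.mm_per_px), boxes


def gen_beam(
    spec: SceneSpec,
    shape: str = "gaussian",
    fwhm_mm: float = 40.0,
    peak: float = 255.0,
    grid_pitch_mm: float | None = None,
) -> RasterImage:
    """Render a radially symmetric beam on a diffuser.

    ``gaussian`` uses sigma = fwhm / 2.3548; ``flat_top`` is a disc of
    diameter ``fwhm_mm`` with a 1-px soft edge.  ``grid_pitch_mm`` overlays
    dark calibration grid lines (the paper's two-image protocol).
    """
    if shape not in ("gaussian", "flat_top"):
        raise InputError(f"shape must be 'gaussian' or 'flat_top', got {shape!r}")
    if not 0 < peak <= 255:
        raise InputError("peak must be in (0, 255]")
    w, h = spec.width_px, spec.height_px
    fwhm_px = fwhm_mm / spec.mm_per_px
    if fwhm_px >= min(w, h):
        raise InputError(
            f"beam FWHM {fwhm_mm} mm ({fwhm_px:.0f} px) exceeds the {w}x{h} frame"
        )
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    if shape == "gaussian":
        sigma = fwhm_px / 2.3548
        profile = np.exp(-(r**2) / (2.0 * sigma**2))
    else:
        profile = np.clip(fwhm_px / 2.0 - r + 0.5, 0.0, 1.0)  # 1-px soft edge
    img = peak * profile
    if grid_pitch_mm is not None:
        pitch_px = grid_pitch_mm / spec.mm_per_px
        if pitch_px < 4:
            raise InputError("grid pitch under 4 px; use a finer scale")
        img = np.maximum(img, 0.35 * peak)  # pedestal so lines stay visible
        phase_x = np.abs((xx - cx + pitch_px / 2.0) % pitch_px - pitch_px / 2.0)
        phase_y = np.abs((yy - cy + pitch_px / 2.0) % pitch_px - pitch_px / 2.0)
        line = (phase_x < 1.0) | (phase_y < 1.0)
        img = np.where(line, img * 0.25, img)
    gray = np.clip(img, 0, 255).round().astype(np.uint8)
    return RasterImage(np.repeat(gray[:, :, None], 3, axis=2), mm_per_px=spec.mm_per_px)


_GRID_NM = np.arange(300.0, 1100.0 + 1.0, 1.0)


def _gaussian_peak(center_nm: float, fwhm_nm: float, amplitude: float) -> np.ndarray:
    sigma = fwhm_nm / 2.3548
    return amplitude * np.exp(-((_GRID_NM - center_nm) ** 2) / (2.0 * sigma**2))


def gen_spectrum(
    kind: str,
    *,
    center_nm: float | None = None,
    fwhm_nm: float | None = None,
    peaks: list[tuple[float, float, float]] | None = None,
    temperature_K: float = 3200.0,
    base: EmissionSpectrum | None = None,
    filter_type: str = "long_pass",
    edge_nm: float | None = None,
    edges_nm: tuple[float, float] | None = None,
    absolute: bool = False,
) -> EmissionSpectrum:
    """Generate an LED, halogen (Planck) or filtered emission spectrum.

    ``led``: a sum of Gaussian peaks, either one ``(center_nm, fwhm_nm)``
    peak or explicit ``peaks=[(center, fwhm, amplitude), ...]``; the default
    is a white-LED template (blue 450 nm peak + broad 550 nm phosphor band).
    ``halogen``: Planck curve at ``temperature_K``, normalized to unit peak.
    ``filtered``: ``base`` times an ideal long-pass/band-pass transmission
    with a 5-nm linear roll-off.  Output grid: 300-1100 nm at 1-nm steps.
    """
    if kind == "led":
        if peaks is None:
            if center_nm is not None:
                peaks = [(center_nm, fwhm_nm if fwhm_nm is not None else 30.0, 1.0)]
            else:  # white-LED template
                peaks = [(450.0, 20.0, 1.0), (550.0, 110.0, 0.7)]
        intensity = np.zeros_like(_GRID_NM)
        for c, f, a in peaks:
            intensity += _gaussian_peak(c, f, a)
    elif kind == "halogen":
        lam = _GRID_NM * 1e-9
        intensity = (2 * _H * _C**2 / lam**5) / np.expm1(_H * _C / (lam * _KB * temperature_K))
        intensity = intensity / intensity.max()
    elif kind == "filtered":
        if base is None:
            raise InputError("filtered spectra need a base spectrum")
        intensity = np.interp(_GRID_NM, base.wavelength_nm, base.intensity, left=0.0, right=0.0)
        if filter_type == "long_pass":
            if edge_nm is None:
                raise InputError("long_pass needs edge_nm")
            if not _GRID_NM[0] <= edge_nm <= _GRID_NM[-1]:
                raise InputError(f"filter edge {edge_nm} nm outside the 300-1100 nm grid")
            trans = np.clip((_GRID_NM - (edge_nm - 5.0)) / 5.0, 0.0, 1.0)
        elif filter_type == "band_pass":
            if edges_nm is None:
                raise InputError("band_pass needs edges_nm=(low, high)")
            lo, hi = edges_nm
            if not (_GRID_NM[0] <= lo < hi <= _GRID_NM[-1]):
                raise InputError(f"filter edges {edges_nm} outside the 300-1100 nm grid")
            rise = np.clip((_GRID_NM - (lo - 5.0)) / 5.0, 0.0, 1.0)
            fall = np.clip(((hi + 5.0) - _GRID_NM) / 5.0, 0.0, 1.0)
            trans = rise * fall
        else:
            raise InputError(f"unknown filter_type {filter_type!r}")
        intensity = intensity * trans
    else:
        raise InputError(f"unknown spectrum kind {kind!r}")
    return EmissionSpectrum(_GRID_NM.copy(), intensity, 1.0, absolute=absolute)


# Palette for the cervix scene; luma of every entry stays well below the
# 250 hot-pixel threshold so injected speculars are countable exactly.
_BG = np.array([70.0, 42.0, 48.0])
_CERVIX = np.array([214.0, 150.0, 158.0])
_OS = np.array([148.0, 82.0, 92.0])
_VESSEL = np.array([150.0, 58.0, 66.0])

_LUMA_CAP = 245.0


def gen_cervix_scene(
    spec: SceneSpec,
    specular_fraction: float = 0.0,
    green_mode: bool = False,
) -> RasterImage:
    """Render a cervix-like scene with an exact count of saturated pixels.

    Exactly ``round(specular_fraction / 100 * H * W)`` seeded pixels are set
    to pure white (luma 255); every other pixel's luma is capped at 245 so
    the specular-fraction metric recovers the injected count exactly.
    """
    if not 0.0 <= specular_fraction <= 30.0:
        raise InputError(f"specular_fraction must be in [0, 30], got {specular_fraction}")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BG
    ax, ay = 0.38 * w, 0.36 * h
    cervix = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    img[cervix] = _CERVIX
    os_mask = ((xx - cx) / (0.08 * w)) ** 2 + ((yy - cy) / (0.10 * h)) ** 2 <= 1.0
    img[os_mask] = _OS

    # branching vessels: seeded random walks radiating from the os
    from skimage.draw import line as _line

    for _ in range(14):
        ang = rng.uniform(0, 2 * np.pi)
        x, y = cx + 0.1 * w * np.cos(ang), cy + 0.1 * h * np.sin(ang)
        for _ in range(rng.integers(4, 9)):
            ang += rng.normal(0.0, 0.5)
            step = rng.uniform(0.03, 0.07) * min(w, h)
            x2, y2 = x + step * np.cos(ang), y + step * np.sin(ang)
            rr, cc = _line(int(round(y)), int(round(x)), int(round(y2)), int(round(x2)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc = rr[keep], cc[keep]
            on = cervix[rr, cc]
            img[rr[on], cc[on]] = _VESSEL
            x, y = x2, y2

    # soft illumination falloff plus a near-saturation highlight blob
    r_norm = np.hypot((xx - cx) / (w / 2.0), (yy - cy) / (h / 2.0))
    img *= (1.0 - 0.18 * np.clip(r_norm, 0, 1) ** 2)[:, :, None]
    hx, hy = cx + 0.12 * w, cy - 0.1 * h
    blob = np.exp(-(((xx - hx) ** 2 + (yy - hy) ** 2) / (2.0 * (0.06 * min(w, h)) ** 2)))
    img += 0.9 * blob[:, :, None] * (255.0 - img)

    if green_mode:
        y_luma = 0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2]
        img = np.stack([0.35 * y_luma, 1.0 * y_luma, 0.30 * y_luma], axis=-1)

    # cap non-specular luma at 245 so only injected pixels cross 250
    luma = 0.299 * img[:, :, 0] + 0.587 * img[:, :, 1] + 0.114 * img[:, :, 2]
    over = luma > _LUMA_CAP
    scale = np.where(over, _LUMA_CAP / np.maximum(luma, 1e-9), 1.0)
    img *= scale[:, :, None]
    img = np.clip(img, 0, 255)

    n_spec = int(round(specular_fraction / 100.0 * h * w))
    if n_spec > 0:
        flat_idx = rng.choice(h * w, size=n_spec, replace=False)
        img.reshape(-1, 3)[flat_idx] = 255.0
    pixels = img.round().astype(np.uint8)

    if n_spec > 0:  # rounding must not push any other pixel over the threshold
        y8 = luma_601(RasterImage(pixels))
        assert int((y8 > 250).sum()) == n_spec
    return RasterImage(pixels, mm_per_px=spec.mm_per_px)
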