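"""Domain types, image/spectrum I/O and the shared luminance definition.

All image metrics operate on 8-bit RGB :class:`RasterImage` grids with an
optional isotropic physical scale (mm per pixel); pixel coordinates are
0-based, row-major, origin top-left.  Spectral metrics operate on
:class:`EmissionSpectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, InputError, ParseError

__all__ = [
    "RasterImage",
    "EmissionSpectrum",
    "LuminanceMap",
    "read_image",
    "write_image",
    "read_spectrum",
    "write_spectrum",
    "luminance",
    "luma_601",
]

#: Rec.601 luma coefficients, applied to 8-bit R, G, B in that order.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_MIN_DIM = 16


@dataclass(frozen=True)
class RasterImage:
    """8-bit RGB pixel grid with an optional physical scale.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Pixel intensities in [0, 255].
    mm_per_px : float, optional
        Isotropic physical scale. Must be positive when given.
    """

    pixels: np.ndarray
    mm_per_px: float | None = None
    bit_depth: int = field(default=8)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise InputError("pixel intensities must be 8-bit values in [0, 255]")
        h, w = px.shape[:2]
        if h < _MIN_DIM or w < _MIN_DIM:
            raise InputError(f"image must be at least {_MIN_DIM}x{_MIN_DIM}, got {h}x{w}")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise InputError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if self.bit_depth != 8:
            raise InputError("only 8-bit images are supported")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_scale(self, mm_per_px: float) -> "RasterImage":
        return replace(self, mm_per_px=mm_per_px)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Sampled spectral intensity versus wavelength.

    ``absolute=True`` marks calibrated units (W cm^-2 nm^-1 sr^-1); otherwise
    intensities are relative.  ``delta_lambda_nm`` is the per-sample bin width
    used by rectangle-rule quadrature.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    delta_lambda_nm: np.ndarray
    absolute: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise InputError("wavelength and intensity must be 1-D and equal length")
        if wl.size < 2:
            raise InputError("a spectrum needs at least 2 samples")
        if np.any(np.diff(wl) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if wl[0] < 300 or wl[-1] > 1400:
            raise InputError("wavelengths must lie within [300, 1400] nm")
        if np.any(it < 0):
            raise InputError("intensities must be non-negative")
        dl = np.broadcast_to(np.asarray(self.delta_lambda_nm, dtype=float), wl.shape).copy()
        if np.any(dl <= 0):
            raise InputError("bin widths must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        object.__setattr__(self, "delta_lambda_nm", dl)

    def scaled(self, factor: float, *, absolute: bool | None = None) -> "EmissionSpectrum":
        """Return a copy with intensities multiplied by ``factor``."""
        if factor < 0:
            raise InputError("scale factor must be non-negative")
        return EmissionSpectrum(
            self.wavelength_nm,
            self.intensity * factor,
            self.delta_lambda_nm,
            absolute=self.absolute if absolute is None else absolute,
        )


@dataclass(frozen=True)
class LuminanceMap:
    """Per-pixel luma normalized to the frame maximum (all values in [0, 1])."""

    values: np.ndarray
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InputError("luminance map must be 2-D")
        if v.min() < 0 or v.max() > 1:
            raise InputError("luminance values must lie in [0, 1]")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise InputError("mm_per_px must be positive")
        object.__setattr__(self, "values", v)


def read_image(path: str | Path, mm_per_px: float | None = None) -> RasterImage:
    """Read a PNG/TIFF/JPEG file into an 8-bit RGB :class:`RasterImage`.

    16-bit sources are down-converted by integer division (``// 256``);
    grayscale is replicated to 3 channels.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype == np.uint16 or arr.dtype == np.int32:
        arr = (arr.astype(np.uint32) // 256).clip(0, 255).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"unsupported pixel type {arr.dtype} in {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RasterImage(arr, mm_per_px=mm_per_px)


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write an image as PNG or TIFF (by extension); lossless round-trip."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def read_spectrum(path: str | Path, *, absolute: bool = False) -> EmissionSpectrum:
    """Read a two-column CSV (wavelength_nm, intensity) spectrum.

    Header row and ``#`` comments are permitted.  Rows are sorted by
    wavelength, duplicate wavelengths averaged, and the per-sample bin
    width set to the median spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such spectrum file: {path}")
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = [p.strip() for p in body.replace("\t", ",").split(",") if p.strip()]
            if len(parts) < 2:
                raise ParseError(f"{path}: row {lineno}: expected 2 columns, got {len(parts)}")
            try:
                wl, it = float(parts[0]), float(parts[1])
            except ValueError as exc:
                if not rows and lineno <= 2:  # tolerate a single header row
                    continue
                raise ParseError(f"{path}: row {lineno}: non-numeric cell in {parts}") from exc
            rows.append((wl, it))
    if len(rows) < 2:
        raise InputError(f"{path}: a spectrum needs at least 2 data rows, got {len(rows)}")
    data = np.array(sorted(rows), dtype=float)
    wl, it = data[:, 0], data[:, 1]
    uniq, inverse = np.unique(wl, return_inverse=True)
    if uniq.size != wl.size:
        it = np.bincount(inverse, weights=it) / np.bincount(inverse)
        wl = uniq
    if wl.size < 2:
        raise InputError(f"{path}: fewer than 2 distinct wavelengths after averaging")
    delta = float(np.median(np.diff(wl)))
    return EmissionSpectrum(wl, it, delta, absolute=absolute)


def write_spectrum(spectrum: EmissionSpectrum, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelength_nm, spectrum.intensity):
            fh.write(f"{wl:.6g},{it:.10g}\n")


def luma_601(image: RasterImage) -> np.ndarray:
    """Un-normalized Rec.601 luma (float, 0-255 range) per pixel."""
    px = image.pixels.astype(float)
    r, g, b = LUMA_WEIGHTS
    return r * px[:, :, 0] + g * px[:, :, 1] + b * px[:, :, 2]


def luminance(image: RasterImage) -> LuminanceMap:
    """Rec.601 luma normalized to the frame maximum.

    An all-black frame maps to all zeros (no division by zero).
    """
    y = luma_601(image)
    peak = y.max()
    if peak > 0:
        y = y / peak
    return LuminanceMap(y, mm_per_px=image.mm_per_px)
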