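"""CIELAB color-reproduction error and Lab-statistics color matching.

The sRGB <-> Lab chain uses the standard IEC 61966-2-1 decoding, the
sRGB-to-XYZ matrix (D65), and — for D50 chart work — Bradford chromatic
adaptation, so that sRGB white maps to L=100, a=b=0 under either white.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np

from .core_io import RasterImage
from .errors import InputError

__all__ = [
    "LabColor",
    "PatchReading",
    "ColorErrorReport",
    "srgb_to_lab",
    "lab_to_srgb_8bit",
    "delta_e_ab",
    "delta_c_ab",
    "extract_patches",
    "color_error_report",
    "match_color",
]

_M_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# Bradford adaptation D65 -> D50
_M_D65_TO_D50 = np.array(
    [
        [1.0478112, 0.0228866, -0.0501270],
        [0.0295424, 0.9904844, -0.0170491],
        [-0.0092345, 0.0150436, 0.7521316],
    ]
)
_WHITE_XYZ = {
    "D65": np.array([0.95047, 1.0, 1.08883]),
    "D50": np.array([0.96422, 1.0, 0.82521]),
}
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # 1 / (3 delta^2)


def srgb_decode(srgb: np.ndarray) -> np.ndarray:
    """sRGB gamma expansion, [0, 1] encoded -> linear."""
    s = np.asarray(srgb, dtype=float)
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear -> gamma-encoded sRGB, both in [0, 1]."""
    lin = np.clip(np.asarray(linear, dtype=float), 0.0, None)
    return np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)


def _f_lab(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_lab_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) / _KAPPA)


def srgb_array_to_lab(srgb: np.ndarray, white: str = "D50") -> np.ndarray:
    """Vectorized sRGB ([0,1], last axis RGB) -> Lab under the given white."""
    if white not in _WHITE_XYZ:
        raise InputError(f"white must be 'D50' or 'D65', got {white!r}")
    xyz = srgb_decode(srgb) @ _M_RGB_TO_XYZ.T
    if white == "D50":
        xyz = xyz @ _M_D65_TO_D50.T
    f = _f_lab(xyz / _WHITE_XYZ[white])
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_to_srgb(lab: np.ndarray, white: str = "D50") -> np.ndarray:
    """Vectorized Lab -> encoded sRGB in [0, 1] (gamut-clipped)."""
    if white not in _WHITE_XYZ:
        raise InputError(f"white must be 'D50' or 'D65', got {white!r}")
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_lab_inv(fx), _f_lab_inv(fy), _f_lab_inv(fz)], axis=-1)
    xyz = xyz * _WHITE_XYZ[white]
    if white == "D50":
        xyz = xyz @ np.linalg.inv(_M_D65_TO_D50).T
    linear = xyz @ np.linalg.inv(_M_RGB_TO_XYZ).T
    return np.clip(srgb_encode(np.clip(linear, 0.0, None)), 0.0, 1.0)


@dataclass(frozen=True)
class LabColor:
    """A CIELAB coordinate (L in [0, 100], |a|, |b| <= 128)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not -0.5 <= self.L <= 100.5:
            raise InputError(f"L must lie in [0, 100], got {self.L}")
        if abs(self.a) > 128 or abs(self.b) > 128:
            raise InputError(f"|a|, |b| must be <= 128, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class PatchReading:
    patch_id: str
    measured: LabColor
    reference: LabColor


@dataclass(frozen=True)
class ColorErrorReport:
    """Per-patch and summary CIELAB reproduction errors."""

    patch_ids: tuple[str, ...]
    delta_e: tuple[float, ...]
    delta_c: tuple[float, ...]
    mean_de: float
    max_de: float
    mean_dc: float
    max_dc: float


def srgb_to_lab(rgb: tuple[int, int, int], white: str = "D50") -> LabColor:
    """Convert one 8-bit sRGB triple to Lab (D50 default, Bradford-adapted)."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape != (3,) or arr.min() < 0 or arr.max() > 255:
        raise InputError(f"rgb must be an 8-bit triple, got {rgb!r}")
    lab = srgb_array_to_lab(arr / 255.0, white=white)
    return LabColor(float(lab[0]), float(lab[1]), float(lab[2]))


def lab_to_srgb_8bit(color: LabColor, white: str = "D50") -> tuple[int, int, int]:
    srgb = lab_to_srgb(np.array([color.L, color.a, color.b]), white=white)
    v = np.clip(srgb * 255.0, 0, 255).round().astype(int)
    return int(v[0]), int(v[1]), int(v[2])


def delta_e_ab(x: LabColor, y: LabColor) -> float:
    """Euclidean CIELAB distance (includes the lightness axis)."""
    return float(np.sqrt((x.L - y.L) ** 2 + (x.a - y.a) ** 2 + (x.b - y.b) ** 2))


def delta_c_ab(x: LabColor, y: LabColor) -> float:
    """Chromatic CIELAB distance (a, b only; luminance excluded)."""
    return float(np.sqrt((x.a - y.a) ** 2 + (x.b - y.b) ** 2))


def extract_patches(
    image: RasterImage,
    layout: tuple[int, int],
    inset: float = 0.25,
) -> list[np.ndarray]:
    """Mean RGB (floats) of each patch of a chart that fills the frame.

    Each patch is sampled over its central (1 - 2*inset)^2 region to avoid
    patch borders; patches are returned row-major from the top-left.
    """
    rows, cols = layout
    if not 0.0 <= inset < 0.5:
        raise InputError(f"inset must be in [0, 0.5), got {inset}")
    h, w = image.height, image.width
    if h // rows < 8 or w // cols < 8:
        raise InputError(f"{cols}x{rows} layout gives cells under 8 px in a {w}x{h} frame")
    r_edges = np.linspace(0, h, rows + 1)
    c_edges = np.linspace(0, w, cols + 1)
    px = image.pixels.astype(float)
    means: list[np.ndarray] = []
    for r in range(rows):
        for c in range(cols):
            rh = r_edges[r + 1] - r_edges[r]
            cw = c_edges[c + 1] - c_edges[c]
            r0 = int(round(r_edges[r] + inset * rh))
            r1 = int(round(r_edges[r + 1] - inset * rh))
            c0 = int(round(c_edges[c] + inset * cw))
            c1 = int(round(c_edges[c + 1] - inset * cw))
            means.append(px[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0))
    return means


def color_error_report(chart: list[PatchReading]) -> ColorErrorReport:
    """Per-patch Delta-E*ab / Delta-C*ab with their means and maxima."""
    if not chart:
        raise InputError("color_error_report needs at least one patch")
    ids = tuple(p.patch_id for p in chart)
    if len(set(ids)) != len(ids):
        raise InputError("patch_id values must be unique")
    de = tuple(delta_e_ab(p.measured, p.reference) for p in chart)
    dc = tuple(delta_c_ab(p.measured, p.reference) for p in chart)
    return ColorErrorReport(
        patch_ids=ids,
        delta_e=de,
        delta_c=dc,
        mean_de=fmean(de),
        max_de=max(de),
        mean_dc=fmean(dc),
        max_dc=max(dc),
    )


Roi = tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open


def _roi_slice(image: RasterImage, roi: Roi, name: str) -> np.ndarray:
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= image.height and 0 <= c0 < c1 <= image.width):
        raise InputError(f"{name} ROI {roi} outside the {image.width}x{image.height} frame")
    if r1 - r0 < 32 or c1 - c0 < 32:
        raise InputError(f"{name} ROI must be at least 32x32 px, got {roi}")
    return image.pixels[r0:r1, c0:c1]


def match_color(
    source: RasterImage,
    source_roi: Roi,
    reference: RasterImage,
    reference_roi: Roi,
    white: str = "D50",
    l_levels: tuple[float, float] | None = None,
) -> RasterImage:
    """Per-channel Lab mean/std statistics transfer fitted on ROIs.

    The affine transform that maps the source ROI's Lab channel statistics
    onto the reference ROI's is applied to the whole source frame, then
    converted back to sRGB with gamut clipping.  A zero-variance source
    channel is shifted by mean only.  ``l_levels=(lo, hi)`` additionally
    compresses the output L range into [100*lo/255, 100*hi/255].
    """
    src_px = _roi_slice(source, source_roi, "source")
    ref_px = _roi_slice(reference, reference_roi, "reference")
    src_lab_roi = srgb_array_to_lab(src_px / 255.0, white=white).reshape(-1, 3)
    ref_lab_roi = srgb_array_to_lab(ref_px / 255.0, white=white).reshape(-1, 3)
    mu_s, sd_s = src_lab_roi.mean(axis=0), src_lab_roi.std(axis=0)
    mu_r, sd_r = ref_lab_roi.mean(axis=0), ref_lab_roi.std(axis=0)

    lab = srgb_array_to_lab(source.pixels / 255.0, white=white)
    out = np.empty_like(lab)
    for ch in range(3):
        if sd_s[ch] > 1e-9:
            out[..., ch] = (lab[..., ch] - mu_s[ch]) * (sd_r[ch] / sd_s[ch]) + mu_r[ch]
        else:
            out[..., ch] = lab[..., ch] - mu_s[ch] + mu_r[ch]
    out[..., 0] = np.clip(out[..., 0], 0.0, 100.0)
    out[..., 1:] = np.clip(out[..., 1:], -128.0, 128.0)
    if l_levels is not None:
        lo, hi = l_levels
        if not 0 <= lo < hi <= 255:
            raise InputError(f"l_levels must satisfy 0 <= lo < hi <= 255, got {l_levels}")
        out[..., 0] = (lo + out[..., 0] / 100.0 * (hi - lo)) / 255.0 * 100.0
    srgb = lab_to_srgb(out, white=white)
    pixels = np.clip(srgb * 255.0, 0, 255).round().astype(np.uint8)
    return RasterImage(pixels, mm_per_px=source.mm_per_px)
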