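"""Edge-refined foveation contrast-sensitivity masking in the wavelet domain.

The raw gaze point is uncertain within a circle of radius N*v*tan(e). Inside
that circle the point with maximal total directional Sobel magnitude (TMSM,
four 3x3 kernels at 0/45/90/135 degrees) is taken as the refined foveation
point. Around it, every DWT coefficient receives a weight equal to the
contrast-sensitivity ratio CS(f_band, eccentricity)/CS(f_band, 0), producing
a mask that is 1 at the foveation point and decays with eccentricity, faster
in higher-frequency sub-bands. Applying the mask means: forward 4-level
Daubechies DWT, per-coefficient multiply, inverse DWT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ShapeError
from .gaze import FoveationGeometry
from .wavelet import pad_to_multiple, subband_shapes, wavedec2, waverec2

__all__ = [
    "FoveationPoint",
    "WaveletMask",
    "SOBEL_KERNELS",
    "sobel_tmsm",
    "tmsm_map",
    "refine_foveation_point",
    "build_mask",
    "apply_mask",
]

# Directional 3x3 Sobel kernels at 0, 45, 90 and 135 degrees (y down).
SOBEL_KERNELS = (
    np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),
    np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float),
    np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float),
    np.array([[-2, -1, 0], [-1, 0, 1], [0, 1, 2]], dtype=float),
)

# Foveated contrast-sensitivity model constants (configurable):
# CS(f, ecc) ~ exp(-CS_DECAY * f * (ecc + CS_E2) / CS_E2), f in cycles/degree,
# ecc in degrees; the mask stores the ratio CS(f, ecc) / CS(f, 0).
CS_DECAY = 0.106
CS_E2 = 2.3


@dataclass(frozen=True)
class FoveationPoint:
    """Raw gaze point, its edge-refined replacement, and the winning TMSM."""

    xf: tuple[float, float]
    xcf: tuple[float, float]
    tmsm: float


@dataclass(frozen=True)
class WaveletMask:
    """Per-sub-band weight rasters in [0, 1] for a 4-level DWT layout."""

    weights: dict
    geometry: FoveationGeometry
    point: FoveationPoint
    levels: int
    order: int
    shape: tuple[int, int]  # shape of the source image (before padding)
    padded_shape: tuple[int, int]


def tmsm_map(image: np.ndarray) -> np.ndarray:
    """Total directional Sobel magnitude at every pixel (replicate borders)."""
    img = np.asarray(image, dtype=float)
    out = np.zeros_like(img)
    for k in SOBEL_KERNELS:
        out += np.abs(ndimage.correlate(img, k, mode="nearest"))
    return out


def sobel_tmsm(image: np.ndarray, point: tuple[int, int]) -> float:
    """TMSM at a single (x, y) point: sum of the four |Sobel| responses."""
    x, y = int(round(point[0])), int(round(point[1]))
    img = np.asarray(image, dtype=float)
    if not (0 <= x < img.shape[1] and 0 <= y < img.shape[0]):
        raise ValueError("point outside the image")
    pad = np.pad(img, 1, mode="edge")
    win = pad[y:y + 3, x:x + 3]
    return float(sum(np.abs(np.sum(win * k)) for k in SOBEL_KERNELS))


def refine_foveation_point(
    image: np.ndarray,
    xf: tuple[float, float],
    geometry: FoveationGeometry,
) -> FoveationPoint:
    """Maximize TMSM over pixels strictly inside the gaze-error circle.

    Ties are broken by smaller distance to the raw point, then by (y, x).
    A radius of zero (or a circle containing no pixel) returns the raw point.
    """
    img = np.asarray(image, dtype=float)
    radius = geometry.radius
    x0, y0 = float(xf[0]), float(xf[1])
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    dist = np.hypot(xx - x0, yy - y0)
    inside = dist < radius
    if not inside.any():
        return FoveationPoint(xf=(x0, y0), xcf=(x0, y0),
                              tmsm=sobel_tmsm(img, (int(round(x0)), int(round(y0))))
                              if 0 <= round(x0) < img.shape[1] and 0 <= round(y0) < img.shape[0]
                              else 0.0)
    tm = tmsm_map(img)
    cand_y, cand_x = np.nonzero(inside)
    vals = tm[cand_y, cand_x]
    d = dist[cand_y, cand_x]
    # lexsort: last key dominates -> maximize val, then minimize dist, then (y, x)
    order = np.lexsort((cand_x, cand_y, d, -vals))
    best = order[0]
    bx, by = int(cand_x[best]), int(cand_y[best])
    return FoveationPoint(xf=(x0, y0), xcf=(float(bx), float(by)), tmsm=float(vals[best]))


def _band_frequency(level: int, levels: int, band: str, f_max: float) -> float:
    if band == "LL":
        return f_max / (1 << (levels + 1))
    return f_max / (1 << level)


def build_mask(
    image_shape: tuple[int, int],
    foveation_point: FoveationPoint,
    geometry: FoveationGeometry,
    levels: int = 4,
    *,
    order: int = 4,
    cs_decay: float = CS_DECAY,
    cs_e2: float = CS_E2,
) -> WaveletMask:
    """Build per-sub-band contrast-sensitivity weights around the refined point.

    A coefficient at row r, column c of a level-lambda sub-band corresponds to
    the full-resolution point (c * 2^lambda, r * 2^lambda); its weight is
    CS(f_lambda, ecc)/CS(f_lambda, 0) = exp(-cs_decay * f_lambda * ecc / cs_e2)
    with ecc = atan(d / (N * v)) in degrees, clipped to [0, 1]. The image shape
    is edge-padded internally to a multiple of 2^levels.
    """
    if levels < 1:
        raise ShapeError("levels must be >= 1")
    block = 1 << levels
    if min(image_shape) < block:
        raise ShapeError(f"shape {image_shape} too small for {levels} DWT levels")
    padded = (image_shape[0] + (-image_shape[0]) % block,
              image_shape[1] + (-image_shape[1]) % block)
    xcf = np.asarray(foveation_point.xcf, dtype=float)
    nv = geometry.N * geometry.v
    # pixels-per-degree at the viewing distance; Nyquist frequency in cpd
    f_max = nv * math.pi / 360.0

    weights: dict = {}
    for (lam, band), (h, w) in subband_shapes(padded, levels).items():
        scale = 1 << lam
        cx = np.arange(w) * scale
        cy = np.arange(h) * scale
        d = np.hypot(cx[None, :] - xcf[0], cy[:, None] - xcf[1])
        ecc = np.degrees(np.arctan(d / nv))
        f = _band_frequency(lam, levels, band, f_max)
        weights[(lam, band)] = np.clip(np.exp(-cs_decay * f * ecc / cs_e2), 0.0, 1.0)
    return WaveletMask(weights=weights, geometry=geometry, point=foveation_point,
                       levels=levels, order=order, shape=tuple(image_shape),
                       padded_shape=padded)


def apply_mask(image: np.ndarray, mask: WaveletMask, *, clip: bool = True) -> np.ndarray:
    """Forward DWT, per-coefficient multiply by the mask, inverse DWT.

    The output has the input's shape; when `clip` is set it is clipped to the
    input's value range.

    Raises
    ------
    ShapeError
        If the mask was built for a different image shape.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != mask.shape:
        raise ShapeError(f"mask built for {mask.shape}, image is {img.shape}")
    padded, orig = pad_to_multiple(img, mask.levels)
    coeffs = wavedec2(padded, mask.levels, mask.order)
    weighted = {key: coeffs[key] * mask.weights[key] for key in coeffs}
    rec = waverec2(weighted, mask.levels, mask.order)[: orig[0], : orig[1]]
    if clip:
        rec = np.clip(rec, img.min(), img.max())
    return rec
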