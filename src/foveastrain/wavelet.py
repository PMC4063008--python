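"""Orthonormal Daubechies 2-D multilevel DWT with periodized boundaries.

Self-contained (no external wavelet dependency). Filters are generated by
spectral factorization of the Daubechies half-band polynomial, so any order
is available at machine precision; periodization keeps the transform an
exact orthogonal map, which gives perfect reconstruction and halved
coefficient rasters at every level for even-sized inputs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import comb

from .errors import ShapeError

__all__ = [
    "daubechies_filter",
    "wavedec2",
    "waverec2",
    "pad_to_multiple",
    "subband_shapes",
]


@lru_cache(maxsize=32)
def daubechies_filter(order: int) -> np.ndarray:
    """Minimal-phase Daubechies scaling filter with `order` vanishing moments.

    Length is 2*order; coefficients sum to sqrt(2) and satisfy the
    orthonormality conditions sum_n h[n] h[n+2k] = delta_k.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if order == 1:
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    # P(y) = sum_k C(order-1+k, k) y^k ; roots in y give z-plane roots via
    # y = (2 - z - 1/z)/4  <=>  z^2 - (2 - 4y) z + 1 = 0.
    k = np.arange(order)
    p_coeffs = comb(order - 1 + k, k)  # ascending powers of y
    y_roots = np.roots(p_coeffs[::-1])
    z_roots = []
    for y in y_roots:
        zz = np.roots([1.0, -(2.0 - 4.0 * y), 1.0])
        z_roots.append(zz[np.argmin(np.abs(zz))])  # minimal phase: inside unit circle
    poly = np.array([1.0 + 0j])
    for _ in range(order):
        poly = np.convolve(poly, [1.0, 1.0])
    for z in z_roots:
        poly = np.convolve(poly, [1.0, -z])
    h = np.real(poly)
    return h * np.sqrt(2.0) / h.sum()


def _filters(order: int) -> tuple[np.ndarray, np.ndarray]:
    h = daubechies_filter(order)
    g = ((-1) ** np.arange(len(h))) * h[::-1]  # quadrature mirror
    return h, g


def _analysis_axis(x: np.ndarray, h: np.ndarray, g: np.ndarray, axis: int):
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    if n % 2:
        raise ShapeError("axis length must be even for one DWT level")
    m = len(h)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(m)[None, :]) % n
    win = x[..., idx]  # (..., n/2, m)
    a = win @ h
    d = win @ g
    return np.moveaxis(a, -1, axis), np.moveaxis(d, -1, axis)


def _synthesis_axis(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray, axis: int):
    a = np.moveaxis(a, axis, -1)
    d = np.moveaxis(d, axis, -1)
    half = a.shape[-1]
    n = 2 * half
    m = len(h)
    idx = (2 * np.arange(half)[:, None] + np.arange(m)[None, :]) % n
    flat_a = a.reshape(-1, half)
    flat_d = d.reshape(-1, half)
    out = np.zeros((flat_a.shape[0], n))
    contrib = flat_a[:, :, None] * h[None, None, :] + flat_d[:, :, None] * g[None, None, :]
    # scatter-add the overlapping synthesis windows
    np.add.at(out, (np.arange(out.shape[0])[:, None, None], idx[None, :, :]), contrib)
    out = out.reshape(a.shape[:-1] + (n,))
    return np.moveaxis(out, -1, axis)


def _dwt2(x: np.ndarray, order: int):
    h, g = _filters(order)
    lo, hi = _analysis_axis(x, h, g, axis=0)
    ll, lh = _analysis_axis(lo, h, g, axis=1)
    hl, hh = _analysis_axis(hi, h, g, axis=1)
    return ll, lh, hl, hh


def _idwt2(ll, lh, hl, hh, order: int):
    h, g = _filters(order)
    lo = _synthesis_axis(ll, lh, h, g, axis=1)
    hi = _synthesis_axis(hl, hh, h, g, axis=1)
    return _synthesis_axis(lo, hi, h, g, axis=0)


def wavedec2(image: np.ndarray, levels: int, order: int = 4) -> dict:
    """Multilevel 2-D DWT; LL is decomposed recursively.

    Returns a dict keyed by (level, band) with band in {"LH","HL","HH"} for
    levels 1..levels plus ("LL" at level `levels`). Level-l rasters have
    shape (H/2^l, W/2^l); H and W must be divisible by 2^levels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ShapeError("wavedec2 expects a 2-D raster")
    if img.shape[0] % (1 << levels) or img.shape[1] % (1 << levels):
        raise ShapeError(
            f"shape {img.shape} not divisible by 2^{levels}; pad first"
        )
    coeffs: dict = {}
    ll = img
    for lam in range(1, levels + 1):
        ll, lh, hl, hh = _dwt2(ll, order)
        coeffs[(lam, "LH")] = lh
        coeffs[(lam, "HL")] = hl
        coeffs[(lam, "HH")] = hh
    coeffs[(levels, "LL")] = ll
    return coeffs


def waverec2(coeffs: dict, levels: int, order: int = 4) -> np.ndarray:
    """Inverse of :func:`wavedec2`."""
    ll = coeffs[(levels, "LL")]
    for lam in range(levels, 0, -1):
        ll = _idwt2(ll, coeffs[(lam, "LH")], coeffs[(lam, "HL")], coeffs[(lam, "HH")], order)
    return ll


def pad_to_multiple(image: np.ndarray, levels: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetrically edge-pad so both dimensions divide by 2^levels.

    Returns the padded raster and the original (H, W) for cropping back.
    """
    img = np.asarray(image, dtype=float)
    block = 1 << levels
    pad_h = (-img.shape[0]) % block
    pad_w = (-img.shape[1]) % block
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
    return img, (image.shape[0], image.shape[1])


def subband_shapes(shape: tuple[int, int], levels: int) -> dict:
    """Coefficient raster shape for every sub-band key of :func:`wavedec2`."""
    out = {}
    h, w = shape
    for lam in range(1, levels + 1):
        h, w = h // 2, w // 2
        for band in ("LH", "HL", "HH"):
            out[(lam, band)] = (h, w)
    out[(levels, "LL")] = (h, w)
    return out
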