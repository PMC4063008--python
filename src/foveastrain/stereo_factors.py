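"""Per-frame eyestrain factors from anaglyph stereo frames.

CSD: sum of absolute per-pixel differences between consecutive foveated
disparity maps. SD: sum of the foveated disparity map. FCE: absolute
horizontal distance of the gaze point from the screen midline. EC: summed
Canny edge magnitude over the two foveated half-images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .errors import ChannelError, ShapeError, ZeroImage
from .foveation import WaveletMask, apply_mask

__all__ = [
    "StereoPair",
    "DisparityMap",
    "FactorSample",
    "split_anaglyph",
    "normalize_brightness",
    "compute_disparity",
    "compute_sd",
    "compute_csd",
    "compute_fce",
    "compute_ec",
]


@dataclass(frozen=True)
class StereoPair:
    """Left (green channel) and right (red channel) views as gray rasters."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        if np.asarray(self.left).shape != np.asarray(self.right).shape:
            raise ShapeError("left/right shapes differ")


@dataclass(frozen=True)
class DisparityMap:
    """Horizontal disparities in pixels with an invalid-pixel mask."""

    values: np.ndarray
    valid: np.ndarray

    def filled(self, fill: float = 0.0) -> np.ndarray:
        return np.where(self.valid, self.values, fill)


@dataclass(frozen=True)
class FactorSample:
    timestamp: float
    csd: float
    sd: float
    fce: float
    ec: float


def split_anaglyph(frame: np.ndarray) -> StereoPair:
    """Separate a red-green anaglyph: left = green channel, right = red."""
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ChannelError("anaglyph frame must have 3 color channels")
    return StereoPair(left=arr[..., 1].astype(float), right=arr[..., 0].astype(float))


def normalize_brightness(pair: StereoPair) -> StereoPair:
    """Scale the right image so both views share the same mean gray level."""
    left = np.asarray(pair.left, dtype=float)
    right = np.asarray(pair.right, dtype=float)
    ml, mr = float(left.mean()), float(right.mean())
    if mr == 0.0:
        if ml == 0.0:
            return StereoPair(left=left, right=right)  # degenerate: both blank
        raise ZeroImage("right image mean is zero; cannot match brightness")
    return StereoPair(left=left, right=np.clip(right * (ml / mr), 0.0, 255.0))


def compute_disparity(
    pair: StereoPair, block: int = 9, search_range: int = 16
) -> DisparityMap:
    """SAD block matching along horizontal lines with a left-right check.

    Disparity d means right[x + d] corresponds to left[x]; the per-pixel cost
    is the block-summed absolute difference, minimized over
    d in [-search_range, search_range]. Ties prefer smaller |d| (so flat
    untextured inputs resolve to disparity 0). Pixels failing the left-right
    consistency check (|dL(x) + dR(x + dL)| > 1) or whose block leaves the
    frame are marked invalid.
    """
    if block < 3 or block % 2 == 0:
        raise ValueError("block must be odd and >= 3")
    if search_range < 1:
        raise ValueError("search_range must be >= 1")
    left = np.asarray(pair.left, dtype=np.float32)
    right = np.asarray(pair.right, dtype=np.float32)
    h, w = left.shape

    # order candidates by |d| then d so np.argmin tie-breaks toward 0
    cands = sorted(range(-search_range, search_range + 1), key=lambda d: (abs(d), d))
    def _cost_volume(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        vol = np.full((len(cands), h, w), np.inf, dtype=np.float32)
        for i, d in enumerate(cands):
            diff = np.full((h, w), np.nan, dtype=np.float32)
            if d >= 0:
                diff[:, : w - d] = np.abs(a[:, : w - d] - b[:, d:])
            else:
                diff[:, -d:] = np.abs(a[:, -d:] - b[:, : w + d])
            sad = ndimage.uniform_filter(np.nan_to_num(diff, nan=0.0), size=block)
            bad = ndimage.uniform_filter(np.isnan(diff).astype(np.float32), size=block) > 0
            sad[bad] = np.inf
            vol[i] = sad
        return vol

    cost_l = _cost_volume(left, right)

    # left disparity
    il = np.argmin(cost_l, axis=0)
    dl = np.asarray(cands)[il].astype(np.float32)
    finite_l = np.isfinite(np.take_along_axis(cost_l, il[None], axis=0)[0])

    # right disparity computed independently (mirror matching)
    cost_rr = _cost_volume(right, left)
    ir = np.argmin(cost_rr, axis=0)
    dr = np.asarray(cands)[ir].astype(np.float32)
    finite_r = np.isfinite(np.take_along_axis(cost_rr, ir[None], axis=0)[0])

    # left-right consistency: dR at (x + dL) should be ~ -dL
    xs = np.arange(w)[None, :] + dl.astype(int)
    xs_ok = (xs >= 0) & (xs < w)
    xs_clip = np.clip(xs, 0, w - 1)
    dr_at = dr[np.arange(h)[:, None], xs_clip]
    consistent = np.abs(dl + dr_at) <= 1
    valid = finite_l & xs_ok & consistent & finite_r[np.arange(h)[:, None], xs_clip]
    return DisparityMap(values=dl.astype(float), valid=valid)


def compute_sd(disparity: DisparityMap, mask: WaveletMask) -> float:
    """Sum of the foveation-masked disparity raster (invalid pixels as 0)."""
    dmap = np.abs(disparity.filled(0.0))
    if dmap.shape != mask.shape:
        raise ShapeError(f"mask built for {mask.shape}, disparity is {dmap.shape}")
    foveated = apply_mask(dmap, mask)
    return float(foveated.sum())


def foveate_disparity(disparity: DisparityMap, mask: WaveletMask) -> np.ndarray:
    """Foveation-masked |disparity| raster, kept in floating point."""
    dmap = np.abs(disparity.filled(0.0))
    if dmap.shape != mask.shape:
        raise ShapeError(f"mask built for {mask.shape}, disparity is {dmap.shape}")
    return apply_mask(dmap, mask)


def compute_csd(prev_foveated: np.ndarray, curr_foveated: np.ndarray) -> float:
    """Sum of absolute pixel differences between consecutive foveated maps."""
    prev = np.asarray(prev_foveated, dtype=float)
    curr = np.asarray(curr_foveated, dtype=float)
    if prev.shape != curr.shape:
        raise ShapeError("consecutive disparity maps differ in shape")
    return float(np.abs(curr - prev).sum())


def compute_fce(gaze_x: float, monitor_width: int) -> float:
    """|monitor_width / 2 - gaze_x|: distance of gaze from the screen midline."""
    return abs(monitor_width / 2 - gaze_x)


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Unnormalized 3x3 Sobel gradient magnitude (8-bit convention)."""
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def compute_ec(
    left_foveated: np.ndarray,
    right_foveated: np.ndarray,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
    *,
    sigma: float = 1.0,
) -> float:
    """Summed gradient magnitude over Canny edge pixels of both images.

    Thresholds follow the 8-bit unnormalized-Sobel convention (a full-range
    step has magnitude up to 4*255 = 1020); they are rescaled internally for
    the [0, 1] float Canny implementation.
    """
    left = np.asarray(left_foveated, dtype=float)
    right = np.asarray(right_foveated, dtype=float)
    if left.shape != right.shape:
        raise ShapeError("left/right shapes differ")
    total = 0.0
    for img in (left, right):
        if img.max() == img.min():
            continue  # no edges in a constant image
        edges = canny(img / 255.0, sigma=sigma,
                      low_threshold=canny_low / 1020.0,
                      high_threshold=canny_high / 1020.0)
        total += float(gradient_magnitude(img)[edges].sum())
    return total
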