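"""Pupil, specular-reflection and eye open/closed detection on NIR eye frames.

The pupil is located with a circular edge detector (CED): the score of a
candidate (center, radius) is the difference of mean gray level between two
adjacent circular templates, an outer ring two pixels beyond the inner one.
The initial CED fix is then refined by local binarization, component
labeling, size filtering, hole filling and centroiding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from .errors import NoPupilFound, RefinementFailed, SRCountError

__all__ = [
    "EyeFrame",
    "PupilResult",
    "SRQuad",
    "BlinkState",
    "detect_pupil_ced",
    "refine_pupil",
    "detect_srs",
    "blink_state",
    "order_quad_points",
    "DEFAULT_DARK_CUTOFF",
    "DEFAULT_SR_CUTOFF",
]

DEFAULT_DARK_CUTOFF = 70  # gray level below which a pixel counts as "black"
DEFAULT_SR_CUTOFF = 230  # gray level above which a pixel is SR-bright


@dataclass(frozen=True)
class EyeFrame:
    """One grayscale eye-camera image with acquisition metadata."""

    pixels: np.ndarray
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("EyeFrame.pixels must be a 2-D raster")
        if px.shape[1] < 64 or px.shape[0] < 48:
            raise ValueError("EyeFrame must be at least 64x48 pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PupilResult:
    """Detected pupil: sub-pixel center, radius and local dark-pixel count."""

    center: tuple[float, float]  # (x, y)
    radius: float
    black_pixel_count: int
    refined: bool = False
    score: float = float("nan")


@dataclass(frozen=True)
class SRQuad:
    """Four specular reflections ordered top-left, top-right, bottom-right, bottom-left."""

    points: np.ndarray  # (4, 2) array of (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (4, 2):
            raise ValueError("SRQuad requires exactly four (x, y) points")
        if len({tuple(p) for p in pts.tolist()}) != 4:
            raise ValueError("SRQuad points must be distinct")
        object.__setattr__(self, "points", pts)

    def signed_area(self) -> float:
        """Shoelace area; magnitude near zero means a degenerate quad."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class BlinkState:
    state: str  # "open" or "closed"
    black_pixel_count: int

    @property
    def is_open(self) -> bool:
        return self.state == "open"


@lru_cache(maxsize=256)
def _ring_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dy, dx) offsets whose rounded Euclidean length equals `radius`."""
    r = int(radius)
    span = np.arange(-(r + 1), r + 2)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    on = np.round(np.hypot(dy, dx)).astype(int) == r
    return dy[on].copy(), dx[on].copy()


def _ring_kernel(radius: int) -> np.ndarray:
    dy, dx = _ring_offsets(radius)
    r = int(radius) + 1
    k = np.zeros((2 * r + 1, 2 * r + 1))
    k[dy + r, dx + r] = 1.0
    return k / k.sum()


def ced_score_map(image: np.ndarray, radius: int, gap: int = 2) -> np.ndarray:
    """Mean(outer ring at radius+gap) - mean(inner ring at radius) per center.

    Centers whose outer ring leaves the frame are set to -inf.
    """
    img = np.asarray(image, dtype=float)
    inner = fftconvolve(img, _ring_kernel(radius), mode="same")
    outer = fftconvolve(img, _ring_kernel(radius + gap), mode="same")
    score = outer - inner
    margin = radius + gap + 1
    valid = np.full(img.shape, -np.inf)
    if img.shape[0] > 2 * margin and img.shape[1] > 2 * margin:
        valid[margin:-margin, margin:-margin] = score[margin:-margin, margin:-margin]
    return valid


def count_black_pixels(
    image: np.ndarray,
    center: tuple[float, float],
    half_size: int,
    dark_cutoff: int = DEFAULT_DARK_CUTOFF,
) -> int:
    """Count pixels darker than `dark_cutoff` in a clipped square window."""
    img = np.asarray(image)
    cx, cy = int(round(center[0])), int(round(center[1]))
    y0, y1 = max(0, cy - half_size), min(img.shape[0], cy + half_size + 1)
    x0, x1 = max(0, cx - half_size), min(img.shape[1], cx + half_size + 1)
    return int(np.sum(img[y0:y1, x0:x1] < dark_cutoff))


def detect_pupil_ced(
    frame: EyeFrame,
    radius_min: int = 10,
    radius_max: int | None = None,
    *,
    grid: int = 2,
    contrast_floor: float = 10.0,
    dark_cutoff: int = DEFAULT_DARK_CUTOFF,
) -> PupilResult:
    """Locate the pupil by maximizing circular-ring gray-level contrast.

    Centers are searched on a `grid`-pixel lattice for every integer radius in
    [radius_min, radius_max], then the best fix is re-evaluated at 1-px
    resolution in its neighborhood. Ties prefer the smallest radius, then the
    smallest (y, x) center.

    Raises
    ------
    NoPupilFound
        If the maximal ring contrast is below `contrast_floor`.
    """
    img = np.asarray(frame.pixels, dtype=float)
    if radius_min < 3:
        raise ValueError("radius_min must be >= 3")
    if radius_max is None:
        radius_max = min(frame.width, frame.height) // 2 - 3
    if radius_max > min(frame.width, frame.height) // 2:
        raise ValueError("radius_max exceeds half the frame size")

    best_score = -np.inf
    best = None  # (radius, y, x)
    maps: dict[int, np.ndarray] = {}
    for r in range(radius_min, radius_max + 1):
        smap = ced_score_map(img, r)
        maps[r] = smap
        sub = smap[::grid, ::grid]
        idx = int(np.argmax(sub))
        score = float(sub.flat[idx])
        if score > best_score:  # strict: keeps smallest radius on ties
            yy, xx = np.unravel_index(idx, sub.shape)
            best_score = score
            best = (r, int(yy) * grid, int(xx) * grid)

    if best is None or not np.isfinite(best_score):
        raise NoPupilFound("no valid CED candidate in the frame")

    # 1-px refinement around the coarse optimum, over all radii.
    r0, y0, x0 = best
    for r in range(radius_min, radius_max + 1):
        smap = maps[r]
        ylo, yhi = max(0, y0 - grid), min(smap.shape[0], y0 + grid + 1)
        xlo, xhi = max(0, x0 - grid), min(smap.shape[1], x0 + grid + 1)
        window = smap[ylo:yhi, xlo:xhi]
        idx = int(np.argmax(window))
        score = float(window.flat[idx])
        if score > best_score:
            wy, wx = np.unravel_index(idx, window.shape)
            best_score = score
            best = (r, ylo + int(wy), xlo + int(wx))

    if best_score < contrast_floor:
        raise NoPupilFound(
            f"maximal ring contrast {best_score:.2f} below floor {contrast_floor}"
        )
    r, y, x = best
    black = count_black_pixels(img, (x, y), 2 * r, dark_cutoff)
    return PupilResult(center=(float(x), float(y)), radius=float(r),
                       black_pixel_count=black, refined=False, score=best_score)


def refine_pupil(
    frame: EyeFrame,
    initial: PupilResult,
    *,
    window_factor: float = 4.0,
    rel_size_band: tuple[float, float] = (0.3, 3.0),
    abs_size_band: tuple[float, float] | None = None,
) -> PupilResult:
    """Refine the pupil center by local Otsu binarization and centroiding.

    A square window of side `window_factor * initial.radius` is binarized with
    Otsu's threshold; dark connected components outside the size band
    (`rel_size_band` times the initial circle area, or `abs_size_band` pixels
    if given) are discarded, SR holes are filled, and the centroid of the
    remaining dark pixels becomes the refined center.

    Raises
    ------
    RefinementFailed
        If no component survives size filtering.
    """
    img = np.asarray(frame.pixels, dtype=float)
    cx, cy = initial.center
    half = max(3, int(round(window_factor * initial.radius / 2)))
    y0, y1 = max(0, int(cy) - half), min(img.shape[0], int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(img.shape[1], int(cx) + half + 1)
    window = img[y0:y1, x0:x1]

    if window.size == 0 or window.max() == window.min():
        raise RefinementFailed("refinement window has no contrast")
    dark = window < threshold_otsu(window)

    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise RefinementFailed("no dark component in refinement window")
    if abs_size_band is not None:
        lo, hi = abs_size_band
    else:
        area = np.pi * initial.radius**2
        lo, hi = rel_size_band[0] * area, rel_size_band[1] * area
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero((sizes >= lo) & (sizes <= hi)) + 1
    if keep.size == 0:
        raise RefinementFailed("all dark components outside the size band")

    mask = np.isin(labels, keep)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    mask = ndimage.binary_fill_holes(mask)
    my, mx = ndimage.center_of_mass(mask)
    count = int(mask.sum())
    return PupilResult(
        center=(x0 + float(mx), y0 + float(my)),
        radius=float(np.sqrt(count / np.pi)),
        black_pixel_count=count,
        refined=True,
        score=initial.score,
    )


def detect_srs(
    frame: EyeFrame,
    pupil: PupilResult,
    *,
    region_halfwidth: int | None = None,
    bright_cutoff: int = DEFAULT_SR_CUTOFF,
    size_band: tuple[int, int] = (4, 100),
) -> SRQuad:
    """Detect the four NIR specular reflections around the pupil.

    Bright pixels inside a square region around the pupil center are labeled;
    components outside `size_band` (pixel counts) are discarded. Exactly four
    must remain; their centroids are returned ordered TL, TR, BR, BL by
    angular position around the common centroid.

    Raises
    ------
    SRCountError
        If the number of surviving components differs from four.
    """
    img = np.asarray(frame.pixels, dtype=float)
    cx, cy = pupil.center
    if region_halfwidth is None:
        region_halfwidth = max(int(round(3 * pupil.radius)), 48)
    y0, y1 = max(0, int(cy) - region_halfwidth), min(img.shape[0], int(cy) + region_halfwidth + 1)
    x0, x1 = max(0, int(cx) - region_halfwidth), min(img.shape[1], int(cx) + region_halfwidth + 1)
    region = img[y0:y1, x0:x1]

    bright = region > bright_cutoff
    labels, n = ndimage.label(bright, structure=np.ones((3, 3), dtype=int))
    centroids = []
    for i in range(1, n + 1):
        size = int(np.sum(labels == i))
        if size_band[0] <= size <= size_band[1]:
            my, mx = ndimage.center_of_mass(labels == i)
            centroids.append((x0 + float(mx), y0 + float(my)))
    if len(centroids) != 4:
        raise SRCountError(f"expected 4 specular reflections, found {len(centroids)}")

    return SRQuad(points=order_quad_points(np.array(centroids)))


def order_quad_points(points: np.ndarray) -> np.ndarray:
    """Order four (x, y) points TL, TR, BR, BL by angle around their centroid.

    Invariant under any permutation of the input points.
    """
    pts = np.asarray(points, dtype=float)
    ref = pts.mean(axis=0)
    # atan2 with y downward: TL ~ -135deg < TR ~ -45deg < BR ~ 45deg < BL ~ 135deg
    angles = np.arctan2(pts[:, 1] - ref[1], pts[:, 0] - ref[0])
    return pts[np.argsort(angles)]


def blink_state(
    frame: EyeFrame,
    region: tuple[int, int, int, int] | None,
    open_threshold: int,
    *,
    dark_cutoff: int = DEFAULT_DARK_CUTOFF,
) -> BlinkState:
    """Classify the eye as open/closed from the dark-pixel count.

    `region` is an (x0, y0, x1, y1) pupil search window (None = whole frame).
    The eye is open iff the count of pixels darker than `dark_cutoff` is at
    least `open_threshold`.
    """
    if open_threshold <= 0:
        raise ValueError("open_threshold must be positive")
    img = np.asarray(frame.pixels)
    if region is not None:
        rx0, ry0, rx1, ry1 = region
        img = img[max(0, ry0):ry1, max(0, rx0):rx1]
    count = int(np.sum(img < dark_cutoff))
    return BlinkState(state="open" if count >= open_threshold else "closed",
                      black_pixel_count=count)
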