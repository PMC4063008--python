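"""Gaze mapping from eye-image features to monitor coordinates.

The four corneal specular reflections image the monitor corners, so a
4-point projective (homography) transform sends the SR quad to the monitor
rectangle; the pupil center mapped through it is the raw gaze point. A
one-point center calibration compensates the angle-kappa offset. A simple
dispersion-based (I-DT) pass optionally suppresses saccadic jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import ProjectiveTransform

from .errors import DegenerateQuad
from .eye_image import SRQuad

__all__ = [
    "GazeSample",
    "FoveationGeometry",
    "KappaOffset",
    "map_gaze",
    "calibrate_kappa",
    "gaze_circle",
    "compensate_saccades",
]


@dataclass(frozen=True)
class GazeSample:
    """One gaze fix in monitor pixel coordinates (0-based, y downward)."""

    timestamp: float
    screen: tuple[float, float]
    valid: bool = True


@dataclass(frozen=True)
class FoveationGeometry:
    """Viewing geometry defining the gaze-error circle.

    N is the image width in pixels, v the viewing distance in image widths,
    e the gaze-error half-angle in degrees; the circle radius in pixels is
    N * v * tan(e).
    """

    N: int
    v: float
    e: float

    def __post_init__(self) -> None:
        if self.N <= 0 or self.v <= 0:
            raise ValueError("N and v must be positive")
        if not 0 <= self.e < 90:
            raise ValueError("e must lie in [0, 90) degrees")

    @property
    def radius(self) -> float:
        return self.N * self.v * math.tan(math.radians(self.e))


@dataclass(frozen=True)
class KappaOffset:
    dx: float
    dy: float


def map_gaze(
    pupil_center: tuple[float, float],
    srs: SRQuad,
    monitor: tuple[int, int],
    *,
    kappa: KappaOffset | None = None,
    margin_frac: float = 0.05,
) -> GazeSample:
    """Map a pupil center to monitor coordinates through the SR homography.

    The projective transform sending the SR quad (TL, TR, BR, BL) to the
    monitor corner rectangle is solved exactly from the four correspondences
    and applied to the pupil center; a kappa offset, if given, is added.
    Points farther than `margin_frac` of the monitor dimension outside the
    rectangle are flagged invalid; in-margin points are clamped.

    Raises
    ------
    DegenerateQuad
        If the SR quad is (near-)collinear.
    """
    tf = map_gaze_transform(srs, monitor)
    w, h = monitor
    x, y = tf(np.asarray(pupil_center, dtype=float)[None, :])[0]
    if kappa is not None:
        x, y = x + kappa.dx, y + kappa.dy
    mx, my = margin_frac * w, margin_frac * h
    inside = (-mx <= x <= w - 1 + mx) and (-my <= y <= h - 1 + my)
    if inside:
        x = min(max(x, 0.0), float(w - 1))
        y = min(max(y, 0.0), float(h - 1))
    return GazeSample(timestamp=float("nan"), screen=(float(x), float(y)), valid=inside)


def map_gaze_transform(srs: SRQuad, monitor: tuple[int, int]) -> ProjectiveTransform:
    """The homography sending the SR quad to the monitor rectangle."""
    w, h = monitor
    if abs(srs.signed_area()) < 1e-9:
        raise DegenerateQuad("SR quad has (near-)zero area")
    dst = np.array([(0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)], dtype=float)
    if hasattr(ProjectiveTransform, "from_estimate"):
        tf = ProjectiveTransform.from_estimate(srs.points, dst)
        if not tf or not np.all(np.isfinite(tf.params)):
            raise DegenerateQuad("projective transform estimation failed")
    else:  # older scikit-image
        tf = ProjectiveTransform()
        if not tf.estimate(srs.points, dst) or not np.all(np.isfinite(tf.params)):
            raise DegenerateQuad("projective transform estimation failed")
    return tf


def calibrate_kappa(
    mapped_center_gaze: tuple[float, float], monitor: tuple[int, int]
) -> KappaOffset:
    """Kappa offset from one fixation at the monitor center."""
    w, h = monitor
    return KappaOffset(dx=w / 2 - mapped_center_gaze[0], dy=h / 2 - mapped_center_gaze[1])


def gaze_circle(geometry: FoveationGeometry) -> float:
    """Radius (pixels) of the circle containing the true gaze point."""
    return geometry.radius


def _dispersion(xy: np.ndarray) -> float:
    return float((xy[:, 0].max() - xy[:, 0].min()) + (xy[:, 1].max() - xy[:, 1].min()))


def compensate_saccades(
    series: list[GazeSample],
    window_frames: int = 5,
    dispersion_px: float = 30.0,
) -> list[GazeSample]:
    """Suppress saccadic jitter with dispersion-based fixation detection (I-DT).

    Runs whose x-range + y-range stays within `dispersion_px` over at least
    `window_frames` samples are fixations; every sample in a run is replaced
    by the run's componentwise median, and transit samples snap to the nearest
    fixation's median. Output length equals input length.
    """
    n = len(series)
    if n == 0:
        return []
    xy = np.array([s.screen for s in series], dtype=float)

    runs: list[tuple[int, int]] = []  # [start, stop)
    i = 0
    while i + window_frames <= n:
        j = i + window_frames
        if _dispersion(xy[i:j]) <= dispersion_px:
            while j < n and _dispersion(xy[i:j + 1]) <= dispersion_px:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return list(series)

    medians = [np.median(xy[a:b], axis=0) for a, b in runs]
    out: list[GazeSample] = []
    for k, s in enumerate(series):
        hit = next((idx for idx, (a, b) in enumerate(runs) if a <= k < b), None)
        if hit is None:
            # snap to nearest run boundary in index distance
            dists = [min(abs(k - a), abs(k - (b - 1))) for a, b in runs]
            hit = int(np.argmin(dists))
        m = medians[hit]
        out.append(replace(s, screen=(float(m[0]), float(m[1]))))
    return out
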