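"""Deterministic synthetic eye-camera and anaglyph stereo sequences.

Every generator is seeded and byte-reproducible, and ships ground truth so
each pipeline stage (pupil tracking, blink counting, disparity, CSD) can be
validated by parameter recovery without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import SpecError
from .gaze import GazeSample

__all__ = [
    "EyeSceneSpec",
    "StereoSceneSpec",
    "SceneObject",
    "gen_eye_sequence",
    "gen_anaglyph_video",
    "gen_gaze_scanpath",
    "scheduled_transition_counts",
]

CLOSED_EYE_GRAY = 180  # uniform eyelid field rendered during a blink
PUPIL_GRAY = 20
BACKGROUND_GRAY = 200
SR_GRAY = 255


@dataclass(frozen=True)
class EyeSceneSpec:
    """Parameters of a synthetic NIR eye sequence.

    `pupil_center` is a single (x, y) or an (n_frames, 2) trajectory;
    `blink_schedule` lists non-overlapping [close_t, open_t) intervals in
    seconds during which the frame is an eyelid-gray field.
    """

    shape: tuple[int, int] = (120, 160)  # (height, width)
    pupil_center: tuple[float, float] | np.ndarray = (80.0, 60.0)
    pupil_radius: float = 18.0
    sr_points: tuple = ((50.0, 30.0), (110.0, 30.0), (110.0, 90.0), (50.0, 90.0))
    blink_schedule: tuple = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sched = sorted(tuple(map(tuple, self.blink_schedule)))
        for (c0, o0), (c1, _) in zip(sched, sched[1:]):
            if c1 < o0:
                raise SpecError("blink intervals overlap")
        for c, o in sched:
            if o <= c:
                raise SpecError("blink interval must have open_t > close_t")
        if len({tuple(p) for p in self.sr_points}) != 4:
            raise SpecError("SR points must be four distinct positions")
        object.__setattr__(self, "blink_schedule", tuple(sched))


@dataclass(frozen=True)
class SceneObject:
    """A textured rectangle with its own horizontal disparity."""

    x: int
    y: int
    width: int
    height: int
    disparity: float
    gray_boost: float = 40.0


@dataclass(frozen=True)
class StereoSceneSpec:
    """Parameters of a synthetic red-green anaglyph sequence.

    `disparity` is the background's horizontal disparity in pixels: a scalar,
    a per-frame array, or a callable of time in seconds. Scene changes swap
    the background texture at the given times.
    """

    shape: tuple[int, int] = (128, 128)
    disparity: float | np.ndarray = 0.0
    scene_changes: tuple = ()
    objects: tuple = ()
    texture_sigma: float = 1.5
    seed: int = 0


def _eye_state(t: float, schedule) -> str:
    for close_t, open_t in schedule:
        if close_t <= t < open_t:
            return "closed"
    return "open"


def _render_open_eye(spec: EyeSceneSpec, center: tuple[float, float]) -> np.ndarray:
    h, w = spec.shape
    img = np.full((h, w), float(BACKGROUND_GRAY))
    yy, xx = np.mgrid[0:h, 0:w]
    # anti-aliased dark pupil disk
    cover = np.clip(spec.pupil_radius + 0.5 - np.hypot(xx - center[0], yy - center[1]), 0.0, 1.0)
    img += cover * (PUPIL_GRAY - BACKGROUND_GRAY)
    for sx, sy in spec.sr_points:
        x0, y0 = int(round(sx)), int(round(sy))
        img[max(0, y0 - 1):y0 + 2, max(0, x0 - 1):x0 + 2] = SR_GRAY
    return img


def gen_eye_sequence(
    spec: EyeSceneSpec, fps: float, duration_s: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render eye frames and return them with a per-frame ground-truth table."""
    n = int(round(fps * duration_s))
    centers = np.asarray(spec.pupil_center, dtype=float)
    if centers.ndim == 1:
        centers = np.tile(centers, (n, 1))
    elif len(centers) != n:
        raise SpecError(f"trajectory length {len(centers)} != frame count {n}")

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    frames = np.empty((n, h, w), dtype=np.uint8)
    rows = []
    for i in range(n):
        t = i / fps
        state = _eye_state(t, spec.blink_schedule)
        if state == "open":
            img = _render_open_eye(spec, tuple(centers[i]))
        else:
            img = np.full((h, w), float(CLOSED_EYE_GRAY))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).round().astype(np.uint8)
        rows.append({"frame_index": i, "timestamp_s": t,
                     "pupil_x": centers[i, 0], "pupil_y": centers[i, 1],
                     "state": state})
    return frames, pd.DataFrame(rows)


def scheduled_transition_counts(
    spec: EyeSceneSpec, fps: float, duration_s: float,
    window: float = 60.0, step: float = 10.0,
) -> np.ndarray:
    """Per-window closed-to-open transition counts implied by the schedule.

    Independent of the image pipeline: states come straight from the blink
    schedule, and transitions are counted by a direct loop over windows.
    """
    n = int(round(fps * duration_s))
    states = [_eye_state(i / fps, spec.blink_schedule) for i in range(n)]
    total = n / fps
    if total < window:
        return np.zeros(0)
    n_win = int(np.floor((total - window) / step + 1e-9)) + 1
    counts = np.zeros(n_win)
    for k in range(n_win):
        t0 = k * step
        c = 0
        for i in range(n - 1):
            if states[i] == "closed" and states[i + 1] == "open":
                if i / fps >= t0 and (i + 1) / fps < t0 + window:
                    c += 1
        counts[k] = c
    return counts


def _texture(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    tex = gaussian_filter(noise, sigma=sigma, mode="wrap")
    lo, hi = tex.min(), tex.max()
    return 30.0 + (tex - lo) / (hi - lo) * 190.0


def _disparity_at(spec: StereoSceneSpec, i: int, t: float, n: int) -> int:
    d = spec.disparity
    if callable(d):
        return int(round(d(t)))
    arr = np.atleast_1d(np.asarray(d, dtype=float))
    if arr.size == 1:
        return int(round(arr[0]))
    if arr.size != n:
        raise SpecError(f"disparity schedule length {arr.size} != frame count {n}")
    return int(round(arr[i]))


def gen_anaglyph_video(
    spec: StereoSceneSpec, fps: float, duration_s: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render red-green anaglyph frames plus a ground-truth table.

    The green channel carries the left view and the red channel the right
    view, which is the left view translated by the scheduled disparity
    (objects by their own disparities). Scene changes regenerate the
    background texture.
    """
    n = int(round(fps * duration_s))
    h, w = spec.shape
    changes = sorted(spec.scene_changes)
    seeds = np.random.SeedSequence(spec.seed).spawn(len(changes) + 1)
    textures = [_texture((h, w), spec.texture_sigma, np.random.default_rng(s))
                for s in seeds]

    frames = np.zeros((n, h, w, 3), dtype=np.uint8)
    rows = []
    for i in range(n):
        t = i / fps
        seg = sum(1 for c in changes if t >= c)
        tex = textures[seg]
        d_bg = _disparity_at(spec, i, t, n)
        left = tex.copy()
        # matcher convention: right[x + d] == left[x], so shift rightward by d
        right = np.roll(tex, d_bg, axis=1)
        for obj in spec.objects:
            rng_o = np.random.default_rng(hash((spec.seed, obj.x, obj.y)) % (2**32))
            patch = np.clip(
                _texture((obj.height, obj.width), spec.texture_sigma, rng_o)
                + obj.gray_boost, 0, 255)
            d_o = int(round(obj.disparity))
            left[obj.y:obj.y + obj.height, obj.x:obj.x + obj.width] = patch
            xr = obj.x + d_o
            if 0 <= xr and xr + obj.width <= w:
                right[obj.y:obj.y + obj.height, xr:xr + obj.width] = patch
        frames[i, ..., 0] = np.clip(right, 0, 255).round().astype(np.uint8)
        frames[i, ..., 1] = np.clip(left, 0, 255).round().astype(np.uint8)
        rows.append({"frame_index": i, "timestamp_s": t, "disparity": d_bg,
                     "scene_change": any(abs(t - c) < 0.5 / fps for c in changes)})
    return frames, pd.DataFrame(rows)


def gen_gaze_scanpath(
    fixations: list[tuple[float, float, float]],
    saccade_ms: float = 40.0,
    fps: float = 15.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[GazeSample], list[int]]:
    """Piecewise-constant fixations with jitter joined by linear saccades.

    `fixations` is a list of (x, y, duration_s). Returns the samples and a
    parallel list of ground-truth fixation ids (-1 during saccadic transit).
    """
    if any(dur <= 0 for _, _, dur in fixations):
        raise ValueError("fixation durations must be positive")
    rng = np.random.default_rng(seed)
    samples: list[GazeSample] = []
    ids: list[int] = []
    t = 0.0
    for k, (x, y, dur) in enumerate(fixations):
        n = max(1, int(round(dur * fps)))
        for _ in range(n):
            jx, jy = (rng.normal(0, jitter_sd, 2) if jitter_sd > 0 else (0.0, 0.0))
            samples.append(GazeSample(timestamp=t, screen=(x + jx, y + jy), valid=True))
            ids.append(k)
            t += 1.0 / fps
        if k + 1 < len(fixations):
            nx, ny, _ = fixations[k + 1]
            n_sac = int(round(saccade_ms / 1000.0 * fps))
            for j in range(n_sac):
                a = (j + 1) / (n_sac + 1)
                samples.append(GazeSample(
                    timestamp=t, screen=(x + a * (nx - x), y + a * (ny - y)), valid=True))
                ids.append(-1)
                t += 1.0 / fps
    return samples, ids
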