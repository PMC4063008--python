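"""End-to-end orchestration: track -> gaze -> factors -> stats.

These helpers glue the per-frame operations into the CSV-to-CSV stages
exposed by the CLI and used by the synthetic recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eye_image, gaze as gaze_mod, stereo_factors, windows_stats
from .errors import FoveastrainError
from .eye_image import EyeFrame, SRQuad
from .foveation import FoveationPoint, apply_mask, build_mask, refine_foveation_point
from .gaze import FoveationGeometry, GazeSample, calibrate_kappa, map_gaze

__all__ = [
    "track_eye_frames",
    "gaze_from_track",
    "compute_factor_series",
    "stats_report",
]

TRACK_COLUMNS = [
    "frame_index", "timestamp_s", "pupil_x", "pupil_y", "pupil_radius",
    "black_count", "state",
    "sr1_x", "sr1_y", "sr2_x", "sr2_y", "sr3_x", "sr3_y", "sr4_x", "sr4_y",
]


def track_eye_frames(
    frames: np.ndarray,
    fps: float,
    *,
    radius_min: int = 10,
    radius_max: int | None = None,
    open_threshold: int = 200,
    dark_cutoff: int = eye_image.DEFAULT_DARK_CUTOFF,
) -> pd.DataFrame:
    """Run pupil/SR/blink detection on every frame of a sequence.

    Frames where the pupil or the SR quad cannot be found keep NaNs in the
    corresponding columns; the blink state is always computed.
    """
    rows = []
    for i, px in enumerate(frames):
        frame = EyeFrame(pixels=px, timestamp=i / fps, frame_index=i)
        row: dict = {"frame_index": i, "timestamp_s": i / fps}
        state = eye_image.blink_state(frame, None, open_threshold, dark_cutoff=dark_cutoff)
        row["state"] = state.state
        row["black_count"] = state.black_pixel_count
        try:
            pupil = eye_image.detect_pupil_ced(frame, radius_min, radius_max,
                                               dark_cutoff=dark_cutoff)
            pupil = eye_image.refine_pupil(frame, pupil)
            row["pupil_x"], row["pupil_y"] = pupil.center
            row["pupil_radius"] = pupil.radius
            srs = eye_image.detect_srs(frame, pupil)
            for k, (sx, sy) in enumerate(srs.points, start=1):
                row[f"sr{k}_x"], row[f"sr{k}_y"] = sx, sy
        except FoveastrainError:
            pass
        rows.append(row)
    return pd.DataFrame(rows).reindex(columns=TRACK_COLUMNS)


def gaze_from_track(
    track: pd.DataFrame,
    monitor: tuple[int, int],
    *,
    calib_frame: int = 0,
    compensate: bool = False,
    window_frames: int = 5,
    dispersion_px: float = 30.0,
) -> pd.DataFrame:
    """Map tracked pupil centers to monitor coordinates via the SR homography.

    The frame at `calib_frame` is assumed to fixate the monitor center and
    provides the kappa offset.
    """
    def _sample(row) -> GazeSample | None:
        if not np.isfinite(row["pupil_x"]) or not np.isfinite(row["sr1_x"]):
            return None
        srs = SRQuad(points=np.array(
            [[row[f"sr{k}_x"], row[f"sr{k}_y"]] for k in range(1, 5)]))
        return map_gaze((row["pupil_x"], row["pupil_y"]), srs, monitor)

    calib_row = track.iloc[calib_frame]
    kappa = None
    calib = _sample(calib_row)
    if calib is not None:
        kappa = calibrate_kappa(calib.screen, monitor)

    samples: list[GazeSample] = []
    for _, row in track.iterrows():
        s = _sample(row)
        if s is None:
            samples.append(GazeSample(timestamp=row["timestamp_s"],
                                      screen=(monitor[0] / 2, monitor[1] / 2),
                                      valid=False))
            continue
        x, y = s.screen
        if kappa is not None:
            x = min(max(x + kappa.dx, 0.0), monitor[0] - 1.0)
            y = min(max(y + kappa.dy, 0.0), monitor[1] - 1.0)
        samples.append(GazeSample(timestamp=row["timestamp_s"], screen=(x, y),
                                  valid=s.valid))
    if compensate:
        samples = gaze_mod.compensate_saccades(samples, window_frames, dispersion_px)
    return pd.DataFrame({
        "timestamp_s": [s.timestamp for s in samples],
        "screen_x": [s.screen[0] for s in samples],
        "screen_y": [s.screen[1] for s in samples],
        "valid": [s.valid for s in samples],
    })


def compute_factor_series(
    video_frames: np.ndarray,
    gaze_xy: np.ndarray,
    monitor: tuple[int, int],
    *,
    viewing_distance_widths: float = 3.0,
    gaze_error_deg: float = 1.12,
    block: int = 9,
    search_range: int = 16,
    fps: float = 15.0,
    refine_gaze: bool = True,
) -> pd.DataFrame:
    """CSD, SD, FCE and EC for every anaglyph frame.

    `gaze_xy` holds one (x, y) monitor-coordinate gaze point per frame;
    monitor coordinates are scaled to frame coordinates by the width ratio
    before foveation.
    """
    n = len(video_frames)
    if len(gaze_xy) != n:
        raise ValueError("need one gaze point per video frame")
    h, w = video_frames[0].shape[:2]
    scale = w / monitor[0]
    geometry = FoveationGeometry(N=w, v=viewing_distance_widths, e=gaze_error_deg)

    rows = []
    prev_fov = None
    for i in range(n):
        pair = stereo_factors.normalize_brightness(
            stereo_factors.split_anaglyph(video_frames[i]))
        gx, gy = gaze_xy[i]
        fx = float(np.clip(gx * scale, 0, w - 1))
        fy = float(np.clip(gy * scale, 0, h - 1))
        if refine_gaze:
            point = refine_foveation_point(pair.left, (fx, fy), geometry)
        else:
            point = FoveationPoint(xf=(fx, fy), xcf=(fx, fy), tmsm=0.0)
        mask = build_mask((h, w), point, geometry)

        disp = stereo_factors.compute_disparity(pair, block, search_range)
        fov_disp = stereo_factors.foveate_disparity(disp, mask)
        sd = float(fov_disp.sum())
        csd = stereo_factors.compute_csd(prev_fov, fov_disp) if prev_fov is not None else 0.0
        prev_fov = fov_disp

        fce = stereo_factors.compute_fce(gx, monitor[0])
        left_f = apply_mask(pair.left, mask)
        right_f = apply_mask(pair.right, mask)
        ec = stereo_factors.compute_ec(left_f, right_f)
        rows.append({"timestamp_s": i / fps, "csd": csd, "sd": sd,
                     "fce": fce, "ec": ec})
    return pd.DataFrame(rows)


def stats_report(
    blink: windows_stats.WindowSeries,
    factors: dict[str, windows_stats.WindowSeries],
) -> dict:
    """Per-factor correlation/gradient/R^2 plus the pairwise Cohen's d table."""
    report: dict = {"factors": {}}
    values = {}
    for name, series in factors.items():
        pairs = windows_stats.pair_and_normalize(blink, series)
        try:
            r, grad, r2 = windows_stats.correlate(pairs)
        except FoveastrainError:
            r = grad = r2 = float("nan")
        report["factors"][name] = {"pearson_r": r, "gradient": grad, "r_squared": r2}
        values[name] = pairs.factor
    names = list(factors)
    report["cohens_d"] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                eff = windows_stats.cohens_d(
                    float(np.mean(values[a])), float(np.std(values[a], ddof=1)),
                    float(np.mean(values[b])), float(np.std(values[b], ddof=1)))
                report["cohens_d"][f"{a}_vs_{b}"] = {"d": eff.d, "label": eff.label}
            except FoveastrainError:
                report["cohens_d"][f"{a}_vs_{b}"] = {"d": float("nan"), "label": ""}
    return report
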