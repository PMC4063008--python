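"""Windowing, pairing and the statistical battery relating factors to blink rate.

Blink rate and every factor are summed over 60 s windows advanced in 10 s
steps (50 s overlap), min-max normalized per user, then related by Pearson
correlation / OLS regression, a 2^2 factorial decomposition, Cohen's d with
small/medium/large labeling, and a paired two-tailed t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDesign, DegenerateInput, GridMismatch, ZeroSpread
from .eye_image import BlinkState

__all__ = [
    "WindowSeries",
    "PairedSeries",
    "FactorialResult",
    "EffectSize",
    "count_windows",
    "blink_rate_series",
    "window_sum_series",
    "pair_and_normalize",
    "correlate",
    "factorial_2k",
    "cohens_d",
    "paired_ttest_two_tailed",
]

DEFAULT_WINDOW_S = 60.0
DEFAULT_STEP_S = 10.0

_EPS = 1e-9  # guards float step arithmetic in window counting


@dataclass(frozen=True)
class WindowSeries:
    """One value per sliding window of `window_length` s advanced by `step` s."""

    values: np.ndarray
    window_length: float = DEFAULT_WINDOW_S
    step: float = DEFAULT_STEP_S
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairedSeries:
    """Per-window (blink_rate, factor) pairs, each min-max normalized to [0,1]."""

    blink: np.ndarray
    factor: np.ndarray

    def __len__(self) -> int:
        return len(self.blink)


@dataclass(frozen=True)
class FactorialResult:
    """Coefficients and variance decomposition of the 2^2 factorial design."""

    q0: float
    qA: float
    qB: float
    qAB: float

    @property
    def ss_a(self) -> float:
        return 4.0 * self.qA**2

    @property
    def ss_b(self) -> float:
        return 4.0 * self.qB**2

    @property
    def ss_ab(self) -> float:
        return 4.0 * self.qAB**2

    @property
    def ss_total(self) -> float:
        return self.ss_a + self.ss_b + self.ss_ab

    def _ratio(self, ss: float) -> float:
        if self.ss_total == 0.0:
            raise DegenerateDesign("zero total sum of squares; ratios undefined")
        return 100.0 * ss / self.ss_total

    @property
    def ratio_a(self) -> float:
        return self._ratio(self.ss_a)

    @property
    def ratio_b(self) -> float:
        return self._ratio(self.ss_b)

    @property
    def ratio_ab(self) -> float:
        return self._ratio(self.ss_ab)

    def predict(self, xa: float, xb: float) -> float:
        return self.q0 + self.qA * xa + self.qB * xb + self.qAB * xa * xb


@dataclass(frozen=True)
class EffectSize:
    d: float
    label: str  # "small" | "medium" | "large"


def count_windows(total_duration: float, window: float = DEFAULT_WINDOW_S,
                  step: float = DEFAULT_STEP_S) -> int:
    """floor((total - window)/step) + 1, or 0 when the video is shorter."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if total_duration < window:
        return 0
    return int(math.floor((total_duration - window) / step + _EPS)) + 1


def _window_starts(total_duration: float, window: float, step: float) -> np.ndarray:
    return np.arange(count_windows(total_duration, window, step)) * step


def blink_rate_series(
    states: list[BlinkState] | list[str],
    fps: float,
    window: float = DEFAULT_WINDOW_S,
    step: float = DEFAULT_STEP_S,
) -> WindowSeries:
    """Count closed-to-open transitions per window (open-to-close not counted).

    A transition between frames t and t+1 is credited to every window that
    contains both frame times; windows are [start, start + window).
    """
    flags = np.array(
        [s.is_open if isinstance(s, BlinkState) else s == "open" for s in states],
        dtype=bool,
    )
    n = len(flags)
    total = n / fps
    times = np.arange(n) / fps
    trans = np.flatnonzero(~flags[:-1] & flags[1:])  # index of the closed frame
    starts = _window_starts(total, window, step)
    counts = np.zeros(len(starts))
    for k, t0 in enumerate(starts):
        in_win = (times[trans] >= t0) & (times[trans + 1] < t0 + window)
        counts[k] = int(in_win.sum())
    return WindowSeries(values=counts, window_length=window, step=step, total_duration=total)


def window_sum_series(
    values: np.ndarray,
    fps: float,
    window: float = DEFAULT_WINDOW_S,
    step: float = DEFAULT_STEP_S,
) -> WindowSeries:
    """Sum per-frame factor values over each sliding window."""
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    total = n / fps
    times = np.arange(n) / fps
    starts = _window_starts(total, window, step)
    sums = np.zeros(len(starts))
    for k, t0 in enumerate(starts):
        sums[k] = vals[(times >= t0) & (times < t0 + window)].sum()
    return WindowSeries(values=sums, window_length=window, step=step, total_duration=total)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)  # constant series map to all-zeros by convention
    return (x - lo) / (hi - lo)


def pair_and_normalize(br: WindowSeries, factor: WindowSeries) -> PairedSeries:
    """Min-max normalize each series to [0, 1] and pair them per window."""
    if (len(br) != len(factor) or br.window_length != factor.window_length
            or br.step != factor.step):
        raise GridMismatch("blink-rate and factor series use different window grids")
    return PairedSeries(blink=_minmax(br.values), factor=_minmax(factor.values))


def correlate(pairs: PairedSeries) -> tuple[float, float, float]:
    """(Pearson r, OLS gradient of blink rate on the factor, R^2 of the fit)."""
    x, y = pairs.factor, pairs.blink
    if len(x) < 3:
        raise DegenerateInput("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInput("constant series: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope, r * r


def factorial_2k(y1: float, y2: float, y3: float, y4: float) -> FactorialResult:
    """Exact 2^2 factorial fit to the four cell means.

    Cells are ordered (Large, Large), (Small, Large), (Large, Small),
    (Small, Small) of (SD, CSD), coded xA, xB = (-1,-1), (1,-1), (-1,1), (1,1).
    """
    ys = (y1, y2, y3, y4)
    if not all(np.isfinite(ys)):
        raise ValueError("cell means must be finite")
    q0 = (y1 + y2 + y3 + y4) / 4.0
    qa = (-y1 + y2 - y3 + y4) / 4.0
    qb = (-y1 - y2 + y3 + y4) / 4.0
    qab = (y1 - y2 - y3 + y4) / 4.0
    return FactorialResult(q0=q0, qA=qa, qB=qb, qAB=qab)


_D_THRESHOLDS = {0.2: "small", 0.5: "medium", 0.8: "large"}


def label_effect_size(d: float) -> str:
    """Nearest of {0.2 small, 0.5 medium, 0.8 large} by |d|; above 0.8 large."""
    a = abs(d)
    if a >= 0.8:
        return "large"
    return min(_D_THRESHOLDS.items(), key=lambda kv: abs(a - kv[0]))[1]


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> EffectSize:
    """|mean1 - mean2| / sqrt((sd1^2 + sd2^2)/2) with a size label."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0.0:
        raise ZeroSpread("both groups have zero spread")
    d = abs(mean1 - mean2) / pooled
    return EffectSize(d=d, label=label_effect_size(d))


def paired_ttest_two_tailed(before, after) -> tuple[float, float]:
    """Paired t statistic and two-tailed p with n-1 degrees of freedom."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or len(b) < 2:
        raise DegenerateInput("need two equal-length samples of size >= 2")
    if np.all(b == a):
        raise DegenerateInput("all paired differences are zero")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)
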