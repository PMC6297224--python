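"""Per-lineage estimators for mother-machine time-lapse traces.

Inputs are per-frame observables of one trapped mother cell: time, cell
length ``l`` and mean fluorescence ``M`` of a transcriptional reporter,
recorded at a uniform frame interval (10 min by default).  From these the
module estimates:

* the relative single-cell growth rate g = l^-1 dl/dt, by forward
  differences with segmentation/division artefact correction and a 5-frame
  moving-average smooth;
* the promoter activity A = M (g + p) + dM/dt — the production rate of the
  reporter per unit cell length, corrected for dilution by growth and for
  bleaching/degradation at rate ``p``;
* activity pulses (local maxima of the smoothed activity, with heights read
  from the unsmoothed series in a 7-frame window);
* the normalized growth/activity cross-correlation;
* the lineage-population growth rate from the cell-cycle-time distribution;
* low-growth events (maximal runs below a threshold) and their
  complementary duration distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "FrameSeries",
    "GrowthSeries",
    "ActivitySeries",
    "Peak",
    "LowGrowthEvent",
    "PopulationSample",
    "moving_average",
    "growth_rate_series",
    "promoter_activity_series",
    "find_activity_peaks",
    "cross_correlation",
    "population_growth_rate",
    "low_growth_events",
    "event_duration_cdf",
    "display_smooth",
]

#: default frame interval (minutes) of the mother-machine movies
DEFAULT_FRAME_DT_MIN = 10.0
#: default bleaching/degradation constant for promoter activity (1/h)
DEFAULT_P = 0.1
#: default moving-average span (frames)
DEFAULT_SPAN = 5
#: default peak-height window (frames)
PEAK_WINDOW = 7


@dataclass
class FrameSeries:
    """Observed (or synthetic) per-frame record of one lineage.

    ``t`` is in hours, uniformly spaced; ``division[i] == 1`` marks frames
    following a division (the length dropped between i-1 and i).
    """

    t: np.ndarray
    l: np.ndarray
    M: np.ndarray
    division: np.ndarray | None = None
    lineage_id: int | str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.l = np.asarray(self.l, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if not (len(self.t) == len(self.l) == len(self.M)):
            raise ValueError("t, l and M must have equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame times must be uniformly spaced")
        if np.any(self.l <= 0):
            raise ValueError("lengths must be positive")
        if self.division is None:
            self.division = np.zeros(len(self.t), dtype=np.int8)
        else:
            self.division = np.asarray(self.division).astype(np.int8)
            if len(self.division) != len(self.t):
                raise ValueError("division markers must match frame count")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class GrowthSeries:
    """Per-frame growth-rate estimate (1/h).

    ``g`` is the final (smoothed) estimate; ``g_corrected`` is the
    unsmoothed, artefact-corrected series that the activity pipeline uses.
    """

    t: np.ndarray
    g: np.ndarray
    g_corrected: np.ndarray
    replaced: np.ndarray  # frames whose raw value was invalid/negative
    smoothed: bool = True
    span: int = DEFAULT_SPAN

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ActivitySeries:
    """Per-frame promoter activity (AU per hour per unit length)."""

    t: np.ndarray
    A: np.ndarray
    p: float = DEFAULT_P

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Peak:
    frame: int            # index of the smoothed-series local maximum
    height: float         # max of the unsmoothed activity in the window
    window: tuple = (0, 0)  # [lo, hi) span searched for the height


@dataclass
class LowGrowthEvent:
    start: int
    end: int              # inclusive frame index
    duration: float       # (end - start + 1) * frame interval
    censored: bool = False
    lineage_id: int | str | None = None

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass
class PopulationSample:
    """Distribution of cell-cycle times: fractions n_i at cycle times c_i (h)."""

    n: np.ndarray
    c: np.ndarray
    t_D: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if len(self.n) == 0 or len(self.n) != len(self.c):
            raise ValueError("n and c must be non-empty and equal length")
        if np.any(self.c <= 0):
            raise ValueError("cycle times must be positive")
        if not np.isclose(self.n.sum(), 1.0, atol=1e-8):
            raise ValueError("fractions must sum to 1")


def moving_average(x, span: int = DEFAULT_SPAN) -> np.ndarray:
    """Centered moving mean; endpoints use the shrinking symmetric window.

    With span 5 the first/last frame are untouched, the second/penultimate
    average 3 frames — the convention of MATLAB's ``smooth``.
    """
    x = np.asarray(x, dtype=float)
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    if span == 1:
        return x.copy()
    n = len(x)
    half = span // 2
    out = np.empty(n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return out


def _fill_invalid(raw: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Replace invalid entries by the mean of the nearest valid neighbours.

    "Nearest" is the closest preceding and the closest following valid
    frame; at trace edges the single available side is used.
    """
    out = raw.copy()
    valid_idx = np.flatnonzero(~invalid)
    if len(valid_idx) == 0:
        raise ValueError("no valid (non-negative) growth-rate frames")
    for i in np.flatnonzero(invalid):
        prev_candidates = valid_idx[valid_idx < i]
        next_candidates = valid_idx[valid_idx > i]
        vals = []
        if len(prev_candidates):
            vals.append(raw[prev_candidates[-1]])
        if len(next_candidates):
            vals.append(raw[next_candidates[0]])
        out[i] = float(np.mean(vals))
    return out


def growth_rate_series(frames: FrameSeries, span: int = DEFAULT_SPAN,
                       smooth: bool = True) -> GrowthSeries:
    """Relative growth rate g ~ (l_{t+1} - l_t) / (dt * l_t), cleaned.

    Frame pairs spanning a division are excluded from the raw difference
    (mother-cell halving is physiology, not shrinkage) and filled, like
    negative raw values (segmentation artefacts), with the mean of the
    nearest non-negative valid frames.  The final frame, which has no
    forward difference, is filled the same way.  The corrected series is
    then smoothed with a centered moving average (5 frames by default).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    dt = frames.dt
    n = len(frames)
    raw = np.empty(n)
    raw[:-1] = (frames.l[1:] - frames.l[:-1]) / (dt * frames.l[:-1])
    raw[-1] = np.nan
    invalid = np.zeros(n, dtype=bool)
    invalid[-1] = True
    # a marker at frame i+1 means the pair (i, i+1) straddles a division
    div_next = np.flatnonzero(frames.division[1:] == 1)
    invalid[div_next] = True
    with np.errstate(invalid="ignore"):
        invalid |= np.nan_to_num(raw, nan=-1.0) < 0
    corrected = _fill_invalid(raw, invalid)
    g = moving_average(corrected, span) if smooth else corrected.copy()
    return GrowthSeries(t=frames.t.copy(), g=g, g_corrected=corrected,
                        replaced=invalid, smoothed=smooth, span=span)


def promoter_activity_series(frames: FrameSeries, p: float = DEFAULT_P,
                             span: int = DEFAULT_SPAN) -> ActivitySeries:
    """Promoter activity A = M_s (g + p) + dM_s/dt, per unit cell length.

    ``M_s`` is the 5-frame moving average of the mean fluorescence and
    dM_s/dt its forward difference (backward at the final frame); ``g`` is
    the unsmoothed, artefact-corrected relative growth rate.  ``p``
    (default 0.1/h) lumps reporter degradation and photobleaching; the
    qualitative conclusions should not depend on it — see
    :func:`activity_p_sensitivity`.
    """
    growth = growth_rate_series(frames, span=span)
    dt = frames.dt
    M_s = moving_average(frames.M, span)
    dMdt = np.empty(len(frames))
    dMdt[:-1] = (M_s[1:] - M_s[:-1]) / dt
    dMdt[-1] = dMdt[-2] if len(frames) > 1 else 0.0
    A = M_s * (growth.g_corrected + p) + dMdt
    return ActivitySeries(t=frames.t.copy(), A=A, p=p)


def activity_p_sensitivity(frames: FrameSeries,
                           p_values=(0.05, 0.1, 0.2),
                           span: int = DEFAULT_SPAN) -> pd.DataFrame:
    """Recompute the activity series at several bleaching constants."""
    cols = {f"A_p{p:g}": promoter_activity_series(frames, p=p, span=span).A
            for p in p_values}
    return pd.DataFrame({"time_h": frames.t, **cols})


def _local_maxima(x: np.ndarray) -> list[int]:
    """Interior local maxima; plateaus yield their first frame. O(n)."""
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def find_activity_peaks(A, span: int = DEFAULT_SPAN,
                        window: int = PEAK_WINDOW) -> list[Peak]:
    """Activity pulses: local maxima of the smoothed series.

    The series is smoothed with a centered moving average (5 frames), local
    maxima are taken strictly greater than both neighbours (first frame of
    a plateau wins; endpoints are never peaks), and each peak's height is
    the highest value of the *unsmoothed* activity within a 7-frame window
    centered on the maximum (clipped at the trace ends).  Heights are
    absolute activity values; no baseline is subtracted.
    """
    a = A.A if isinstance(A, ActivitySeries) else np.asarray(A, dtype=float)
    if len(a) < window:
        raise ValueError(f"need at least {window} frames")
    smoothed = moving_average(a, span)
    half = window // 2
    peaks = []
    for i in _local_maxima(smoothed):
        lo = max(0, i - half)
        hi = min(len(a), i + half + 1)
        peaks.append(Peak(frame=i, height=float(np.max(a[lo:hi])),
                          window=(lo, hi)))
    return peaks


def cross_correlation(x, y, max_lag: int) -> pd.DataFrame:
    """Normalized cross-correlation of two equal-length series vs lag.

    c(k) = sum_t (x(t+k) - xbar)(y(t) - ybar)
           / sqrt(sum (x-xbar)^2 * sum (y-ybar)^2)

    — the ``xcov(..., 'coeff')`` convention: means over the whole series,
    one global normalization, so c(0) = 1 when x == y.  Positive lag means
    x shifted later than y.  Returns a DataFrame with columns (lag, corr).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        raise ValueError("constant series has zero autocovariance")
    full = np.correlate(xd, yd, mode="full")  # index n-1+k == lag k
    lags = np.arange(-max_lag, max_lag + 1)
    corr = full[n - 1 + lags[0]: n + lags[-1]] / denom
    return pd.DataFrame({"lag": lags, "corr": corr})


def average_cross_correlation(pairs, max_lag: int) -> pd.DataFrame:
    """Mean +/- SD of per-lineage normalized correlation curves."""
    curves = [cross_correlation(x, y, max_lag)["corr"].to_numpy()
              for x, y in pairs]
    stack = np.vstack(curves)
    return pd.DataFrame({
        "lag": np.arange(-max_lag, max_lag + 1),
        "corr_mean": stack.mean(axis=0),
        "corr_std": stack.std(axis=0, ddof=1) if len(curves) > 1
        else np.zeros(stack.shape[1]),
    })


def population_growth_rate(sample: PopulationSample) -> float:
    """Population growth rate from the cell-cycle-time distribution.

    Solves sum_i n_i 2^{t_D / c_i} = 2 for the population doubling time
    t_D (the left side is strictly increasing in t_D, equals 1 at 0 and is
    >= 2 at max c_i, so the root is bracketed) and returns ln2 / t_D.
    """
    n, c = sample.n, sample.c

    def objective(t):
        return float(np.sum(n * np.exp2(t / c))) - 2.0

    hi = float(c.max())
    if objective(hi) < 0:  # guard against rounding at the bracket edge
        hi *= 1.0 + 1e-9
    t_D = brentq(objective, 0.0, hi, xtol=1e-14, rtol=1e-14)
    sample.t_D = t_D
    return float(np.log(2.0) / t_D)


def low_growth_events(g, threshold: float, frame_dt: float | None = None,
                      t=None, lineage_id=None) -> list[LowGrowthEvent]:
    """Maximal runs of consecutive frames with g < threshold.

    Duration is run length x frame interval (same units as ``frame_dt``).
    Runs touching either trace boundary are included but flagged censored —
    their true duration is only bounded from below.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(g, GrowthSeries):
        if t is None:
            t = g.t
        g = g.g
    g = np.asarray(g, dtype=float)
    if frame_dt is None:
        if t is None:
            raise ValueError("provide frame_dt or a time axis")
        frame_dt = float(t[1] - t[0])
    below = g < threshold
    events = []
    n = len(g)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            events.append(LowGrowthEvent(
                start=i, end=j, duration=(j - i + 1) * frame_dt,
                censored=(i == 0 or j == n - 1), lineage_id=lineage_id))
            i = j + 1
        else:
            i += 1
    return events


def event_duration_cdf(events, complementary: bool = True) -> pd.DataFrame:
    """Duration distribution of low-growth events.

    By default the complementary cumulative fraction P(duration >= d) at
    the sorted unique durations (the orientation that makes "more long
    events" read as a heavier tail); ``complementary=False`` gives
    P(duration <= d).
    """
    if len(events) == 0:
        raise ValueError("no events")
    durations = np.sort(np.asarray(
        [e.duration if isinstance(e, LowGrowthEvent) else float(e)
         for e in events]))
    uniq = np.unique(durations)
    if complementary:
        frac = 1.0 - np.searchsorted(durations, uniq, side="left") / len(durations)
    else:
        frac = np.searchsorted(durations, uniq, side="right") / len(durations)
    return pd.DataFrame({"duration": uniq, "fraction": frac})


def display_smooth(x, span: int = DEFAULT_SPAN) -> np.ndarray:
    """Extra smoothing pass for plots only — never feed this to statistics."""
    return moving_average(np.asarray(x, dtype=float), span)
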