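"""Urge time-course analysis.

Suppression-failure trials are split into Urge High / Urge Low by each
trial's Pearson correlation with its subject's mean urgeometer curve, and the
landmarks of the mean High curve are extracted: rise onset (sustained
exceedance of a pre-onset baseline), elbow (two-line least-squares
changepoint of the rising segment), peak (argmax), return to baseline and
total duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    InsufficientSegmentError,
    NoOnsetError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Moving-average width (s) applied to mean curves before landmark detection.
DEFAULT_SMOOTHING_S = 0.2
#: Rise-onset criterion: baseline mean + K x baseline SD ...
ONSET_K = 2.0
#: ... sustained for at least this long.
ONSET_SUSTAIN_S = 0.25
#: Width (s) of the default pre-onset baseline (earliest part of the grid).
ONSET_BASELINE_S = 0.5


@dataclass
class UrgeCurve:
    """Across-trial mean and SD of urge epochs on a shared time grid."""

    mean: np.ndarray
    sd: np.ndarray
    times: np.ndarray
    n_trials: int
    label: str | None = None

    def __post_init__(self):
        if np.any(self.sd < 0):
            raise ParameterError("SD must be non-negative")
        if self.mean.shape != self.times.shape or self.sd.shape != self.times.shape:
            raise ParameterError("mean/sd/times must share one grid")


@dataclass
class UrgeLandmarks:
    """Landmark latencies of one urge curve, seconds relative to blink peak."""

    onset: float
    elbow: float
    peak: float
    return_time: float
    duration: float
    censored: bool = False


def correlate_trials(trials: np.ndarray, subject_mean: np.ndarray) -> np.ndarray:
    """Pearson r of each trial with the within-subject mean curve.

    Zero-variance trials (or a zero-variance mean) get r = 0 by convention.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    m = np.asarray(subject_mean, dtype=float)
    if trials.shape[1] != m.size or m.size < 2:
        raise ParameterError("trials and subject_mean must share >= 2 samples")
    tc = trials - trials.mean(axis=1, keepdims=True)
    mc = m - m.mean()
    denom = np.sqrt((tc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ mc) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def classify_trials(
    r: np.ndarray, rule: str = "median", threshold: float = 0.5
) -> np.ndarray:
    """Assign High/Low classes from per-trial correlations.

    ``median``: per-subject median split (ties and the median itself go Low,
    consistent with "about half" of trials being High).  ``threshold``: High
    iff r > ``threshold``.
    """
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        raise ParameterError("need at least 2 trials")
    if rule == "median":
        if np.all(r == r[0]):
            logger.warning("degenerate split: all correlations identical; all trials Low")
            return np.full(r.size, "Low", dtype=object)
        cut = np.median(r)
        return np.where(r > cut, "High", "Low").astype(object)
    if rule == "threshold":
        return np.where(r > threshold, "High", "Low").astype(object)
    raise ParameterError(f"unknown rule {rule!r}")


def classify_subject_trials(
    trials: np.ndarray,
    subjects: np.ndarray,
    rule: str = "median",
    threshold: float = 0.5,
    refine: bool = False,
) -> pd.DataFrame:
    """Correlate-and-classify per subject; returns a per-trial table.

    The within-subject mean includes all of that subject's trials.  With
    ``refine=True`` one refinement step recomputes the mean from the High set
    and re-correlates before the final split.
    """
    trials = np.asarray(trials, dtype=float)
    subjects = np.asarray(subjects)
    rows = np.empty(trials.shape[0], dtype=object)
    rvals = np.empty(trials.shape[0])
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        sub = trials[idx]
        r = correlate_trials(sub, sub.mean(axis=0))
        cls = classify_trials(r, rule=rule, threshold=threshold)
        if refine and np.any(cls == "High"):
            r = correlate_trials(sub, sub[cls == "High"].mean(axis=0))
            cls = classify_trials(r, rule=rule, threshold=threshold)
        rvals[idx] = r
        rows[idx] = cls
    return pd.DataFrame({"subject": subjects, "r": rvals, "urge_class": rows})


def mean_urge_curve(
    trials: np.ndarray, times: np.ndarray, label: str | None = None
) -> UrgeCurve:
    """Pointwise mean and SD across trials."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 1 or trials.size == 0:
        raise DegenerateInputError("empty trial class")
    sd = trials.std(axis=0, ddof=0) if trials.shape[0] > 1 else np.zeros(trials.shape[1])
    return UrgeCurve(
        mean=trials.mean(axis=0),
        sd=sd,
        times=np.asarray(times, dtype=float),
        n_trials=trials.shape[0],
        label=label,
    )


def smooth_curve(y: np.ndarray, fs: float, width_s: float = DEFAULT_SMOOTHING_S) -> np.ndarray:
    """Centered moving average; edges are normalised by the actual window
    coverage so the curve is not pulled toward zero.  width_s = 0 disables."""
    if width_s <= 0:
        return np.asarray(y, dtype=float)
    w = max(1, int(round(width_s * fs)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def _as_curve_arrays(curve, smoothing_s: float):
    if isinstance(curve, UrgeCurve):
        y, t = curve.mean, curve.times
    else:
        y, t = curve
        y = np.asarray(y, dtype=float)
        t = np.asarray(t, dtype=float)
    fs = 1.0 / np.median(np.diff(t))
    return smooth_curve(y, fs, smoothing_s), t


def detect_peak(curve, smoothing_s: float = DEFAULT_SMOOTHING_S) -> float:
    """Latency of the maximum of the (optionally smoothed) mean curve.

    Ties go to the earliest sample; a constant curve is degenerate.
    """
    y, t = _as_curve_arrays(curve, smoothing_s)
    if np.all(y == y[0]):
        raise DegenerateInputError("constant curve has no peak")
    return float(t[int(np.argmax(y))])


def _segment_sse_prefix(x: np.ndarray, y: np.ndarray):
    """Vectorised SSE of least-squares lines on all prefixes/suffixes.

    Returns (sse_prefix, sse_suffix) where sse_prefix[j] is the SSE of a line
    fit to points 0..j and sse_suffix[j] the SSE of a line fit to j..n-1.
    Computed from running sums of x, y, x^2, y^2, xy.
    """
    def running_sse(xs, ys):
        n = np.arange(1, xs.size + 1, dtype=float)
        sx = np.cumsum(xs)
        sy = np.cumsum(ys)
        sxx = np.cumsum(xs * xs)
        syy = np.cumsum(ys * ys)
        sxy = np.cumsum(xs * ys)
        vxx = sxx - sx * sx / n
        vyy = syy - sy * sy / n
        vxy = sxy - sx * sy / n
        with np.errstate(invalid="ignore", divide="ignore"):
            sse = vyy - np.where(vxx > 0, vxy * vxy / np.maximum(vxx, 1e-300), 0.0)
        return np.maximum(sse, 0.0)

    sse_pre = running_sse(x, y)
    sse_suf = running_sse(x[::-1], y[::-1])[::-1]
    return sse_pre, sse_suf


def two_line_sse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Total SSE of two independent line fits split at each interior index.

    ``sse[j]`` covers segments [0..j] and [j..n-1] (the breakpoint belongs to
    both); entries with fewer than 3 points on either side are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sse_pre, sse_suf = _segment_sse_prefix(x, y)
    n = x.size
    out = np.full(n, np.nan)
    j = np.arange(2, n - 2)
    out[j] = sse_pre[j] + sse_suf[j]
    return out


def detect_elbow(
    curve,
    t_start: float | None = None,
    t_end: float | None = None,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
    method: str = "exhaustive",
) -> float:
    """Two-line-fit changepoint of the rising segment.

    Returns the interior grid point minimising the summed SSE of independent
    least-squares lines fit to [t_start, b] and [b, t_end].  The exhaustive
    grid scan is the reference behaviour; ``method='bisection'`` runs a
    ternary search (valid when the SSE profile is unimodal) with a terminal
    exhaustive scan of the final bracket.
    """
    y, t = _as_curve_arrays(curve, smoothing_s)
    if t_start is None:
        t_start = detect_rise_onset(curve, smoothing_s=smoothing_s)
    if t_end is None:
        t_end = detect_peak(curve, smoothing_s=smoothing_s)
    if not t_start < t_end:
        raise ParameterError("t_start must precede t_end")
    m = (t >= t_start) & (t <= t_end)
    xs, ys = t[m], y[m]
    if xs.size < 5:
        raise InsufficientSegmentError("need >= 3 points on each side of the breakpoint")
    sse = two_line_sse(xs, ys)
    valid = np.flatnonzero(~np.isnan(sse))
    if method == "exhaustive":
        best = valid[np.nanargmin(sse[valid])]
    elif method == "bisection":
        best = _ternary_search_min(lambda j: sse[j], valid)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(xs[best])


def _ternary_search_min(f, candidates: np.ndarray, final_scan: int = 32) -> int:
    """Ternary search over an (assumed unimodal) discrete function, finishing
    with an exhaustive scan of the final bracket."""
    lo, hi = 0, candidates.size - 1
    while hi - lo > final_scan:
        m1 = lo + (hi - lo) // 3
        m2 = hi - (hi - lo) // 3
        if f(candidates[m1]) <= f(candidates[m2]):
            hi = m2 - 1
        else:
            lo = m1 + 1
    span = candidates[lo : hi + 1]
    vals = np.array([f(j) for j in span])
    return int(span[int(np.argmin(vals))])


def detect_rise_onset(
    curve,
    baseline_window: tuple | None = None,
    k: float = ONSET_K,
    sustain_s: float = ONSET_SUSTAIN_S,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
) -> float:
    """Earliest time after which the curve stays above baseline mean +
    ``k`` x baseline SD for at least ``sustain_s``.

    The default baseline is the earliest ``0.5`` s of the grid (a pre-onset
    quiet period); pass an explicit ``baseline_window`` to override.
    """
    y, t = _as_curve_arrays(curve, smoothing_s)
    fs = 1.0 / np.median(np.diff(t))
    if baseline_window is None:
        baseline_window = (t[0], t[0] + ONSET_BASELINE_S)
    bl = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not np.any(bl):
        raise ParameterError("baseline window outside the curve grid")
    thr = y[bl].mean() + k * y[bl].std(ddof=0)
    above = y > thr
    w = max(1, int(round(sustain_s * fs)))
    if above.size < w:
        raise ParameterError("sustain window longer than the curve")
    sustained = np.convolve(above.astype(int), np.ones(w, dtype=int), mode="valid") == w
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        raise NoOnsetError("curve never exceeds the onset criterion")
    return float(t[idx[0]])


def urge_duration(
    curve,
    baseline_window: tuple | None = None,
    k: float = ONSET_K,
    sustain_s: float = ONSET_SUSTAIN_S,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
) -> float:
    """Time from rise onset to the first sustained return to the baseline
    band after the peak; censored at the epoch end (with a warning) if the
    curve never returns."""
    return landmarks(
        curve,
        baseline_window=baseline_window,
        k=k,
        sustain_s=sustain_s,
        smoothing_s=smoothing_s,
    ).duration


def landmarks(
    curve,
    baseline_window: tuple | None = None,
    k: float = ONSET_K,
    sustain_s: float = ONSET_SUSTAIN_S,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
) -> UrgeLandmarks:
    """All landmarks of one urge curve (onset < elbow < peak asserted)."""
    y, t = _as_curve_arrays(curve, smoothing_s)
    fs = 1.0 / np.median(np.diff(t))
    onset = detect_rise_onset(curve, baseline_window, k, sustain_s, smoothing_s)
    peak = detect_peak(curve, smoothing_s)
    try:
        elbow = detect_elbow(curve, onset, peak, smoothing_s)
    except (InsufficientSegmentError, ParameterError):
        elbow = float("nan")  # e.g. a rectangular pulse has no rising segment
    if np.isfinite(elbow) and not onset < elbow < peak:
        raise DegenerateInputError("landmark ordering onset < elbow < peak violated")

    if baseline_window is None:
        baseline_window = (t[0], t[0] + ONSET_BASELINE_S)
    bl = (t >= baseline_window[0]) & (t <= baseline_window[1])
    thr = y[bl].mean() + k * y[bl].std(ddof=0)
    after = t > peak
    below = (y <= thr) & after
    w = max(1, int(round(sustain_s * fs)))
    censored = False
    ret_idx = None
    flat = below.astype(int)
    run = np.convolve(flat, np.ones(w, dtype=int), mode="valid") == w
    idx = np.flatnonzero(run)
    if idx.size:
        ret_idx = idx[0]
    else:
        # allow a shorter run touching the epoch end
        tail = np.flatnonzero(below)
        if tail.size and np.all(below[tail[0]:]):
            ret_idx = tail[0]
    if ret_idx is None:
        censored = True
        ret = float(t[-1])
        logger.warning("urge curve never returned to baseline; duration censored")
    else:
        ret = float(t[ret_idx])
    return UrgeLandmarks(
        onset=onset,
        elbow=elbow,
        peak=peak,
        return_time=ret,
        duration=ret - onset,
        censored=censored,
    )
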