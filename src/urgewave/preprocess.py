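"""Blink preprocessing: band-pass filtering, algorithmic blink-peak
detection, per-minute rate normalisation and behavioural statistics,
blink-locked epoching, and the PVAF data-reduction metric.

The latency convention shared by the whole pipeline is seconds relative to
the blink *peak* (the highest-amplitude moment of the EOG waveform, not its
onset); negative latencies are before the blink.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import (
    DegenerateInputError,
    EmptyEpochSetError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Core analysis window around the blink peak, seconds.
DEFAULT_WINDOW = (-4.030, 1.000)
#: Symmetric padding so wavelet edge artifacts fall outside the core window.
DEFAULT_PAD_S = 1.5
#: ERSP baseline window, seconds relative to the blink peak.
DEFAULT_BASELINE = (-4.0, -3.0)

#: Minimum number of blinks for a subject to enter group analysis.
MIN_BLINKS = {"NoSupp": 20, "Supp": 10, "SuppRwd": 10}


def bandpass(x: np.ndarray, fs: float, lo: float = 1.5, hi: float = 55.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A 4th-order filter applied forward-backward gives ~48 dB/octave roll-off,
    comfortably above the required 20 dB one octave outside the band.
    """
    if not lo < hi:
        raise ParameterError("lo must be < hi")
    if hi >= fs / 2:
        raise ParameterError("hi must be below the Nyquist frequency")
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def detect_blinks(
    eog_trace: np.ndarray,
    fs: float,
    threshold_k: float = 5.0,
    refractory_s: float = 0.5,
) -> np.ndarray:
    """Robust-threshold peak picking on an EOG/blink-component trace.

    Local maxima exceeding ``median + threshold_k x robust SD`` (robust SD =
    1.4826 x MAD, insensitive to the sparse high-amplitude blinks themselves)
    and separated by at least ``refractory_s`` are returned as peak latencies
    in seconds.  A flat or sub-threshold trace yields an empty result.
    """
    x = np.asarray(eog_trace, dtype=float)
    if x.ndim != 1 or x.size < fs:
        raise ParameterError("trace must be 1-D with at least 1 s of samples")
    med = np.median(x)
    rsd = 1.4826 * np.median(np.abs(x - med))
    if rsd == 0.0:
        return np.empty(0)
    thr = med + threshold_k * rsd
    peaks, _ = signal.find_peaks(
        x, height=thr, distance=max(1, int(round(refractory_s * fs)))
    )
    return peaks / fs


def blink_rate_per_minute(events, block_duration_s: float) -> float:
    """Normalise a blink count to events per minute."""
    if block_duration_s <= 0:
        raise ParameterError("block_duration_s must be > 0")
    if isinstance(events, pd.DataFrame):
        count = int((events["trial_type"] == "blink_peak").sum())
    else:
        count = len(events)
    return 60.0 * count / block_duration_s


def paired_ttests_bonferroni(rates: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired t-tests across condition columns, Bonferroni-corrected.

    ``rates`` is a subjects x conditions table with no missing cells.  The
    corrected p is the raw p multiplied by the number of pairs, capped at 1.
    Identical columns give t = 0 and p = 1; a constant non-zero difference
    (zero variance, non-zero mean) is flagged as degenerate.
    """
    if rates.isna().any().any():
        raise ParameterError("rates table has missing cells")
    if len(rates) < 2:
        raise ParameterError("need at least 2 subjects")
    conds = list(rates.columns)
    pairs = list(itertools.combinations(conds, 2))
    rows = []
    for a, b in pairs:
        d = rates[a].to_numpy(dtype=float) - rates[b].to_numpy(dtype=float)
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        elif np.std(d, ddof=1) == 0.0:
            raise DegenerateInputError(
                f"constant non-zero difference between {a} and {b}"
            )
        else:
            t, p = stats.ttest_rel(rates[a], rates[b])
        rows.append(
            {
                "pair": f"{a}-{b}",
                "t": float(t),
                "df": len(d) - 1,
                "p": float(p),
                "p_corrected": min(1.0, float(p) * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def apply_inclusion_rule(
    blink_counts: pd.DataFrame, minimums: dict = MIN_BLINKS
) -> list:
    """Retain subjects with strictly more blinks than the per-condition minimum.

    ``blink_counts`` is a subjects x conditions table of blink counts.
    """
    keep = []
    for subject, row in blink_counts.iterrows():
        ok = all(row[c] > m for c, m in minimums.items() if c in row.index)
        if ok:
            keep.append(subject)
        else:
            logger.info("subject %s excluded by minimum-blink rule: %s", subject, dict(row))
    return keep


@dataclass
class EpochSet:
    """Blink-locked epochs of a single trace with per-epoch metadata.

    ``times`` spans ``[window[0] - pad_s, window[1] + pad_s]`` and contains
    exactly 0 at the event sample; the pad exists so that wavelet edge
    artifacts can be discarded inside, not at, the core window limits.
    """

    data: np.ndarray                 # (n_epochs, n_samples)
    times: np.ndarray                # seconds relative to the event
    fs: float
    metadata: pd.DataFrame
    window: tuple = DEFAULT_WINDOW
    pad_s: float = DEFAULT_PAD_S
    baseline: tuple = DEFAULT_BASELINE
    n_excluded: int = 0

    def __post_init__(self):
        if self.data.shape[0] != len(self.metadata):
            raise ParameterError("metadata length must equal n_epochs")
        if self.data.shape[1] != self.times.size:
            raise ParameterError("times length must equal n_samples")
        if not np.any(self.times == 0.0):
            raise ParameterError("epoch time grid must contain 0")
        if not (self.window[0] <= self.baseline[0] < self.baseline[1] <= self.window[1]):
            raise ParameterError("baseline window must lie inside the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        """Subset of epochs by boolean mask or index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            fs=self.fs,
            metadata=self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.metadata.iloc[mask].reset_index(drop=True),
            window=self.window,
            pad_s=self.pad_s,
            baseline=self.baseline,
            n_excluded=self.n_excluded,
        )

    def crop(self, t_min: float, t_max: float) -> "EpochSet":
        m = (self.times >= t_min) & (self.times <= t_max)
        return dataclasses_replace_epochs(self, self.data[:, m], self.times[m])


def dataclasses_replace_epochs(es: EpochSet, data, times) -> EpochSet:
    return EpochSet(
        data=data, times=times, fs=es.fs, metadata=es.metadata, window=es.window,
        pad_s=es.pad_s, baseline=es.baseline, n_excluded=es.n_excluded,
    )


def epoch(
    trace: np.ndarray,
    fs: float,
    events,
    window: tuple = DEFAULT_WINDOW,
    pad_s: float = DEFAULT_PAD_S,
    metadata: pd.DataFrame | None = None,
    baseline: tuple = DEFAULT_BASELINE,
) -> EpochSet:
    """Cut one epoch per event fully inside the padded recording.

    ``events`` is a sequence of event latencies in seconds (or an event table
    with ``trial_type == 'blink_peak'`` rows).  Events whose padded epoch
    would cross a recording edge are excluded and counted in ``n_excluded``.
    The sample at relative time 0 equals the recording sample at the event
    latency exactly.
    """
    x = np.asarray(trace, dtype=float)
    if isinstance(events, pd.DataFrame):
        blink = events[events["trial_type"] == "blink_peak"]
        latencies = blink["onset"].to_numpy(dtype=float)
        if metadata is None:
            metadata = blink.reset_index(drop=True)
    else:
        latencies = np.asarray(events, dtype=float)
    if metadata is None:
        metadata = pd.DataFrame({"onset": latencies})
    if len(metadata) != latencies.size:
        raise ParameterError("metadata length must equal number of events")

    pre = int(round((pad_s - window[0]) * fs))
    post = int(round((window[1] + pad_s) * fs))
    centers = np.round(latencies * fs).astype(int)
    ok = (centers - pre >= 0) & (centers + post < x.size)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.info("epoching excluded %d event(s) too close to recording edges", n_excluded)
    centers = centers[ok]
    if centers.size == 0:
        raise EmptyEpochSetError("no events survived epoching")
    offsets = np.arange(-pre, post + 1)
    data = x[centers[:, None] + offsets[None, :]]
    return EpochSet(
        data=data,
        times=offsets / fs,
        fs=fs,
        metadata=metadata.iloc[ok].reset_index(drop=True),
        window=tuple(window),
        pad_s=pad_s,
        baseline=tuple(baseline),
        n_excluded=n_excluded,
    )


def compute_pvaf(original: np.ndarray, processed: np.ndarray) -> float:
    """Percent variance accounted for by a processing step.

    ``100 * (1 - var(original - processed) / var(original))``, with variance
    pooled over all channels and samples.  Identity processing gives 100,
    total removal gives 0.
    """
    original = np.asarray(original, dtype=float)
    processed = np.asarray(processed, dtype=float)
    if original.shape != processed.shape:
        raise ParameterError("original and processed must have equal shapes")
    v0 = np.var(original)
    if v0 == 0.0:
        raise DegenerateInputError("original signal has zero variance")
    return 100.0 * (1.0 - np.var(original - processed) / v0)
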