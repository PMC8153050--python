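"""Event-related spectral perturbation (ERSP).

Blink-locked epochs are decomposed with complex Morlet wavelets (wavelet
support = cycles(f)/f seconds, cycles growing linearly with frequency),
power is averaged across trials per unit, expressed in dB relative to the
mean power in the pre-blink baseline window ([-4, -3] s by default), and
resampled onto the output grid (100 frequencies x 252 latencies by default).
Positive dB means power above baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .exceptions import DegenerateInputError, EdgeContaminationError, ParameterError
from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ERSPConfig:
    f_min: float = 1.0
    f_max: float = 55.0
    n_freqs: int = 100
    freq_spacing: str = "linear"      # or "log"
    t_min: float = -4.030
    t_max: float = 1.000
    n_times: int = 252
    c_min: float = 3.0                # cycles at f_min ...
    c_max: float = 16.0               # ... growing linearly to c_max at f_max
    baseline: tuple = (-4.0, -3.0)
    single_trial_baseline: bool = False

    def __post_init__(self):
        if self.n_freqs < 2 or self.n_times < 2:
            raise ParameterError("n_freqs and n_times must be >= 2")
        if not self.f_min < self.f_max:
            raise ParameterError("f_min must be < f_max")
        if not (self.t_min <= self.baseline[0] < self.baseline[1] <= self.t_max):
            raise ParameterError("baseline must lie inside the output window")

    @property
    def freqs(self) -> np.ndarray:
        if self.freq_spacing == "linear":
            return np.linspace(self.f_min, self.f_max, self.n_freqs)
        if self.freq_spacing == "log":
            return np.geomspace(self.f_min, self.f_max, self.n_freqs)
        raise ParameterError("freq_spacing must be 'linear' or 'log'")

    def cycles(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        return self.c_min + (self.c_max - self.c_min) * (f - self.f_min) / (
            self.f_max - self.f_min
        )

    @property
    def out_times(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_times)


@dataclass
class ERSPTensor:
    """dB power maps: frequencies x latencies x units, shared grid."""

    values: np.ndarray               # (n_freqs, n_times, n_units)
    freqs: np.ndarray
    times: np.ndarray
    units: pd.DataFrame              # one row per unit (subject, condition, ...)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("ERSP values must be finite")
        if self.values.shape[2] != len(self.units):
            raise ParameterError("unit metadata length mismatch")

    @property
    def unit_array(self) -> np.ndarray:
        """(n_units, n_freqs, n_times) view for the statistics module."""
        return np.moveaxis(self.values, 2, 0)


def morlet_wavelet(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet with support ``n_cycles / freq`` s."""
    half = int(round(n_cycles / freq * fs / 2.0))
    t = np.arange(-half, half + 1) / fs
    sigma = n_cycles / (2.0 * np.pi * freq)
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_power(
    epochs: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    cycles: np.ndarray,
    chunk: int = 16,
) -> np.ndarray:
    """Squared magnitude of the complex Morlet transform.

    ``epochs`` is (n_epochs, n_times) or 1-D; returns power with shape
    (n_epochs, n_freqs, n_times).  The signal must be at least as long as the
    longest wavelet, otherwise every output sample would be edge-contaminated.
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    cycles = np.broadcast_to(np.asarray(cycles, dtype=float), freqs.shape)
    n_t = x.shape[1]
    wavelets = [morlet_wavelet(f, c, fs) for f, c in zip(freqs, cycles)]
    max_w = max(w.size for w in wavelets)
    if n_t < max_w:
        raise EdgeContaminationError(
            f"signal ({n_t} samples) shorter than the longest wavelet ({max_w})"
        )
    nfft = next_fast_len(n_t + max_w - 1)
    X = fft(x, nfft, axis=-1)
    out = np.empty((x.shape[0], freqs.size, n_t))
    for start in range(0, freqs.size, chunk):
        block = wavelets[start : start + chunk]
        W = np.stack([fft(w, nfft) for w in block])           # (b, nfft)
        conv = ifft(X[:, None, :] * W[None, :, :], axis=-1)   # (n_ep, b, nfft)
        for bi, w in enumerate(block):
            lag = (w.size - 1) // 2
            out[:, start + bi, :] = np.abs(conv[:, bi, lag : lag + n_t]) ** 2
    return out


def baseline_db(
    power: np.ndarray, times: np.ndarray, baseline_window: tuple
) -> np.ndarray:
    """dB relative to the per-frequency mean power in the baseline window.

    ``power`` is (..., n_freqs, n_times); the baseline mean is taken over the
    time samples inside the window of the *given* map (classic ERSP applies
    this to the trial-averaged power).
    """
    times = np.asarray(times, dtype=float)
    m = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not np.any(m):
        raise ParameterError("baseline window is empty on the time grid")
    base = np.mean(power[..., m], axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise DegenerateInputError("zero baseline power")
    return 10.0 * np.log10(power / base)


def compute_ersp(
    epochs: EpochSet,
    config: ERSPConfig = ERSPConfig(),
    unit_col: str | None = None,
) -> ERSPTensor:
    """Per-unit trial-averaged baseline-normalised ERSP on the output grid.

    Units are groups of epochs sharing ``unit_col`` in the metadata (the
    ``subject`` column by default; a single unit when neither is present).
    The epoch padding must cover at least half the longest wavelet beyond the
    output window so that no edge artifact enters it.
    """
    freqs = config.freqs
    cycles = config.cycles(freqs)
    half_w = (cycles[0] / freqs[0]) / 2.0
    tol = 1.5 / epochs.fs
    if (
        epochs.times[0] > config.t_min - half_w + tol
        or epochs.times[-1] < config.t_max + half_w - tol
    ):
        raise EdgeContaminationError(
            "epoch padding too small for the longest wavelet: need "
            f"[{config.t_min - half_w:.3f}, {config.t_max + half_w:.3f}] s"
        )

    md = epochs.metadata
    if unit_col is None:
        unit_col = "subject" if "subject" in md.columns else None
    if unit_col is None:
        groups = {0: np.arange(epochs.n_epochs)}
        md = md.assign(unit=0)
        unit_col = "unit"
    else:
        groups = {
            key: idx.to_numpy()
            for key, idx in md.groupby(unit_col, sort=True).groups.items()
        }

    out_times = config.out_times
    raw_idx = np.array(
        [int(np.argmin(np.abs(epochs.times - t))) for t in out_times]
    )
    values = []
    unit_rows = []
    for key, idx in groups.items():
        if idx.size == 0:
            logger.info("unit %r has zero epochs; dropped", key)
            continue
        power = morlet_power(epochs.data[idx], epochs.fs, freqs, cycles)
        if config.single_trial_baseline:
            power = 10 ** (
                baseline_db(power, epochs.times, config.baseline) / 10.0
            )
        avg = power.mean(axis=0)
        db = baseline_db(avg, epochs.times, config.baseline)
        values.append(db[:, raw_idx])
        row = {unit_col: key}
        first = md.iloc[idx[0]]
        for col in ("subject", "condition", "urge_class"):
            if col in md.columns:
                row.setdefault(col, first[col])
        row["n_epochs"] = int(idx.size)
        unit_rows.append(row)
    if not values:
        raise DegenerateInputError("no unit had any epochs")
    return ERSPTensor(
        values=np.stack(values, axis=-1),
        freqs=freqs,
        times=out_times,
        units=pd.DataFrame(unit_rows),
    )
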