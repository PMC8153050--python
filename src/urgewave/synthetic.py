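"""Seeded synthetic cohort generator.

Emulates the structure of a paediatric blink-suppression EEG study: for each
subject there are three block conditions (blink freely ``NoSupp``, verbal
suppression ``Supp``, suppression for reward ``SuppRwd``).  Every session
carries a small set of source signals (post-ICA style activations): a
left-prefrontal source with a theta (4-8 Hz) power increase around blinks in
the suppression conditions, an anterior-cingulate source with a delta
(1-4 Hz) power decrease that under plain suppression follows high-urge blinks
only but under reward applies to both urge classes, and an EOG source
emitting a stereotyped high-amplitude blink waveform at every blink.  During
suppression blocks a continuous joystick "urgeometer" trace is simulated by
placing a premonitory-urge kernel at every high-urge blink.

Every random decision flows from a single seed and full ground truth (blink
latencies, urge classes, planted effect windows, dipole cluster labels) is
returned alongside the data, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from numpy.random import Generator, SeedSequence, default_rng
from scipy import ndimage, signal

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

CONDITIONS = ("NoSupp", "Supp", "SuppRwd")
URGE_CLASSES = ("High", "Low")

#: Blink rates per minute across subjects: (mean, SD) per condition.
DEFAULT_BLINK_RATES = {
    "NoSupp": (17.8, 8.9),
    "Supp": (10.7, 6.2),
    "SuppRwd": (8.4, 4.4),
}

#: Cluster centres (mm, MNI-like frame) for the planted dipole cloud.
#: Pairwise separation is at least 40 mm (>= 5x the default 8 mm spread).
DEFAULT_DIPOLE_CENTERS = np.array(
    [
        [-40.0, 35.0, 30.0],   # left dorsolateral prefrontal
        [40.0, 35.0, 30.0],    # right dorsolateral prefrontal
        [0.0, 25.0, 28.0],     # anterior cingulate
        [0.0, -20.0, 60.0],    # supplementary motor / midline central
        [-50.0, -20.0, 45.0],  # left sensorimotor
        [50.0, -20.0, 45.0],   # right sensorimotor
        [-45.0, -65.0, 35.0],  # left parietal
        [45.0, -65.0, 35.0],   # right parietal
        [0.0, -75.0, 40.0],    # precuneus
        [0.0, -95.0, 5.0],     # occipital
        [-55.0, -25.0, -5.0],  # left temporal
        [55.0, -25.0, -5.0],   # right temporal
    ]
)


def _as_rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UrgeKernel:
    """Piecewise-linear premonitory-urge template.

    The urge is zero until ``t_onset``, rises slowly to ``elbow_level *
    peak_amplitude`` at ``t_elbow``, rises steeply to ``peak_amplitude`` at
    ``t_peak``, declines back to zero at ``t_return`` and then briefly
    undershoots by ``undershoot_depth``.  Times are seconds relative to the
    blink peak (negative = before).
    """

    t_onset: float = -5.0
    t_elbow: float = -1.8
    t_peak: float = -0.4
    t_return: float = 2.0
    peak_amplitude: float = 1.0
    elbow_level: float = 0.3
    undershoot_depth: float = 0.05
    undershoot_halfwidth_s: float = 0.25
    smoothing_width: float = 0.0

    def __post_init__(self):
        if not (self.t_onset < self.t_elbow < self.t_peak < 0.0 < self.t_return):
            raise ParameterError(
                "urge kernel breakpoints must satisfy "
                "t_onset < t_elbow < t_peak < 0 < t_return"
            )
        if not 0.0 <= self.peak_amplitude <= 1.0:
            raise ParameterError("peak_amplitude must be in [0, 1]")
        if not 0.0 < self.elbow_level < 1.0:
            raise ParameterError("elbow_level must be in (0, 1)")
        if self.undershoot_depth < 0:
            raise ParameterError("undershoot_depth must be >= 0")
        if self.smoothing_width < 0:
            raise ParameterError("smoothing_width must be >= 0")
        if self.peak_amplitude > 0 and not self.slope_post > self.slope_pre > 0:
            raise ParameterError(
                "kernel must rise faster after the elbow (slope_post > slope_pre > 0)"
            )

    @property
    def slope_pre(self) -> float:
        """Urge-units/s over [t_onset, t_elbow]."""
        return self.elbow_level * self.peak_amplitude / (self.t_elbow - self.t_onset)

    @property
    def slope_post(self) -> float:
        """Urge-units/s over [t_elbow, t_peak]."""
        return (
            (1.0 - self.elbow_level)
            * self.peak_amplitude
            / (self.t_peak - self.t_elbow)
        )

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the (unsmoothed) kernel at arbitrary times."""
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        p = self
        rise1 = (t >= p.t_onset) & (t < p.t_elbow)
        v[rise1] = p.slope_pre * (t[rise1] - p.t_onset)
        elbow_val = p.elbow_level * p.peak_amplitude
        rise2 = (t >= p.t_elbow) & (t < p.t_peak)
        v[rise2] = elbow_val + p.slope_post * (t[rise2] - p.t_elbow)
        fall = (t >= p.t_peak) & (t < p.t_return)
        v[fall] = p.peak_amplitude * (p.t_return - t[fall]) / (p.t_return - p.t_peak)
        if p.undershoot_depth > 0:
            hw = p.undershoot_halfwidth_s
            down = (t >= p.t_return) & (t < p.t_return + hw)
            v[down] = -p.undershoot_depth * (t[down] - p.t_return) / hw
            up = (t >= p.t_return + hw) & (t < p.t_return + 2 * hw)
            v[up] = -p.undershoot_depth * (p.t_return + 2 * hw - t[up]) / hw
        return v


@dataclass(frozen=True)
class EffectSpec:
    """A planted band-power modulation locked to blinks.

    ``gain_db`` is the signed power change of the band inside
    ``[onset, offset]`` (seconds relative to each blink peak), applied to the
    blinks whose (condition, urge class) cell is in ``applies_to``.  The
    modulation envelope ramps up/down with a raised cosine of ``ramp_s``
    seconds starting at ``onset`` / ending at ``offset``, mimicking a gradual
    build-up of oscillatory power.
    """

    source: str
    band: tuple[float, float]
    onset: float
    offset: float
    gain_db: float
    applies_to: frozenset = frozenset()
    ramp_s: float = 0.5

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (1.0 <= f_lo < f_hi <= 55.0):
            raise ParameterError("band must satisfy 1 <= f_lo < f_hi <= 55 Hz")
        if not self.onset < self.offset:
            raise ParameterError("effect onset must precede offset")
        if not np.isfinite(self.gain_db):
            raise ParameterError("gain_db must be finite")
        object.__setattr__(self, "applies_to", frozenset(map(tuple, self.applies_to)))


def default_effect_specs() -> tuple[EffectSpec, ...]:
    """The two planted effects: suppression theta increase (left prefrontal,
    both suppression conditions) and urge-locked delta decrease (anterior
    cingulate; high-urge blinks only without reward, both classes with
    reward)."""
    return (
        EffectSpec(
            source="left_prefrontal",
            band=(4.0, 8.0),
            onset=-1.5,
            offset=0.5,
            gain_db=3.0,
            applies_to=frozenset(
                {("Supp", "High"), ("Supp", "Low"), ("SuppRwd", "High"), ("SuppRwd", "Low")}
            ),
        ),
        EffectSpec(
            source="acc",
            band=(1.0, 4.0),
            onset=-1.0,
            offset=1.0,
            gain_db=-3.0,
            applies_to=frozenset(
                {("Supp", "High"), ("SuppRwd", "High"), ("SuppRwd", "Low")}
            ),
        ),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration for the synthetic cohort."""

    n_subjects: int = 26
    conditions: tuple = CONDITIONS
    block_duration_s: float = 330.0
    fs: float = 250.0
    blink_rates: dict = field(default_factory=lambda: dict(DEFAULT_BLINK_RATES))
    blink_refractory_s: float = 0.5
    p_urge_high: float = 0.5
    urge_kernel: UrgeKernel = field(default_factory=UrgeKernel)
    urge_gain_sd: float = 0.2
    urge_jitter_sd_s: float = 0.1
    urge_noise_sd: float = 0.1
    effect_specs: tuple = field(default_factory=default_effect_specs)
    source_labels: tuple = ("left_prefrontal", "acc", "eog")
    noise_exponent: float = 1.0
    n_channels: int = 8
    blink_amplitude: float = 8.0
    blink_wave_s: float = 0.3
    dipole_k_true: int = 12
    dipole_spread_mm: float = 8.0
    dipoles_per_cluster: int = 76

    def __post_init__(self):
        for cond, (m, sd) in self.blink_rates.items():
            if m <= 0 or sd <= 0:
                raise ParameterError(f"blink rate mean/SD for {cond} must be > 0")
        if not 0.0 <= self.p_urge_high <= 1.0:
            raise ParameterError("p_urge_high must be in [0, 1]")
        if self.fs < 4 * 55.0:
            raise ParameterError("fs must be at least 4 x 55 Hz")
        for spec in self.effect_specs:
            if spec.source not in self.source_labels:
                raise ParameterError(f"effect source {spec.source!r} not in source_labels")

    @property
    def n_samples(self) -> int:
        return int(round(self.block_duration_s * self.fs))


@dataclass
class SessionRecording:
    """Source activations plus mixing and events for one subject x condition."""

    sources: np.ndarray          # (n_sources, n_samples)
    source_labels: tuple
    mixing: np.ndarray           # (n_channels, n_sources)
    fs: float
    subject: int
    condition: str
    events: pd.DataFrame         # onset, duration, trial_type, condition, urge_class
    urge: np.ndarray | None      # urgeometer trace, absent iff condition == NoSupp

    def source(self, label: str) -> np.ndarray:
        return self.sources[self.source_labels.index(label)]

    @property
    def channels(self) -> np.ndarray:
        return self.mixing @ self.sources


@dataclass
class SessionTruth:
    """Planted ground truth for one session."""

    blink_latencies_s: np.ndarray
    urge_class: list            # one entry per blink; None in NoSupp
    rate_per_min: float
    effects: list               # EffectSpec applied in this session


@dataclass
class DipoleSet:
    """Equivalent-dipole coordinates (mm) with a subject id per IC."""

    coordinates: np.ndarray     # (n_ics, 3)
    subject: np.ndarray         # (n_ics,)

    def __post_init__(self):
        if not np.all(np.isfinite(self.coordinates)):
            raise ParameterError("dipole coordinates must be finite")


@dataclass
class Cohort:
    config: CohortConfig
    sessions: dict              # (subject, condition) -> SessionRecording
    truth: dict                 # (subject, condition) -> SessionTruth
    dipoles: DipoleSet
    dipole_labels: np.ndarray   # true cluster id per IC
    subject_rates: dict         # (subject, condition) -> planted rate/min


# ---------------------------------------------------------------------------
# Elementary simulators
# ---------------------------------------------------------------------------


def default_t_grid(fs: float = 250.0, t_min: float = -5.5, t_max: float = 2.5) -> np.ndarray:
    """Epoch time grid at 1/fs steps, containing exactly 0."""
    return np.arange(round(t_min * fs), round(t_max * fs) + 1) / fs


def make_urge_kernel(params: UrgeKernel, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the urge kernel on a uniform time grid.

    Optionally convolves with a Gaussian of ``smoothing_width`` seconds and
    clips the result to ``[-undershoot_depth, 1]``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    dt = np.diff(t_grid)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(dt <= 0):
        raise ParameterError("t_grid must be a strictly increasing 1-D vector")
    v = params(t_grid)
    if params.smoothing_width > 0:
        if not np.allclose(dt, dt[0]):
            raise ParameterError("smoothing requires a uniform t_grid")
        sigma = params.smoothing_width / dt[0]
        v = ndimage.gaussian_filter1d(v, sigma, mode="nearest")
    return np.clip(v, -params.undershoot_depth, 1.0)


def simulate_urge_trials(
    kernel: UrgeKernel,
    n_trials: int,
    p_high: float = 0.5,
    gain_sd: float = 0.2,
    jitter_sd_s: float = 0.1,
    noise_sd: float = 0.1,
    seed=None,
    t_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-trial urgeometer epochs plus true High/Low labels.

    High trials carry the kernel scaled by a positive mean-1 gamma gain and
    shifted by a Gaussian time jitter; Low trials are noise only.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if not 0.0 <= p_high <= 1.0:
        raise ParameterError("p_high must be in [0, 1]")
    rng = _as_rng(seed)
    if t_grid is None:
        t_grid = default_t_grid()
    n_t = t_grid.size
    labels = np.where(rng.random(n_trials) < p_high, "High", "Low")
    trials = np.zeros((n_trials, n_t))
    for i in range(n_trials):
        if labels[i] == "High":
            gain = 1.0
            if gain_sd > 0:
                gain = rng.gamma(1.0 / gain_sd**2, gain_sd**2)
            delta = rng.normal(0.0, jitter_sd_s) if jitter_sd_s > 0 else 0.0
            trials[i] = gain * _shifted_kernel(kernel, t_grid, delta)
        if noise_sd > 0:
            trials[i] += rng.normal(0.0, noise_sd, n_t)
    return trials, labels


def _shifted_kernel(kernel: UrgeKernel, t_grid: np.ndarray, delta: float) -> np.ndarray:
    """Kernel time-shifted by ``delta`` (positive = later), smoothed/clipped."""
    v = kernel(np.asarray(t_grid) - delta)
    if kernel.smoothing_width > 0:
        dt = t_grid[1] - t_grid[0]
        v = ndimage.gaussian_filter1d(v, kernel.smoothing_width / dt, mode="nearest")
    return np.clip(v, -kernel.undershoot_depth, 1.0)


def simulate_blink_train(
    duration_s: float,
    rate_per_min: float,
    refractory_s: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Stationary renewal blink train with an absolute refractory period.

    Inter-event gaps are ``refractory_s + Exp(mu)`` with ``mu`` chosen so the
    realized event rate equals ``rate_per_min`` exactly; the first event is
    drawn from the equilibrium forward-recurrence distribution so the expected
    count is ``duration_s * rate_per_min / 60`` without edge bias.
    """
    if rate_per_min < 0 or refractory_s < 0:
        raise ParameterError("rate and refractory must be non-negative")
    if rate_per_min == 0:
        return np.empty(0)
    mean_gap = 60.0 / rate_per_min
    if refractory_s >= mean_gap:
        raise ParameterError(
            "infeasible rate/refractory pair: rate_per_min * refractory_s / 60 must be < 1"
        )
    mu = mean_gap - refractory_s
    rng = _as_rng(seed)
    # equilibrium forward recurrence time for the delayed-exponential renewal
    if rng.random() < refractory_s / mean_gap:
        t = rng.uniform(0.0, refractory_s)
    else:
        t = refractory_s + rng.exponential(mu)
    out = []
    while t < duration_s:
        out.append(t)
        t += refractory_s + rng.exponential(mu)
    return np.asarray(out)


def one_over_f_noise(
    n_samples: int, fs: float, exponent: float = 1.0, seed=None
) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum (flat below 1 Hz)."""
    rng = _as_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    w = np.maximum(f, 1.0) ** (-exponent / 2.0)
    w[0] = 0.0
    x = np.fft.irfft(spec * w, n_samples)
    return x / x.std()


def blink_waveform(fs: float, duration_s: float = 0.3, amplitude: float = 1.0):
    """Stereotyped biphasic raised-cosine blink waveform.

    Returns ``(waveform, peak_index)``; the dominant positive lobe peaks at
    ~30% of the waveform duration so the annotated blink latency is the
    highest-amplitude moment, not the onset.
    """
    n = int(round(duration_s * fs)) + 1
    tau = np.arange(n) / fs

    def bump(center, width):
        out = np.zeros(n)
        m = np.abs(tau - center) < width / 2
        out[m] = 0.5 * (1 + np.cos(2 * np.pi * (tau[m] - center) / width))
        return out

    w = bump(0.3 * duration_s, 0.6 * duration_s) - 0.5 * bump(
        0.75 * duration_s, 0.5 * duration_s
    )
    w *= amplitude / w.max()
    return w, int(np.argmax(w))


def _band_sos(band: tuple[float, float], fs: float, btype: str):
    return signal.butter(6, band, btype=btype, fs=fs, output="sos")


def _effect_envelope_db(
    n_samples: int,
    fs: float,
    spec: EffectSpec,
    blink_latencies: np.ndarray,
    urge_class: list,
    condition: str,
) -> np.ndarray:
    """Per-sample dB gain for one effect; overlapping windows sum in dB."""
    env = np.zeros(n_samples)
    t_rel = None
    for b, cls in zip(blink_latencies, urge_class):
        if (condition, cls) not in spec.applies_to:
            continue
        i0 = int(np.floor((b + spec.onset) * fs))
        i1 = int(np.ceil((b + spec.offset) * fs))
        idx = np.arange(max(i0, 0), min(i1 + 1, n_samples))
        if idx.size == 0:
            continue
        t = idx / fs - b
        # raised-cosine ramps inside [onset, onset+ramp] and [offset-ramp, offset]
        r = np.ones_like(t)
        if spec.ramp_s > 0:
            up = t < spec.onset + spec.ramp_s
            r[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - spec.onset) / spec.ramp_s))
            down = t > spec.offset - spec.ramp_s
            r[down] = np.minimum(
                r[down], 0.5 * (1 - np.cos(np.pi * (spec.offset - t[down]) / spec.ramp_s))
            )
        env[idx] += spec.gain_db * np.clip(r, 0.0, 1.0)
    return env


def simulate_session(
    config: CohortConfig,
    subject: int,
    condition: str,
    seed=None,
    rate_per_min: float | None = None,
    mixing: np.ndarray | None = None,
) -> tuple[SessionRecording, SessionTruth]:
    """Simulate one block: 1/f sources with planted band-power effects, an EOG
    source with blink waveforms, events, and (in suppression blocks) the
    urgeometer trace."""
    if condition not in config.conditions:
        raise ParameterError(f"unknown condition {condition!r}")
    rng = _as_rng(seed)
    fs, n = config.fs, config.n_samples

    if rate_per_min is None:
        m, sd = config.blink_rates[condition]
        rate_per_min = float(rng.gamma((m / sd) ** 2, sd**2 / m))
        rate_per_min = max(rate_per_min, 60.0 * 2 / config.block_duration_s)
    blinks = simulate_blink_train(
        config.block_duration_s, rate_per_min, config.blink_refractory_s, rng
    )
    # snap to the sample grid; drop blinks whose waveform does not fit
    blinks = np.round(blinks * fs) / fs
    margin = config.blink_wave_s
    keep = (blinks > margin) & (blinks < config.block_duration_s - margin)
    if np.any(~keep):
        logger.info(
            "subject %s %s: dropped %d blink(s) too close to block edges",
            subject, condition, int(np.sum(~keep)),
        )
    blinks = blinks[keep]

    is_supp = condition != "NoSupp"
    if is_supp:
        urge_class = list(
            np.where(rng.random(blinks.size) < config.p_urge_high, "High", "Low")
        )
    else:
        urge_class = [None] * blinks.size

    wave, peak_idx = blink_waveform(fs, config.blink_wave_s, config.blink_amplitude)
    applied = []
    sources = np.empty((len(config.source_labels), n))
    for si, label in enumerate(config.source_labels):
        sig = one_over_f_noise(n, fs, config.noise_exponent, rng)
        if label == "eog":
            for b in blinks:
                i0 = int(round(b * fs)) - peak_idx
                sources_slice = slice(max(i0, 0), min(i0 + wave.size, n))
                sig[sources_slice] += wave[
                    sources_slice.start - i0 : sources_slice.stop - i0
                ]
        else:
            for spec in config.effect_specs:
                if spec.source != label:
                    continue
                env_db = _effect_envelope_db(n, fs, spec, blinks, urge_class, condition)
                if np.any(env_db != 0.0):
                    applied.append(spec)
                band = signal.sosfiltfilt(_band_sos(spec.band, fs, "bandpass"), sig)
                sig = (sig - band) + 10.0 ** (env_db / 20.0) * band
        sources[si] = sig

    urge = None
    if is_supp:
        urge = np.zeros(n)
        t_all = np.arange(n) / fs
        k = config.urge_kernel
        half_span = 6.0  # kernel support is within +-6 s of the blink
        for b, cls in zip(blinks, urge_class):
            if cls != "High":
                continue
            gain = 1.0
            if config.urge_gain_sd > 0:
                gain = rng.gamma(
                    1.0 / config.urge_gain_sd**2, config.urge_gain_sd**2
                )
            delta = (
                rng.normal(0.0, config.urge_jitter_sd_s)
                if config.urge_jitter_sd_s > 0
                else 0.0
            )
            i0 = max(int((b - half_span) * fs), 0)
            i1 = min(int((b + half_span) * fs) + 1, n)
            urge[i0:i1] += gain * _shifted_kernel(k, t_all[i0:i1] - b, delta)
        if config.urge_noise_sd > 0:
            noise = signal.sosfiltfilt(
                signal.butter(4, 10.0, btype="lowpass", fs=fs, output="sos"),
                rng.standard_normal(n),
            )
            urge += noise * (config.urge_noise_sd / noise.std())

    rows = [
        {"onset": 0.0, "duration": config.block_duration_s, "trial_type": "block_start",
         "condition": condition, "urge_class": None},
    ]
    for b, cls in zip(blinks, urge_class):
        rows.append(
            {"onset": float(b), "duration": 0.0, "trial_type": "blink_peak",
             "condition": condition, "urge_class": cls}
        )
    rows.append(
        {"onset": config.block_duration_s, "duration": 0.0, "trial_type": "block_end",
         "condition": condition, "urge_class": None}
    )
    events = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)

    if mixing is None:
        mixing = rng.standard_normal((config.n_channels, len(config.source_labels)))

    rec = SessionRecording(
        sources=sources,
        source_labels=tuple(config.source_labels),
        mixing=mixing,
        fs=fs,
        subject=subject,
        condition=condition,
        events=events,
        urge=urge,
    )
    truth = SessionTruth(
        blink_latencies_s=blinks,
        urge_class=urge_class,
        rate_per_min=rate_per_min,
        effects=applied,
    )
    return rec, truth


def sample_dipoles(
    k_true: int = 12,
    centers: np.ndarray | None = None,
    spread_mm: float = 8.0,
    n_per_cluster: int = 76,
    seed=None,
    n_subjects: int = 26,
) -> tuple[DipoleSet, np.ndarray]:
    """Isotropic Gaussian dipole clouds around ``k_true`` centres.

    Returns the dipole set (with a subject id per IC, every subject
    contributing at least one IC) and the true cluster label per IC.
    """
    if k_true < 1:
        raise ParameterError("k_true must be >= 1")
    if spread_mm <= 0:
        raise ParameterError("spread_mm must be > 0")
    if centers is None:
        centers = DEFAULT_DIPOLE_CENTERS
    centers = np.asarray(centers, dtype=float)
    if centers.shape[0] < k_true:
        raise ParameterError("fewer centers than k_true")
    rng = _as_rng(seed)
    centers = centers[:k_true]
    n = k_true * n_per_cluster
    labels = np.repeat(np.arange(k_true), n_per_cluster)
    coords = centers[labels] + rng.normal(0.0, spread_mm, (n, 3))
    subjects = rng.integers(0, n_subjects, n)
    # guarantee >= 1 IC per subject
    first = rng.permutation(n)[:n_subjects]
    subjects[first] = np.arange(n_subjects)
    return DipoleSet(coordinates=coords, subject=subjects), labels


def simulate_cohort(config: CohortConfig, seed=None) -> Cohort:
    """Full seeded cohort: all subject x condition sessions, ground truth and
    the planted dipole cloud.  Identical (config, seed) gives bit-identical
    output."""
    ss = SeedSequence(seed if isinstance(seed, int) else None) if not isinstance(seed, SeedSequence) else seed
    subj_seeds = ss.spawn(config.n_subjects)
    dip_seed = ss.spawn(1)[0]
    sessions, truth, rates = {}, {}, {}
    for subject in range(config.n_subjects):
        srng = default_rng(subj_seeds[subject])
        mixing = srng.standard_normal((config.n_channels, len(config.source_labels)))
        for condition in config.conditions:
            m, sd = config.blink_rates[condition]
            rate = float(srng.gamma((m / sd) ** 2, sd**2 / m))
            rate = max(rate, 60.0 * 2 / config.block_duration_s)
            rec, tr = simulate_session(
                config, subject, condition, srng, rate_per_min=rate, mixing=mixing
            )
            sessions[(subject, condition)] = rec
            truth[(subject, condition)] = tr
            rates[(subject, condition)] = rate
    dipoles, dipole_labels = sample_dipoles(
        k_true=config.dipole_k_true,
        spread_mm=config.dipole_spread_mm,
        n_per_cluster=config.dipoles_per_cluster,
        seed=default_rng(dip_seed),
        n_subjects=config.n_subjects,
    )
    return Cohort(
        config=config,
        sessions=sessions,
        truth=truth,
        dipoles=dipoles,
        dipole_labels=dipole_labels,
        subject_rates=rates,
    )


# ---------------------------------------------------------------------------
# External interfaces: TSV / JSON / YAML writers
# ---------------------------------------------------------------------------


def write_session_tsv(rec: SessionRecording, path, what: str = "channels") -> None:
    """Write channel data (mixing x sources) or raw sources as TSV, one column
    per channel plus the urge trace as a dedicated column when present."""
    if what == "channels":
        data = rec.channels
        names = [f"ch{i + 1:02d}" for i in range(data.shape[0])]
    elif what == "sources":
        data = rec.sources
        names = list(rec.source_labels)
    else:
        raise ParameterError("what must be 'channels' or 'sources'")
    df = pd.DataFrame(data.T, columns=names)
    if rec.urge is not None:
        df["urge"] = rec.urge
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_session_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_events_tsv(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["urge_class"] = out["urge_class"].fillna("n/a") if "urge_class" in out else "n/a"
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return ev


def write_ground_truth_json(cohort: Cohort, path) -> None:
    payload = {
        "subject_rates": {f"{s}|{c}": r for (s, c), r in cohort.subject_rates.items()},
        "sessions": {
            f"{s}|{c}": {
                "blink_latencies_s": tr.blink_latencies_s.tolist(),
                "urge_class": tr.urge_class,
                "rate_per_min": tr.rate_per_min,
                "effects": [
                    {
                        "source": e.source, "band": list(e.band), "onset": e.onset,
                        "offset": e.offset, "gain_db": e.gain_db,
                        "applies_to": sorted(map(list, e.applies_to)),
                    }
                    for e in tr.effects
                ],
            }
            for (s, c), tr in cohort.truth.items()
        },
        "dipole_labels": cohort.dipole_labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["urge_kernel"] = dataclasses.asdict(config.urge_kernel)
    d["effect_specs"] = [
        {**dataclasses.asdict(e), "applies_to": sorted(map(list, e.applies_to))}
        for e in config.effect_specs
    ]
    d["conditions"] = list(config.conditions)
    d["source_labels"] = list(config.source_labels)
    d["blink_rates"] = {k: list(v) for k, v in config.blink_rates.items()}
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "urge_kernel" in d:
        d["urge_kernel"] = UrgeKernel(**d["urge_kernel"])
    if "effect_specs" in d:
        d["effect_specs"] = tuple(
            EffectSpec(
                **{
                    **e,
                    "band": tuple(e["band"]),
                    "applies_to": frozenset(map(tuple, e["applies_to"])),
                }
            )
            for e in d["effect_specs"]
        )
    for key in ("conditions", "source_labels"):
        if key in d:
            d[key] = tuple(d[key])
    if "blink_rates" in d:
        d["blink_rates"] = {k: tuple(v) for k, v in d["blink_rates"].items()}
    return CohortConfig(**d)


def save_config_yaml(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config_yaml(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
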