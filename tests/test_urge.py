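import numpy as np
import pytest

from urgewave import (
    DegenerateInputError,
    NoOnsetError,
    ParameterError,
    UrgeKernel,
    classify_subject_trials,
    classify_trials,
    correlate_trials,
    default_t_grid,
    detect_elbow,
    detect_peak,
    detect_rise_onset,
    landmarks,
    make_urge_kernel,
    mean_urge_curve,
    simulate_urge_trials,
    smooth_curve,
    urge_duration,
)
from urgewave.exceptions import InsufficientSegmentError
from urgewave.urge import two_line_sse


def _kernel_curve(noise_sd=0.0, seed=0, kernel=None):
    kernel = kernel or UrgeKernel()
    t = default_t_grid()
    y = make_urge_kernel(kernel, t)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return (y, t)


class TestCorrelateClassify:
    def test_correlation_values(self, rng):
        m = np.sin(np.linspace(0, 4 * np.pi, 200))
        trials = np.stack([m, -m, rng.standard_normal(200)])
        r = correlate_trials(trials, m)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert abs(r[2]) < 0.5

    def test_zero_variance_trial_gets_r0(self):
        m = np.sin(np.linspace(0, np.pi, 50))
        r = correlate_trials(np.zeros((1, 50)), m)
        assert r[0] == 0.0

    def test_median_split_about_half(self, rng):
        r = rng.uniform(-1, 1, 101)
        cls = classify_trials(r, rule="median")
        n_high = int(np.sum(cls == "High"))
        assert n_high == 50  # strict > median, odd count: exactly half below

    def test_ties_go_low(self):
        cls = classify_trials(np.array([0.2, 0.2, 0.9, 0.8]), rule="median")
        assert list(cls) == ["Low", "Low", "High", "High"]

    def test_all_identical_all_low(self):
        cls = classify_trials(np.full(10, 0.3), rule="median")
        assert np.all(cls == "Low")

    def test_threshold_rule(self):
        cls = classify_trials(np.array([0.4, 0.6]), rule="threshold", threshold=0.5)
        assert list(cls) == ["Low", "High"]

    def test_recovers_true_labels(self):
        t = default_t_grid()
        trials, labels = simulate_urge_trials(
            UrgeKernel(), 120, seed=3, t_grid=t
        )
        table = classify_subject_trials(trials, np.zeros(120, dtype=int))
        acc = np.mean(table["urge_class"].to_numpy() == labels)
        assert acc > 0.9


class TestSmoothing:
    def test_constant_preserved_at_edges(self):
        y = np.full(100, 3.0)
        s = smooth_curve(y, fs=50.0, width_s=0.3)
        assert np.allclose(s, 3.0)  # coverage normalisation: no edge droop

    def test_zero_width_identity(self, rng):
        y = rng.standard_normal(50)
        assert np.array_equal(smooth_curve(y, 50.0, 0.0), y)


class TestPeak:
    def test_kernel_peak(self):
        assert detect_peak(_kernel_curve()) == pytest.approx(-0.4, abs=0.05)

    def test_tie_goes_earliest(self):
        t = np.linspace(0, 1, 101)
        y = np.zeros(101)
        y[30] = y[60] = 1.0
        assert detect_peak((y, t), smoothing_s=0.0) == pytest.approx(t[30])

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateInputError):
            detect_peak((np.ones(100), np.linspace(0, 1, 100)))


class TestElbow:
    def test_kernel_elbow(self):
        e = detect_elbow(_kernel_curve(), t_start=-5.0, t_end=-0.4)
        assert e == pytest.approx(-1.8, abs=0.1)

    def test_bisection_equals_exhaustive_on_random_curves(self, rng):
        """Property: bisection agrees with the exhaustive reference on
        100 random piecewise-linear curves with additive noise."""
        for _ in range(100):
            n = int(rng.integers(60, 300))
            t = np.linspace(0.0, 1.0, n)
            b = rng.uniform(0.2, 0.8)
            s1, s2 = rng.uniform(0.1, 1.0), rng.uniform(1.5, 5.0)
            y = np.where(t < b, s1 * t, s1 * b + s2 * (t - b))
            y = y + rng.normal(0, 0.01, n)
            e1 = detect_elbow((y, t), 0.0, 1.0, smoothing_s=0.0, method="exhaustive")
            e2 = detect_elbow((y, t), 0.0, 1.0, smoothing_s=0.0, method="bisection")
            assert e1 == e2

    def test_two_line_sse_nan_guards(self):
        x = np.linspace(0, 1, 10)
        sse = two_line_sse(x, x**2)
        assert np.isnan(sse[0]) and np.isnan(sse[1])
        assert np.isnan(sse[-1]) and np.isnan(sse[-2])

    def test_too_short_segment(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(InsufficientSegmentError):
            detect_elbow((t, t), 0.5, 0.52, smoothing_s=0.0)


class TestOnset:
    def test_kernel_onset(self):
        o = detect_rise_onset(_kernel_curve(noise_sd=0.005, seed=1))
        assert o == pytest.approx(-5.0, abs=0.15)

    def test_never_exceeds_raises(self):
        t = np.linspace(-5, 2, 500)
        y = np.random.default_rng(0).normal(0, 1, 500)
        with pytest.raises(NoOnsetError):
            detect_rise_onset((y, t), k=50.0)

    def test_explicit_baseline_window(self):
        y, t = _kernel_curve()
        o = detect_rise_onset((y, t), baseline_window=(-5.5, -5.2))
        assert o == pytest.approx(-5.0, abs=0.15)


class TestLandmarks:
    def test_kernel_landmarks_close_to_truth(self):
        lm = landmarks(_kernel_curve(noise_sd=0.005, seed=2))
        assert lm.onset == pytest.approx(-5.0, abs=0.15)
        assert lm.elbow == pytest.approx(-1.8, abs=0.15)
        assert lm.peak == pytest.approx(-0.4, abs=0.05)
        assert lm.duration == pytest.approx(7.0, abs=0.3)
        assert lm.onset < lm.elbow < lm.peak < lm.return_time

    def test_translation_equivariance(self):
        """Property: shifting the grid shifts every latency landmark by
        the same amount and leaves the duration unchanged."""
        y, t = _kernel_curve(noise_sd=0.005, seed=3)
        shift = 1.37
        a = landmarks((y, t))
        b = landmarks((y, t + shift))
        assert b.onset == pytest.approx(a.onset + shift, abs=1e-9)
        assert b.elbow == pytest.approx(a.elbow + shift, abs=1e-9)
        assert b.peak == pytest.approx(a.peak + shift, abs=1e-9)
        assert b.return_time == pytest.approx(a.return_time + shift, abs=1e-9)
        assert b.duration == pytest.approx(a.duration, abs=1e-9)

    def test_rectangular_pulse_duration(self):
        fs = 250.0
        t = np.arange(-5.5 * fs, 2.5 * fs) / fs
        y = ((t >= -4.0) & (t <= 0.0)).astype(float)
        lm = landmarks((y, t), smoothing_s=0.0)
        assert np.isnan(lm.elbow)  # no rising segment to break in two
        assert lm.duration == pytest.approx(4.0, abs=0.1)

    def test_censoring_flag(self):
        t = np.linspace(-5.5, 2.5, 2000)
        y = np.clip((t + 5.0) / 4.6, 0.0, 1.0)  # rises and never comes back
        lm = landmarks((y, t))
        assert lm.censored
        assert lm.return_time == pytest.approx(t[-1])

    def test_urge_duration_matches_landmarks(self):
        curve = _kernel_curve(noise_sd=0.005, seed=4)
        assert urge_duration(curve) == landmarks(curve).duration


class TestMeanCurve:
    def test_mean_and_sd(self, rng):
        trials = rng.standard_normal((40, 100))
        c = mean_urge_curve(trials, np.linspace(-5, 2, 100), label="High")
        assert np.allclose(c.mean, trials.mean(axis=0))
        assert np.allclose(c.sd, trials.std(axis=0))
        assert c.n_trials == 40

    def test_empty_class_degenerate(self):
        with pytest.raises(DegenerateInputError):
            mean_urge_curve(np.empty((0, 10)), np.linspace(0, 1, 10))
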