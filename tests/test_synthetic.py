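import dataclasses

import numpy as np
import pytest

from urgewave import (
    CohortConfig,
    ParameterError,
    UrgeKernel,
    blink_rate_per_minute,
    default_t_grid,
    make_urge_kernel,
    sample_dipoles,
    simulate_blink_train,
    simulate_cohort,
    simulate_urge_trials,
)
from urgewave.synthetic import (
    blink_waveform,
    config_from_dict,
    config_to_dict,
    load_config_yaml,
    one_over_f_noise,
    read_events_tsv,
    read_session_tsv,
    save_config_yaml,
    simulate_session,
    write_events_tsv,
    write_session_tsv,
)


class TestUrgeKernel:
    def test_analytic_landmark_values(self):
        k = UrgeKernel()
        t = default_t_grid()
        y = k(t)
        assert k(np.array([k.t_peak]))[0] == pytest.approx(1.0)
        assert k(np.array([k.t_elbow]))[0] == pytest.approx(k.elbow_level)
        # zero before onset, back near zero after the return time
        assert np.all(y[t < k.t_onset - 1e-9] == 0.0)
        assert abs(k(np.array([k.t_return]))[0]) <= k.undershoot_depth + 1e-12
        # strictly rising between onset and peak
        rise = y[(t > k.t_onset) & (t < k.t_peak)]
        assert np.all(np.diff(rise) > -1e-12)

    def test_slope_change_at_elbow(self):
        k = UrgeKernel()
        assert k.slope_post > k.slope_pre > 0

    def test_grid_evaluation_matches_call(self):
        k = UrgeKernel()
        t = default_t_grid()
        assert np.allclose(make_urge_kernel(k, t), np.clip(k(t), -k.undershoot_depth, 1.0))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ParameterError):
            UrgeKernel(t_onset=-1.0, t_elbow=-2.0)


class TestBlinkTrain:
    def test_realized_rate_is_unbiased(self):
        rng = np.random.default_rng(7)
        dur, rate = 330.0, 12.0
        counts = [
            len(simulate_blink_train(dur, rate, 0.5, rng)) for _ in range(800)
        ]
        expected = dur * rate / 60.0
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_refractory_respected(self):
        t = simulate_blink_train(600.0, 20.0, 0.5, 3)
        assert np.all(np.diff(t) >= 0.5)

    def test_zero_rate(self):
        assert simulate_blink_train(100.0, 0.0, 0.5, 0).size == 0

    def test_infeasible_rate(self):
        with pytest.raises(ParameterError):
            simulate_blink_train(100.0, 200.0, 0.5, 0)


class TestUrgeTrials:
    def test_labels_and_shapes(self):
        t = default_t_grid()
        trials, labels = simulate_urge_trials(UrgeKernel(), 64, seed=5, t_grid=t)
        assert trials.shape == (64, t.size)
        assert set(labels) <= {"High", "Low"}

    def test_low_trials_are_noise_only(self):
        t = default_t_grid()
        trials, labels = simulate_urge_trials(
            UrgeKernel(), 200, noise_sd=0.0, seed=5, t_grid=t
        )
        low = trials[labels == "Low"]
        assert np.all(low == 0.0)

    def test_high_trials_track_kernel(self):
        t = default_t_grid()
        trials, labels = simulate_urge_trials(
            UrgeKernel(), 400, gain_sd=0.0, jitter_sd_s=0.0, noise_sd=0.0,
            seed=6, t_grid=t,
        )
        high = trials[labels == "High"]
        assert np.allclose(high, make_urge_kernel(UrgeKernel(), t))


class TestNoiseAndWaveform:
    def test_one_over_f_slope(self):
        fs = 250.0
        x = one_over_f_noise(2**16, fs, exponent=1.0, seed=2)
        f, p = np.fft.rfftfreq(x.size, 1 / fs), np.abs(np.fft.rfft(x)) ** 2
        m = (f > 2) & (f < 50)
        slope = np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)
        assert x.std() == pytest.approx(1.0)

    def test_blink_waveform_peak(self):
        w, peak = blink_waveform(250.0, 0.3, 5.0)
        assert w[peak] == pytest.approx(5.0)
        assert peak == np.argmax(w)
        assert w.min() < 0  # biphasic


class TestSession:
    def test_planted_effect_gain_in_band(self, small_config):
        """Planted +3 dB theta burst raises 4-8 Hz power around blinks."""
        cfg = small_config
        rec, truth = simulate_session(cfg, 0, "Supp", seed=9, rate_per_min=12.0)
        from scipy import signal as sps

        sig = rec.source("left_prefrontal")
        sos = sps.butter(6, (4, 8), btype="bandpass", fs=cfg.fs, output="sos")
        band = sps.sosfiltfilt(sos, sig)
        lat = truth.blink_latencies_s
        lat = lat[(lat > 3) & (lat < cfg.block_duration_s - 3)]
        idx = (lat[:, None] * cfg.fs).astype(int) + np.arange(
            int(-1.0 * cfg.fs), int(0.4 * cfg.fs)
        )
        far = band.copy()
        p_near = np.mean(band[idx] ** 2)
        p_all = np.mean(far**2)
        assert p_near > 1.3 * p_all

    def test_blink_latency_is_positive_peak(self, small_config):
        cfg = small_config
        rec, truth = simulate_session(cfg, 0, "NoSupp", seed=3, rate_per_min=15.0)
        eog = rec.source("eog")
        w = int(0.1 * cfg.fs)
        for lat in truth.blink_latencies_s[:10]:
            i = int(round(lat * cfg.fs))
            seg = eog[i - w: i + w + 1]
            # annotated latency sits within 40 ms of the noisy local maximum
            assert abs(int(np.argmax(seg)) - w) <= int(0.04 * cfg.fs)
            assert eog[i] > 4.0  # blink dominates the unit-variance background

    def test_determinism(self, small_config):
        a, _ = simulate_session(small_config, 1, "Supp", seed=42, rate_per_min=10.0)
        b, _ = simulate_session(small_config, 1, "Supp", seed=42, rate_per_min=10.0)
        assert np.array_equal(a.channels, b.channels)
        assert a.events.equals(b.events)


class TestCohort:
    def test_structure_and_determinism(self, small_config):
        c1 = simulate_cohort(small_config, 11)
        c2 = simulate_cohort(small_config, 11)
        assert len(c1.sessions) == small_config.n_subjects * 3
        k = (0, "NoSupp")
        assert np.array_equal(c1.sessions[k].channels, c2.sessions[k].channels)
        assert np.array_equal(c1.dipoles.coordinates, c2.dipoles.coordinates)

    def test_rate_ordering_in_truth(self):
        cfg = dataclasses.replace(CohortConfig(), n_subjects=20)
        cfg = dataclasses.replace(cfg, effect_specs=(), source_labels=("eog",))
        cohort = simulate_cohort(cfg, 5)
        means = {
            c: np.mean([
                blink_rate_per_minute(
                    cohort.truth[(s, c)].blink_latencies_s, cfg.block_duration_s
                )
                for s in range(cfg.n_subjects)
            ])
            for c in ("NoSupp", "Supp", "SuppRwd")
        }
        assert means["NoSupp"] > means["Supp"] > means["SuppRwd"]


class TestDipoles:
    def test_counts_and_spread(self):
        dip, labels = sample_dipoles(k_true=5, spread_mm=6.0, n_per_cluster=30, seed=1)
        assert dip.coordinates.shape == (150, 3)
        assert len(np.unique(labels)) == 5
        for c in range(5):
            sd = dip.coordinates[labels == c].std(axis=0).mean()
            assert 3.0 < sd < 9.0

    def test_every_subject_contributes(self):
        dip, _ = sample_dipoles(seed=2, n_subjects=26)
        assert set(np.unique(dip.subject)) == set(range(26))


class TestIO:
    def test_session_and_events_roundtrip(self, small_config, tmp_path):
        rec, _ = simulate_session(small_config, 0, "Supp", seed=1, rate_per_min=10.0)
        write_session_tsv(rec, tmp_path / "s.tsv", what="sources")
        df = read_session_tsv(tmp_path / "s.tsv")
        assert set(small_config.source_labels) <= set(df.columns)
        assert len(df) == small_config.n_samples
        write_events_tsv(rec.events, tmp_path / "e.tsv")
        ev = read_events_tsv(tmp_path / "e.tsv")
        assert (ev["trial_type"] == "blink_peak").sum() == (
            rec.events["trial_type"] == "blink_peak"
        ).sum()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig()
        save_config_yaml(cfg, tmp_path / "c.yaml")
        back = load_config_yaml(tmp_path / "c.yaml")
        assert back == cfg
        assert config_from_dict(config_to_dict(cfg)) == cfg
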