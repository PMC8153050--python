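"""Parameter-recovery benchmarks on the default synthetic cohort.

Each function regenerates the relevant synthetic data from a seed, runs the
corresponding slice of the analysis pipeline, and returns the recovered
quantity: condition-mean blink rates, urge time-course landmarks, the
earliest latencies of the significant time-frequency clusters, and the
silhouette-optimal dipole cluster count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.random import SeedSequence

from . import cluster_stats, urge
from .ersp import ERSPConfig
from .ic_clustering import select_k
from .pipeline import _aligned, _subject_ersp, behavioral_stage, urge_stage
from .preprocess import paired_ttests_bonferroni
from .synthetic import (
    CohortConfig,
    default_t_grid,
    sample_dipoles,
    simulate_blink_train,
    simulate_cohort,
    simulate_urge_trials,
)


def _spawn_ints(seed, n):
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _rate_config(config: CohortConfig) -> CohortConfig:
    """Config stripped to the EOG source: blink-rate recovery does not need
    the oscillatory sources or dipoles."""
    return dataclasses.replace(config, effect_specs=(), source_labels=("eog",))


def recover_blink_rates(
    seed, n_replicates: int = 5, config: CohortConfig | None = None
) -> dict:
    """Detect blinks on simulated EOG and recover condition-mean rates/min.

    Averages the across-subject mean over ``n_replicates`` independent
    cohorts to reduce Monte-Carlo error in the group mean; also returns the
    Bonferroni-corrected paired t-tests of the last replicate.
    """
    config = _rate_config(config or CohortConfig())
    seeds = _spawn_ints(seed, n_replicates)
    means = {c: [] for c in config.conditions}
    ttests = None
    for s in seeds:
        cohort = simulate_cohort(config, s)
        beh = behavioral_stage(cohort)
        for c in config.conditions:
            means[c].append(float(beh["rates"][c].mean()))
        ttests = paired_ttests_bonferroni(beh["rates"])
    return {
        "mean_rates": {c: float(np.mean(v)) for c, v in means.items()},
        "per_replicate": means,
        "ttests": ttests,
        "n_subjects": config.n_subjects,
    }


def recover_urge_landmarks(
    seed, n_seeds: int = 20, config: CohortConfig | None = None
) -> dict:
    """Simulate cohort urge trials, classify High/Low per subject, and read
    the landmarks off the grand-mean Urge High curve; medians over seeds.

    Per subject the trial count is the number of suppression-failure blinks
    in the two suppression blocks (rates drawn as in the cohort generator).
    """
    config = config or CohortConfig()
    t_grid = default_t_grid(config.fs)
    out = {k: [] for k in ("onset", "elbow", "peak", "duration")}
    for s in _spawn_ints(seed, n_seeds):
        rng = np.random.default_rng(s)
        trials_all, subjects = [], []
        for subject in range(config.n_subjects):
            n_trials = 0
            for condition in ("Supp", "SuppRwd"):
                m, sd = config.blink_rates[condition]
                rate = float(rng.gamma((m / sd) ** 2, sd**2 / m))
                n_trials += len(
                    simulate_blink_train(
                        config.block_duration_s, rate, config.blink_refractory_s, rng
                    )
                )
            n_trials = max(n_trials, 2)
            trials, _ = simulate_urge_trials(
                config.urge_kernel,
                n_trials,
                config.p_urge_high,
                config.urge_gain_sd,
                config.urge_jitter_sd_s,
                config.urge_noise_sd,
                rng,
                t_grid,
            )
            trials_all.append(trials)
            subjects.extend([subject] * n_trials)
        trials_all = np.concatenate(trials_all, axis=0)
        table = urge.classify_subject_trials(trials_all, np.asarray(subjects))
        high = trials_all[table["urge_class"].to_numpy() == "High"]
        curve = urge.mean_urge_curve(high, t_grid, label="High")
        lm = urge.landmarks(curve)
        out["onset"].append(lm.onset)
        out["elbow"].append(lm.elbow)
        out["peak"].append(lm.peak)
        out["duration"].append(lm.duration)
    return {
        "median": {k: float(np.median(v)) for k, v in out.items()},
        "per_seed": out,
        "n_subjects": config.n_subjects,
    }


def _earliest_in_band(clusters, freqs, times, band):
    """Earliest latency of the largest significant cluster's pixels inside a
    frequency band; None when no significant cluster touches the band."""
    fband = (freqs >= band[0]) & (freqs <= band[1])
    for c in clusters:  # clusters are sorted by decreasing mass
        fi, ti = c.pixels
        inband = fband[fi]
        if np.any(inband):
            return float(times[ti[inband].min()])
    return None


def recover_effect_clusters(
    seed,
    n_perm: int = 500,
    config: CohortConfig | None = None,
    ersp_config: ERSPConfig = ERSPConfig(),
) -> dict:
    """Full planted-cohort wFWER recovery of both localisation targets.

    Suppression contrast: left-prefrontal ERSP across the three conditions,
    repeated-measures ANOVA, pixel p < 0.001, 99.9th null percentile; the
    recovered quantity is the earliest latency of the significant cluster's
    pixels inside 4-8 Hz.  Urge contrast: anterior-cingulate ERSP split by
    the *recovered* urge class in the no-reward suppression condition, paired
    t, pixel p < 0.005, 99.5th percentile; the recovered quantity is the
    pre-blink lead time (minus the earliest in-band latency) inside 1-4 Hz.
    """
    config = config or CohortConfig()
    sim_seed, perm_seed_a, perm_seed_b = _spawn_ints(seed, 3)
    cohort = simulate_cohort(config, sim_seed)
    beh = behavioral_stage(cohort)
    included = beh["included"]
    freqs, times = ersp_config.freqs, ersp_config.out_times
    out = {"n_subjects_included": len(included)}

    # --- suppression main effect on the left prefrontal source -------------
    lp = {
        c: _subject_ersp(cohort, beh["detected"], included, "left_prefrontal", c, ersp_config)
        for c in config.conditions
    }
    subjects, arrs = _aligned(lp)
    levels = [arrs[c] for c in config.conditions]
    fmap = cluster_stats.rm_anova_map(levels)
    null = cluster_stats.permutation_null(
        levels, "rm", 0.001, n_perm, perm_seed_a, connectivity=4
    )
    sig = cluster_stats.wfwer_test(fmap, null, 99.9)
    out["suppression_n_units"] = len(subjects)
    out["suppression_n_clusters"] = len(sig)
    out["suppression_earliest_latency_s"] = _earliest_in_band(
        sig, freqs, times, (4.0, 8.0)
    )

    # --- urge main effect on the anterior cingulate source -----------------
    urge_result = urge_stage(cohort, beh["detected"], included)
    classes = urge_result["trial_table"]
    acc = {
        cls: _subject_ersp(
            cohort, beh["detected"], included, "acc", "Supp", ersp_config,
            classes=classes, urge_class=cls,
        )
        for cls in ("High", "Low")
    }
    subjects_u, arrs_u = _aligned(acc)
    tmap = cluster_stats.paired_t_map(arrs_u["High"], arrs_u["Low"])
    null_u = cluster_stats.permutation_null(
        (arrs_u["High"], arrs_u["Low"]), "paired", 0.005, n_perm, perm_seed_b,
        connectivity=4,
    )
    sig_u = cluster_stats.wfwer_test(tmap, null_u, 99.5)
    earliest = _earliest_in_band(sig_u, freqs, times, (1.0, 4.0))
    out["urge_n_units"] = len(subjects_u)
    out["urge_n_clusters"] = len(sig_u)
    out["urge_earliest_latency_s"] = earliest
    out["urge_lead_time_s"] = None if earliest is None else -earliest
    out["urge_high_fraction"] = urge_result["high_fraction"]
    return out


def recover_dipole_k(seed, config: CohortConfig | None = None, n_restarts: int = 50) -> dict:
    """Silhouette-optimal cluster count on the default planted dipole cloud."""
    config = config or CohortConfig()
    dip_seed, sel_seed = _spawn_ints(seed, 2)
    dipoles, _ = sample_dipoles(
        k_true=config.dipole_k_true,
        spread_mm=config.dipole_spread_mm,
        n_per_cluster=config.dipoles_per_cluster,
        seed=dip_seed,
        n_subjects=config.n_subjects,
    )
    sel = select_k(dipoles, range(2, 21), n_restarts, sel_seed)
    return {
        "best": sel.best,
        "no_optimum": sel.no_optimum,
        "n_ics": dipoles.coordinates.shape[0],
    }
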