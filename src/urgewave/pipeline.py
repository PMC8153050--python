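"""End-to-end orchestration: simulate -> preprocess -> urge -> ersp ->
stats -> ic-clustering, with a machine-readable report and ground-truth
scoring.

The three statistical contrasts mirror the factorial design: a 3-level
repeated-measures main effect of Suppression on the left-prefrontal source
(pixel p < 0.001, 99.9th null percentile), a paired-t main effect of Urge on
the anterior-cingulate source over the two suppression conditions (pixel
p < 0.005, 99.5th percentile), and the 2x2 Urge x Reward interaction on the
same source (pixel p < 0.001, 99.9th percentile).  All randomness flows from
one master seed via named substreams per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_stats, ic_clustering, urge
from .ersp import ERSPConfig, ERSPTensor, compute_ersp
from .exceptions import EmptyEpochSetError, UrgewaveError
from .preprocess import (
    MIN_BLINKS,
    apply_inclusion_rule,
    blink_rate_per_minute,
    detect_blinks,
    epoch,
    paired_ttests_bonferroni,
)
from .synthetic import Cohort, CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

#: Contrast definitions: design, pixel threshold, null percentile.
CONTRASTS = {
    "suppression": {"design": "rm", "alpha_pixel": 0.001, "percentile": 99.9},
    "urge": {"design": "paired", "alpha_pixel": 0.005, "percentile": 99.5},
    "urge-x-reward": {"design": "interaction", "alpha_pixel": 0.001, "percentile": 99.9},
}
#: Source analysed per contrast.
CONTRAST_SOURCE = {
    "suppression": "left_prefrontal",
    "urge": "acc",
    "urge-x-reward": "acc",
}


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    seed: int | None
    behavioral: dict = field(default_factory=dict)
    urge: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)
    ic_clusters: dict = field(default_factory=dict)
    truth_validation: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def behavioral_stage(cohort: Cohort) -> dict:
    """Detect blinks on the EOG source of every session, normalise to rates,
    run the Bonferroni-corrected paired t-tests, apply the minimum-blink
    inclusion rule."""
    cfg = cohort.config
    detected, rate_rows, count_rows = {}, [], []
    for subject in range(cfg.n_subjects):
        rrow, crow = {"subject": subject}, {"subject": subject}
        for condition in cfg.conditions:
            rec = cohort.sessions[(subject, condition)]
            lat = detect_blinks(rec.source("eog"), cfg.fs)
            detected[(subject, condition)] = lat
            rrow[condition] = blink_rate_per_minute(lat, cfg.block_duration_s)
            crow[condition] = len(lat)
        rate_rows.append(rrow)
        count_rows.append(crow)
    rates = pd.DataFrame(rate_rows).set_index("subject")
    counts = pd.DataFrame(count_rows).set_index("subject")
    ttests = paired_ttests_bonferroni(rates)
    included = apply_inclusion_rule(counts, MIN_BLINKS)
    return {
        "rates": rates,
        "counts": counts,
        "ttests": ttests,
        "detected": detected,
        "included": included,
    }


def urge_stage(cohort: Cohort, detected: dict, included: list) -> dict:
    """Epoch the urgeometer trace around detected blinks (both suppression
    conditions pooled), classify trials per subject, average the classes and
    extract the High-curve landmarks."""
    cfg = cohort.config
    trials, meta_rows = [], []
    times = None
    epoch_sets = {}
    for subject in included:
        for condition in ("Supp", "SuppRwd"):
            rec = cohort.sessions[(subject, condition)]
            lat = detected[(subject, condition)]
            if len(lat) == 0:
                continue
            es = epoch(rec.urge, cfg.fs, lat)
            epoch_sets[(subject, condition)] = es
            times = es.times
            trials.append(es.data)
            for onset in es.metadata["onset"]:
                meta_rows.append(
                    {"subject": subject, "condition": condition, "onset": onset}
                )
    if not trials:
        raise EmptyEpochSetError(
            "no included subject has detected suppression-condition blinks"
        )
    trials = np.concatenate(trials, axis=0)
    meta = pd.DataFrame(meta_rows)
    table = urge.classify_subject_trials(trials, meta["subject"].to_numpy())
    meta["r"] = table["r"].to_numpy()
    meta["urge_class"] = table["urge_class"].to_numpy()

    curves, lm = {}, None
    for cls in ("High", "Low"):
        sel = meta["urge_class"].to_numpy() == cls
        if np.any(sel):
            curves[cls] = urge.mean_urge_curve(trials[sel], times, label=cls)
    if "High" in curves:
        lm = urge.landmarks(curves["High"])
    return {
        "trial_table": meta,
        "curves": curves,
        "landmarks": lm,
        "high_fraction": float((meta["urge_class"] == "High").mean()),
        "times": times,
        "epoch_sets": epoch_sets,
    }


def _subject_ersp(
    cohort: Cohort,
    detected: dict,
    subjects: list,
    source: str,
    condition: str,
    ersp_config: ERSPConfig,
    classes: pd.DataFrame | None = None,
    urge_class: str | None = None,
) -> ERSPTensor | None:
    """Per-subject ERSP of one source in one condition (optionally restricted
    to one recovered urge class)."""
    cfg = cohort.config
    data, meta = [], []
    for subject in subjects:
        rec = cohort.sessions[(subject, condition)]
        lat = np.asarray(detected[(subject, condition)])
        if urge_class is not None:
            sub = classes[
                (classes["subject"] == subject) & (classes["condition"] == condition)
            ]
            keep = sub.loc[sub["urge_class"] == urge_class, "onset"].to_numpy()
            lat = keep
        if len(lat) == 0:
            continue
        es = epoch(rec.source(source), cfg.fs, lat)
        data.append(es.data)
        meta.extend(
            {"subject": subject, "condition": condition, "urge_class": urge_class}
            for _ in range(es.n_epochs)
        )
        times = es.times
    if not data:
        return None
    from .preprocess import EpochSet

    es_all = EpochSet(
        data=np.concatenate(data, axis=0),
        times=times,
        fs=cfg.fs,
        metadata=pd.DataFrame(meta),
    )
    return compute_ersp(es_all, ersp_config, unit_col="subject")


def _aligned(tensors: dict) -> tuple:
    """Intersect subjects across tensors; return (subjects, {key: array})."""
    keys = list(tensors)
    subj_sets = [set(t.units["subject"]) for t in tensors.values()]
    common = sorted(set.intersection(*subj_sets))
    out = {}
    for k in keys:
        t = tensors[k]
        order = [list(t.units["subject"]).index(s) for s in common]
        out[k] = t.unit_array[order]
    return common, out


def ersp_stage(
    cohort: Cohort,
    detected: dict,
    classes: pd.DataFrame,
    included: list,
    ersp_config: ERSPConfig = ERSPConfig(),
) -> dict:
    """All per-subject ERSP tensors needed by the three contrasts."""
    tensors = {}
    for condition in cohort.config.conditions:
        tensors[("left_prefrontal", condition, None)] = _subject_ersp(
            cohort, detected, included, "left_prefrontal", condition, ersp_config
        )
    for condition in ("Supp", "SuppRwd"):
        for cls in ("High", "Low"):
            tensors[("acc", condition, cls)] = _subject_ersp(
                cohort, detected, included, "acc", condition, ersp_config,
                classes=classes, urge_class=cls,
            )
    return {k: v for k, v in tensors.items() if v is not None}


def stats_stage(
    tensors: dict,
    seed=None,
    n_perm: int = 1000,
    connectivity: int = 4,
    ersp_config: ERSPConfig = ERSPConfig(),
) -> dict:
    """Run the three contrasts through map -> threshold -> cluster -> wFWER."""
    rng = np.random.SeedSequence(seed if isinstance(seed, (int, np.integer)) else None)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(CONTRASTS, rng.spawn(len(CONTRASTS)))}
    freqs, times = ersp_config.freqs, ersp_config.out_times
    results = {}

    # Contrast 1: main effect Suppression (left prefrontal, 3 levels)
    lp = {c: tensors.get(("left_prefrontal", c, None)) for c in ("NoSupp", "Supp", "SuppRwd")}
    if all(v is not None for v in lp.values()):
        subjects, arrs = _aligned(lp)
        levels = [arrs[c] for c in ("NoSupp", "Supp", "SuppRwd")]
        results["suppression"] = _one_contrast(
            "suppression", cluster_stats.rm_anova_map(levels), levels,
            seeds["suppression"], n_perm, connectivity, freqs, times, len(subjects),
        )

    # Contrasts 2 & 3 need the full 2 x 2 of (reward x urge class) on acc
    acc = {
        (cond, cls): tensors.get(("acc", cond, cls))
        for cond in ("Supp", "SuppRwd")
        for cls in ("High", "Low")
    }
    if all(v is not None for v in acc.values()):
        subjects, arrs = _aligned(acc)
        high = 0.5 * (arrs[("Supp", "High")] + arrs[("SuppRwd", "High")])
        low = 0.5 * (arrs[("Supp", "Low")] + arrs[("SuppRwd", "Low")])
        results["urge"] = _one_contrast(
            "urge", cluster_stats.paired_t_map(high, low), (high, low),
            seeds["urge"], n_perm, connectivity, freqs, times, len(subjects),
        )
        cells = [
            [arrs[("Supp", "High")], arrs[("Supp", "Low")]],
            [arrs[("SuppRwd", "High")], arrs[("SuppRwd", "Low")]],
        ]
        results["urge-x-reward"] = _one_contrast(
            "urge-x-reward", cluster_stats.interaction_map(cells), cells,
            seeds["urge-x-reward"], n_perm, connectivity, freqs, times, len(subjects),
        )
    return results


def _one_contrast(name, stat_map, data, seed, n_perm, connectivity, freqs, times, n_units):
    spec = CONTRASTS[name]
    null = cluster_stats.permutation_null(
        data, spec["design"], spec["alpha_pixel"], n_perm, seed, connectivity
    )
    significant = cluster_stats.wfwer_test(stat_map, null, spec["percentile"])
    for c in significant:
        c.annotate(freqs, times)
    return {
        "map": stat_map,
        "null": null,
        "clusters": significant,
        "n_units": n_units,
        "threshold_mass": null.threshold(spec["percentile"]),
    }


def cluster_table(contrast_result: dict) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(contrast_result["clusters"]):
        rows.append(
            {
                "cluster": i,
                "mass": c.mass,
                "p_corrected": c.p_corrected,
                "n_pixels": c.size,
                "f_lo": c.freq_range[0],
                "f_hi": c.freq_range[1],
                "t_min": c.time_range[0],
                "t_max": c.time_range[1],
                "earliest_latency": c.earliest_time,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "mass", "p_corrected", "n_pixels",
            "f_lo", "f_hi", "t_min", "t_max", "earliest_latency",
        ],
    )


# ---------------------------------------------------------------------------
# Ground-truth scoring
# ---------------------------------------------------------------------------


def match_events(
    detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.1
) -> tuple:
    """Greedy one-to-one matching; returns (recall, precision, matched pairs)."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    used = np.zeros(truth.size, dtype=bool)
    pairs = []
    for i, d in enumerate(detected):
        if truth.size == 0:
            break
        j = int(np.argmin(np.abs(truth - d)))
        if not used[j] and abs(truth[j] - d) <= tol_s:
            used[j] = True
            pairs.append((i, j))
    recall = len(pairs) / truth.size if truth.size else 1.0
    precision = len(pairs) / detected.size if detected.size else 1.0
    return recall, precision, pairs


def validate_against_truth(
    report: RunReport, cohort: Cohort, behavioral: dict, urge_result: dict
) -> dict:
    """Recovery errors vs the planted ground truth: blink detection
    recall/precision, urge-label accuracy, landmark errors, time-frequency
    IoU of the suppression cluster vs the planted effect window, k recovery."""
    cfg = cohort.config
    recalls, precisions = [], []
    correct = total = 0
    for (subject, condition), lat in behavioral["detected"].items():
        tr = cohort.truth[(subject, condition)]
        r, p, pairs = match_events(lat, tr.blink_latencies_s)
        recalls.append(r)
        precisions.append(p)
        if condition == "NoSupp":
            continue
        sub = urge_result["trial_table"]
        sub = sub[(sub["subject"] == subject) & (sub["condition"] == condition)]
        if sub.empty:
            continue
        onset_to_class = dict(zip(sub["onset"], sub["urge_class"]))
        for i, j in pairs:
            cls = onset_to_class.get(lat[i])
            if cls is not None:
                total += 1
                correct += int(cls == tr.urge_class[j])
    out = {
        "detection_recall": float(np.mean(recalls)),
        "detection_precision": float(np.mean(precisions)),
        "urge_accuracy": (correct / total) if total else None,
    }
    lm = urge_result.get("landmarks")
    k = cfg.urge_kernel
    if lm is not None:
        out["landmark_abs_error"] = {
            "onset": abs(lm.onset - k.t_onset),
            "elbow": abs(lm.elbow - k.t_elbow),
            "peak": abs(lm.peak - k.t_peak),
            "duration": abs(lm.duration - (k.t_return - k.t_onset)),
        }
    supp = report.contrasts.get("suppression")
    theta = next((e for e in cfg.effect_specs if e.source == "left_prefrontal"), None)
    if supp and supp["clusters"] and theta is not None:
        ecfg = ERSPConfig()
        freqs, times = ecfg.freqs, ecfg.out_times
        planted = np.zeros((freqs.size, times.size), dtype=bool)
        planted[
            np.ix_(
                (freqs >= theta.band[0]) & (freqs <= theta.band[1]),
                (times >= theta.onset) & (times <= theta.offset),
            )
        ] = True
        detected_mask = np.zeros_like(planted)
        for c in supp["clusters"]:
            detected_mask[c["pixels"][0], c["pixels"][1]] = True
        inter = np.sum(planted & detected_mask)
        union = np.sum(planted | detected_mask)
        out["suppression_cluster_iou"] = float(inter / union) if union else 0.0
    if report.ic_clusters:
        out["k_recovered"] = (
            report.ic_clusters["best"].get("silhouette") == cfg.dipole_k_true
        )
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    config: CohortConfig,
    seed: int | None = None,
    out_dir=None,
    n_perm: int = 1000,
    k_range=range(2, 21),
    n_restarts: int = 50,
    ersp_config: ERSPConfig = ERSPConfig(),
    validate: bool = True,
) -> RunReport:
    """Execute all stages in order and return (and optionally write) the
    report.  Idempotent under a fixed (config, seed)."""
    from .synthetic import config_to_dict

    master = np.random.SeedSequence(seed)
    sim_seed, stats_seed, ic_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(3)
    )
    report = RunReport(config=config_to_dict(config), seed=seed)

    cohort = simulate_cohort(config, sim_seed)
    beh = behavioral_stage(cohort)
    report.behavioral = {
        "mean_rates": {c: float(beh["rates"][c].mean()) for c in config.conditions},
        "sd_rates": {c: float(beh["rates"][c].std(ddof=1)) for c in config.conditions},
        "ttests": beh["ttests"].to_dict(orient="records"),
        "n_subjects_included": len(beh["included"]),
    }

    urge_result = urge_stage(cohort, beh["detected"], beh["included"])
    lm = urge_result["landmarks"]
    report.urge = {
        "high_fraction": urge_result["high_fraction"],
        "n_trials": {
            cls: int((urge_result["trial_table"]["urge_class"] == cls).sum())
            for cls in ("High", "Low")
        },
        "landmarks": dataclasses.asdict(lm) if lm is not None else None,
    }

    tensors = ersp_stage(
        cohort, beh["detected"], urge_result["trial_table"], beh["included"], ersp_config
    )
    stats_res = stats_stage(tensors, stats_seed, n_perm, ersp_config=ersp_config)
    report.contrasts = {
        name: {
            "n_units": res["n_units"],
            "threshold_mass": res["threshold_mass"],
            "clusters": [
                {
                    "mass": c.mass,
                    "p_corrected": c.p_corrected,
                    "n_pixels": c.size,
                    "freq_range": c.freq_range,
                    "time_range": c.time_range,
                    "earliest_latency": c.earliest_time,
                    "pixels": (c.pixels[0].tolist(), c.pixels[1].tolist()),
                }
                for c in res["clusters"]
            ],
        }
        for name, res in stats_res.items()
    }

    sel = ic_clustering.select_k(cohort.dipoles, k_range, n_restarts, ic_seed)
    report.ic_clusters = {
        "best": sel.best,
        "no_optimum": sel.no_optimum,
        "scores": sel.table.to_dict(orient="records"),
    }

    if validate:
        report.truth_validation = validate_against_truth(
            report, cohort, beh, urge_result
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        beh["rates"].to_csv(out / "blink_rates.tsv", sep="\t")
        beh["ttests"].to_csv(out / "blink_rate_ttests.tsv", sep="\t", index=False)
        urge_result["trial_table"].to_csv(out / "urge_trials.tsv", sep="\t", index=False)
        with open(out / "urge_landmarks.json", "w") as fh:
            json.dump(report.urge, fh, indent=1, default=_jsonable)
        for name, res in stats_res.items():
            cluster_table(res).to_csv(
                out / f"clusters_{name}.tsv", sep="\t", index=False
            )
        sel.table.to_csv(out / "ic_k_selection.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
        report.provenance = {
            "blink_rates": "blink_rates.tsv (behavioral_stage: detect_blinks + blink_rate_per_minute)",
            "ttests": "blink_rate_ttests.tsv (paired_ttests_bonferroni)",
            "urge": "urge_trials.tsv, urge_landmarks.json (urge_stage)",
            "contrasts": "clusters_<contrast>.tsv (ersp_stage + stats_stage)",
            "ic_clusters": "ic_k_selection.tsv (select_k)",
            "report": "report.json (run_pipeline)",
        }
        report.to_json(out / "report.json")
    return report
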