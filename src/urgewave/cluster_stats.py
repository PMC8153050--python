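"""Pixel-wise statistics over ERSP tensors and the mass-of-cluster
permutation procedure with weak family-wise error-rate (wFWER) control.

For each time-frequency pixel a paired t (2 matched conditions), a one-way
repeated-measures ANOVA F (k matched conditions) or a 2x2 within-unit
interaction F is computed.  Supra-threshold pixels are grouped into connected
clusters, each cluster's mass is the sum of absolute statistics over its
members, and significance is assessed against the permutation distribution of
the *largest* cluster mass obtained by re-labelling conditions within units
(sign flips for paired designs, within-unit level permutations for k-level
designs).  A cluster is retained when its true mass exceeds the stated
percentile of that null distribution; corrected p uses the add-one estimator
``(1 + #{null >= mass}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .exceptions import ParameterError

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


# ---------------------------------------------------------------------------
# Pixel-wise statistic maps
# ---------------------------------------------------------------------------


@dataclass
class PixelStatMap:
    """t or F values (and p) per time-frequency pixel."""

    stat: np.ndarray            # (n_freqs, n_times)
    p: np.ndarray
    df: tuple
    kind: str                   # "t" or "F"
    design: str                 # "paired", "rm", "interaction"
    n_units: int


def _paired_t_from_diff(d: np.ndarray):
    """Vectorised paired t over axis 0 of differences (n_units, ...).

    Zero-variance pixels get t = 0 and p = 1.
    """
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p[sd == 0.0] = 1.0
    return t, p


def paired_t_map(ersp_a: np.ndarray, ersp_b: np.ndarray) -> PixelStatMap:
    """Per-pixel paired t (df = n-1, two-sided p) for matched units.

    Inputs are (n_units, n_freqs, n_times) with units aligned across
    conditions.
    """
    a = np.asarray(ersp_a, dtype=float)
    b = np.asarray(ersp_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("condition tensors must have matching shapes")
    n = a.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 matched units")
    t, p = _paired_t_from_diff(a - b)
    return PixelStatMap(stat=t, p=p, df=(n - 1,), kind="t", design="paired", n_units=n)


def _rm_anova_f(data: np.ndarray):
    """One-way within-unit F over (k, n, ...) data.

    F = MS_condition / MS_(condition x unit), df = (k-1), (k-1)(n-1).
    """
    k, n = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    cond_means = data.mean(axis=1)
    unit_means = data.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum(axis=0)
    ss_unit = k * ((unit_means - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_unit, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f[~np.isfinite(f)] = 0.0
    p = stats.f.sf(f, df1, df2)
    return f, p, (df1, df2)


def rm_anova_map(ersp_levels) -> PixelStatMap:
    """One-way repeated-measures ANOVA F map over k >= 2 matched levels.

    ``ersp_levels`` is a sequence of (n_units, n_freqs, n_times) tensors with
    the same units in every level.
    """
    data = np.stack([np.asarray(x, dtype=float) for x in ersp_levels])
    if data.shape[1] < 2:
        raise ParameterError("need at least 2 units")
    f, p, df = _rm_anova_f(data)
    return PixelStatMap(stat=f, p=p, df=df, kind="F", design="rm", n_units=data.shape[1])


def interaction_contrast(cells: np.ndarray) -> np.ndarray:
    """Per-unit 2x2 interaction contrast X11 - X12 - X21 + X22."""
    return cells[0, 0] - cells[0, 1] - cells[1, 0] + cells[1, 1]


def interaction_map(cells) -> PixelStatMap:
    """F map (df = 1, n-1) for the A x B within-unit interaction of a complete
    2x2 design.

    ``cells`` is a 2x2 nested sequence (or array) of (n_units, n_freqs,
    n_times) tensors.  The interaction F equals the squared paired t of the
    per-unit double-difference contrast.
    """
    arr = np.asarray(
        [[np.asarray(cells[i][j], dtype=float) for j in (0, 1)] for i in (0, 1)]
    )
    if arr.ndim != 5:
        raise ParameterError("cells must form a complete 2x2 within-unit design")
    n = arr.shape[2]
    if n < 2:
        raise ParameterError("need at least 2 units")
    t, _ = _paired_t_from_diff(interaction_contrast(arr))
    f = t**2
    p = stats.f.sf(f, 1, n - 1)
    return PixelStatMap(
        stat=f, p=p, df=(1, n - 1), kind="F", design="interaction", n_units=n
    )


# ---------------------------------------------------------------------------
# Clustering and the permutation null
# ---------------------------------------------------------------------------


@dataclass
class TFCluster:
    """Connected supra-threshold time-frequency cluster."""

    pixels: tuple               # (freq_indices, time_indices)
    mass: float                 # sum of |statistic| over members
    p_corrected: float | None = None
    freq_range: tuple | None = None   # (f_lo, f_hi) in Hz when grids given
    time_range: tuple | None = None   # (t_min, t_max) in s
    earliest_time: float | None = None

    @property
    def size(self) -> int:
        return len(self.pixels[0])

    def annotate(self, freqs: np.ndarray, times: np.ndarray) -> "TFCluster":
        fi, ti = self.pixels
        self.freq_range = (float(freqs[fi.min()]), float(freqs[fi.max()]))
        self.time_range = (float(times[ti.min()]), float(times[ti.max()]))
        self.earliest_time = float(times[ti.min()])
        return self


def _max_mass(stat: np.ndarray, mask: np.ndarray, structure: np.ndarray) -> float:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0.0
    return float(
        np.max(ndimage.sum_labels(np.abs(stat), labels, np.arange(1, n + 1)))
    )


def threshold_and_cluster(
    stat_map: PixelStatMap, alpha_pixel: float, connectivity: int = 4
) -> list:
    """Connected components of pixels with p < ``alpha_pixel``.

    4-connectivity (edge-sharing neighbours) by default; 8 adds diagonals.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 4 or 8")
    mask = stat_map.p < alpha_pixel
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n + 1):
        fi, ti = np.nonzero(labels == lab)
        clusters.append(
            TFCluster(pixels=(fi, ti), mass=float(np.abs(stat_map.stat[fi, ti]).sum()))
        )
    clusters.sort(key=lambda c: -c.mass)
    return clusters


@dataclass
class PermutationNull:
    """Max cluster-mass distribution under within-unit re-labelling."""

    max_masses: np.ndarray
    n_perm: int
    seed: object
    alpha_pixel: float
    connectivity: int
    design: str

    def threshold(self, percentile: float) -> float:
        """Order-statistic threshold at the given percentile of the null."""
        if not 0.0 < percentile < 100.0:
            raise ParameterError("percentile must be in (0, 100)")
        return float(
            np.quantile(self.max_masses, percentile / 100.0, method="higher")
        )


def _sign_flip_null(d: np.ndarray, alpha, n_perm, rng, structure, df_kind):
    """Null from sign flips of per-unit differences.

    ``df_kind`` is "t" (paired t, two-sided) or "F1" (interaction F = t^2).
    Means and t values per permutation come from running sums: the total sum
    of squares is flip-invariant, so only the flipped sum is recomputed.
    """
    n = d.shape[0]
    flat = d.reshape(n, -1)
    ssq = (flat**2).sum(axis=0)
    shape = d.shape[1:]
    if isinstance(n_perm, str) and n_perm == "exhaustive":
        signs = np.array(
            [[1 if (m >> u) & 1 else -1 for u in range(n)] for m in range(2**n)],
            dtype=float,
        )
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    out = np.empty(signs.shape[0])
    for i, s in enumerate(signs):
        mean = (s @ flat) / n
        var = np.maximum(ssq - n * mean**2, 0.0) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / np.sqrt(var / n)
        t[~np.isfinite(t)] = 0.0
        if df_kind == "t":
            p = 2.0 * stats.t.sf(np.abs(t), n - 1)
            stat = t
        else:
            f = t**2
            p = stats.f.sf(f, 1, n - 1)
            stat = f
        out[i] = _max_mass(
            stat.reshape(shape), (p < alpha).reshape(shape), structure
        )
    return out


def _level_perm_null(data: np.ndarray, alpha, n_perm, rng, structure):
    """Null from independent within-unit permutations of the k level labels."""
    k, n = data.shape[:2]
    out = np.empty(n_perm)
    unit_idx = np.arange(n)[None, :]
    for i in range(n_perm):
        perms = np.stack([rng.permutation(k) for _ in range(n)], axis=1)  # (k, n)
        shuffled = data[perms, unit_idx, ...]
        f, p, _ = _rm_anova_f(shuffled)
        out[i] = _max_mass(f, p < alpha, structure)
    return out


def permutation_null(
    data,
    design: str,
    alpha_pixel: float,
    n_perm: int = 1000,
    seed=None,
    connectivity: int = 4,
) -> PermutationNull:
    """Build the max cluster-mass null for one contrast.

    ``design``:
      * ``"paired"`` - ``data = (ersp_a, ersp_b)``; random sign flips of the
        per-unit differences (``n_perm="exhaustive"`` enumerates all 2^n).
      * ``"rm"`` - ``data`` = sequence of k level tensors; random within-unit
        permutations of the level labels.
      * ``"interaction"`` - ``data`` = 2x2 nested cells; sign flips of the
        per-unit interaction contrast.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 4 or 8")
    if not (isinstance(n_perm, str) and n_perm == "exhaustive") and n_perm < 100:
        raise ParameterError("n_perm must be >= 100 (or 'exhaustive')")
    structure = _STRUCTURES[connectivity]
    rng = np.random.default_rng(seed)
    if design == "paired":
        a, b = data
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        masses = _sign_flip_null(d, alpha_pixel, n_perm, rng, structure, "t")
    elif design == "interaction":
        arr = np.asarray(
            [[np.asarray(data[i][j], dtype=float) for j in (0, 1)] for i in (0, 1)]
        )
        c = interaction_contrast(arr)
        masses = _sign_flip_null(c, alpha_pixel, n_perm, rng, structure, "F1")
    elif design == "rm":
        stacked = np.stack([np.asarray(x, dtype=float) for x in data])
        if isinstance(n_perm, str):
            raise ParameterError("exhaustive enumeration is only defined for paired designs")
        masses = _level_perm_null(stacked, alpha_pixel, n_perm, rng, structure)
    else:
        raise ParameterError(f"unknown design {design!r}")
    return PermutationNull(
        max_masses=masses,
        n_perm=len(masses),
        seed=seed,
        alpha_pixel=alpha_pixel,
        connectivity=connectivity,
        design=design,
    )


def wfwer_test(
    stat_map: PixelStatMap, null: PermutationNull, percentile: float
) -> list:
    """Clusters whose mass exceeds the null's percentile threshold.

    Clusters are re-derived from the map with the null's own pixel threshold
    and connectivity, so observed and surrogate pipelines match by
    construction.  Every returned cluster carries the add-one corrected p.
    """
    thr = null.threshold(percentile)
    clusters = threshold_and_cluster(stat_map, null.alpha_pixel, null.connectivity)
    significant = []
    for c in clusters:
        c.p_corrected = float(
            (1 + np.sum(null.max_masses >= c.mass)) / (1 + null.n_perm)
        )
        if c.mass > thr:
            significant.append(c)
    return significant
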