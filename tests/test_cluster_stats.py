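import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urgewave import (
    ParameterError,
    interaction_map,
    paired_t_map,
    permutation_null,
    rm_anova_map,
    threshold_and_cluster,
    wfwer_test,
)
from urgewave.cluster_stats import PixelStatMap, interaction_contrast


def _paired_data(rng, n=12, shape=(8, 10), effect=0.0):
    a = rng.standard_normal((n, *shape))
    b = rng.standard_normal((n, *shape))
    a[:, :3, :3] += effect
    return a, b


class TestPixelMaps:
    def test_paired_t_matches_scipy(self, rng):
        a, b = _paired_data(rng, effect=1.0)
        out = paired_t_map(a, b)
        t_ref, p_ref = stats.ttest_rel(a[:, 2, 2], b[:, 2, 2])
        assert out.stat[2, 2] == pytest.approx(t_ref)
        assert out.p[2, 2] == pytest.approx(p_ref)
        assert out.df == (a.shape[0] - 1,)

    def test_zero_variance_pixel_is_null(self):
        a = np.zeros((5, 2, 2))
        out = paired_t_map(a, a)
        assert np.all(out.stat == 0.0) and np.all(out.p == 1.0)

    def test_rm_anova_matches_pingouin(self, rng):
        import pingouin

        k, n = 3, 14
        data = rng.standard_normal((k, n, 2, 2))
        data[1] += 0.8
        out = rm_anova_map([data[i] for i in range(k)])
        long = pd.DataFrame(
            {
                "y": np.concatenate([data[i, :, 0, 0] for i in range(k)]),
                "cond": np.repeat(np.arange(k), n),
                "subj": np.tile(np.arange(n), k),
            }
        )
        ref = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert out.stat[0, 0] == pytest.approx(float(ref["F"].iloc[0]))
        assert out.p[0, 0] == pytest.approx(float(ref["p_unc"].iloc[0]))
        assert out.df == (k - 1, (k - 1) * (n - 1))

    def test_t_squared_equals_f_at_two_levels(self, rng):
        """Property: with k = 2 the rm-ANOVA F equals the paired t^2."""
        a, b = _paired_data(rng, effect=0.7)
        t = paired_t_map(a, b)
        f = rm_anova_map([a, b])
        assert np.allclose(f.stat, t.stat**2, atol=1e-8)
        assert np.allclose(f.p, t.p, atol=1e-10)

    def test_interaction_contrast_and_map(self, rng):
        cells = rng.standard_normal((2, 2, 10, 3, 3))
        c = interaction_contrast(cells)
        assert np.allclose(c, cells[0, 0] - cells[0, 1] - cells[1, 0] + cells[1, 1])
        out = interaction_map([[cells[0, 0], cells[0, 1]], [cells[1, 0], cells[1, 1]]])
        t_ref, p_ref = stats.ttest_1samp(c[:, 1, 1], 0.0)
        assert out.stat[1, 1] == pytest.approx(t_ref**2)
        assert out.p[1, 1] == pytest.approx(p_ref)


class TestClustering:
    def _map(self, stat, p):
        return PixelStatMap(stat=stat, p=p, df=10, kind="t", design="paired", n_units=11)

    def test_mass_and_connectivity(self):
        stat = np.zeros((5, 5))
        p = np.ones((5, 5))
        # two diagonal pixels: separate under 4-connectivity, one under 8
        for i, j, v in ((1, 1, 3.0), (2, 2, 4.0)):
            stat[i, j] = v
            p[i, j] = 0.001
        c4 = threshold_and_cluster(self._map(stat, p), 0.01, connectivity=4)
        c8 = threshold_and_cluster(self._map(stat, p), 0.01, connectivity=8)
        assert len(c4) == 2 and len(c8) == 1
        assert c8[0].mass == pytest.approx(7.0)
        assert c4[0].mass == pytest.approx(4.0)  # sorted by decreasing mass

    def test_mass_uses_absolute_stat(self):
        stat = np.array([[-5.0, -4.0], [0.0, 0.0]])
        p = np.array([[0.001, 0.001], [1.0, 1.0]])
        c = threshold_and_cluster(self._map(stat, p), 0.01)
        assert c[0].mass == pytest.approx(9.0)

    def test_annotate(self):
        stat = np.zeros((4, 6)); p = np.ones((4, 6))
        stat[1:3, 2:4] = 5.0; p[1:3, 2:4] = 1e-4
        c = threshold_and_cluster(self._map(stat, p), 0.01)[0]
        freqs = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.linspace(-1, 1, 6)
        c = c.annotate(freqs, times)
        assert c.freq_range == (2.0, 3.0)
        assert c.earliest_time == pytest.approx(times[2])

    def test_invalid_connectivity(self):
        with pytest.raises(ParameterError):
            threshold_and_cluster(self._map(np.zeros((2, 2)), np.ones((2, 2))), 0.05, 5)


class TestPermutationNull:
    def test_exhaustive_equals_enumeration(self, rng):
        """Property: the sign-flip null for n <= 10 paired units equals a
        brute-force enumeration of all 2^n relabelings."""
        n, shape = 5, (4, 5)
        a = rng.standard_normal((n, *shape)) + 0.5
        b = rng.standard_normal((n, *shape))
        alpha = 0.05
        null = permutation_null((a, b), "paired", alpha, "exhaustive", seed=0)

        d = a - b
        ref = []
        from scipy.ndimage import label

        for signs in itertools.product([1.0, -1.0], repeat=n):
            ds = np.asarray(signs)[:, None, None] * d
            t, p = stats.ttest_1samp(ds, 0.0, axis=0)
            t = np.nan_to_num(t)
            p = np.nan_to_num(p, nan=1.0)
            lab, nlab = label(p < alpha)
            masses = [np.abs(t[lab == l]).sum() for l in range(1, nlab + 1)]
            ref.append(max(masses) if masses else 0.0)
        assert null.n_perm == 2**n
        assert np.allclose(np.sort(null.max_masses), np.sort(ref), atol=1e-9)

    def test_threshold_percentile(self):
        null = permutation_null(
            (np.random.default_rng(0).standard_normal((8, 3, 3)),
             np.random.default_rng(1).standard_normal((8, 3, 3))),
            "paired", 0.05, 200, seed=2,
        )
        thr = null.threshold(99.5)
        assert np.mean(null.max_masses > thr) <= 0.005
        with pytest.raises(ParameterError):
            null.threshold(100.0)

    def test_nperm_floor(self, rng):
        a, b = _paired_data(rng)
        with pytest.raises(ParameterError):
            permutation_null((a, b), "paired", 0.05, 50)

    def test_rm_design_rejects_exhaustive(self, rng):
        data = [rng.standard_normal((6, 2, 2)) for _ in range(3)]
        with pytest.raises(ParameterError):
            permutation_null(data, "rm", 0.05, "exhaustive")

    def test_detects_planted_effect(self, rng):
        a, b = _paired_data(rng, n=16, shape=(10, 12), effect=1.5)
        null = permutation_null((a, b), "paired", 0.005, 300, seed=3)
        sig = wfwer_test(paired_t_map(a, b), null, 99.5)
        assert len(sig) >= 1
        fi, ti = sig[0].pixels
        assert fi.max() <= 4 and ti.max() <= 4  # inside the planted block

    def test_corrected_p_add_one(self, rng):
        a, b = _paired_data(rng, n=14, effect=2.0)
        null = permutation_null((a, b), "paired", 0.005, 200, seed=4)
        sig = wfwer_test(paired_t_map(a, b), null, 99.5)
        c = sig[0]
        expected = (1 + np.sum(null.max_masses >= c.mass)) / (1 + null.n_perm)
        assert c.p_corrected == pytest.approx(expected)
        assert c.p_corrected >= 1.0 / (1 + null.n_perm)


class TestFWERCalibration:
    def test_weak_fwer_within_binomial_ci(self):
        """Property: under a global null the familywise false-positive
        rate at alpha_cluster = 0.05 stays inside the binomial 95% interval
        over 200 simulations."""
        n_sim, n, shape = 200, 10, (6, 8)
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(n_sim):
            a = rng.standard_normal((n, *shape))
            b = rng.standard_normal((n, *shape))
            null = permutation_null((a, b), "paired", 0.05, 200, seed=rng)
            sig = wfwer_test(paired_t_map(a, b), null, 95.0)
            hits += bool(sig)
        lo, hi = stats.binom.interval(0.95, n_sim, 0.05)
        assert lo <= hits <= hi
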