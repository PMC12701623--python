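"""Band, cluster and KS statistics, checked against brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from osstap import spectral as sp
from osstap.segmentation import SpectrumSet

from conftest import gaussian_set


def _uniform_spectrum(n_bins=101, bin_hz=10.0):
    freqs = np.arange(n_bins) * bin_hz
    amps = np.full(n_bins, 1.0 / n_bins)
    from osstap.segmentation import NormalizedSpectrum

    return NormalizedSpectrum(bin_freqs=freqs, amplitudes=amps)


class TestBandPower:
    def test_full_band_is_one(self):
        s = _uniform_spectrum()
        band = sp.BandDefinition("all", 0.0, 1000.0)
        assert sp.band_power(s, band) == pytest.approx(1.0)

    def test_half_band_is_half(self):
        s = _uniform_spectrum(n_bins=100)
        band = sp.BandDefinition("half", 0.0, 495.0)  # bins 0..49
        assert sp.band_power(s, band) == pytest.approx(0.5)

    def test_delta_spectrum_contained(self):
        from osstap.segmentation import NormalizedSpectrum

        freqs = np.arange(0, 5000.0, 10.0)
        amps = np.zeros_like(freqs)
        amps[290] = 1.0  # 2900 Hz
        s = NormalizedSpectrum(bin_freqs=freqs, amplitudes=amps)
        assert sp.band_power(s, sp.BandDefinition("2.9kHz", 2700.0, 3100.0)) == pytest.approx(1.0)

    def test_band_outside_range_rejected(self):
        s = _uniform_spectrum()
        with pytest.raises(ValueError):
            sp.band_power(s, sp.BandDefinition("hf", 5000.0, 9000.0))


class TestBandPermutationTest:
    def test_identical_sets_null_identity(self):
        rng = np.random.default_rng(0)
        a = gaussian_set("a", 5, 50, rng)
        b = SpectrumSet.from_matrix("b", a.bin_freqs, a.matrix.copy())
        band = sp.BandDefinition("x", 0.0, 20.0)
        r = sp.band_permutation_test(a, b, band, n_perm=500, seed=1)
        assert r.delta_mu == 0.0
        assert r.cohens_d == 0.0
        assert r.p_value == 1.0

    def test_exact_enumeration_matches_bruteforce(self):
        """4-vs-4 design: permutation p equals independent enumeration of all
        C(8,4) = 70 relabelings using scipy's t statistic."""
        rng = np.random.default_rng(42)
        a = gaussian_set("a", 4, 30, rng)
        b = gaussian_set("b", 4, 30, rng, mean=0.8)
        band = sp.BandDefinition("x", 0.0, 29.0)
        r = sp.band_permutation_test(a, b, band, n_perm=10_000, seed=0)
        assert r.exact
        pa = [sp.band_power(s, band) for s in a.spectra]
        pb = [sp.band_power(s, band) for s in b.spectra]
        pooled = np.array(pa + pb)
        t_obs = abs(stats.ttest_ind(pooled[4:], pooled[:4]).statistic)
        count = 0
        for comb in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(comb)] = True
            t = abs(stats.ttest_ind(pooled[~mask], pooled[mask]).statistic)
            if t >= t_obs - 1e-12:
                count += 1
        assert r.p_value == pytest.approx(count / 70)

    def test_symmetry_under_set_swap(self):
        rng = np.random.default_rng(3)
        a = gaussian_set("a", 4, 20, rng)
        b = gaussian_set("b", 4, 20, rng, mean=0.5)
        band = sp.BandDefinition("x", 0.0, 19.0)
        r_ab = sp.band_permutation_test(a, b, band, n_perm=10_000, seed=0)
        r_ba = sp.band_permutation_test(b, a, band, n_perm=10_000, seed=0)
        assert r_ba.delta_mu == pytest.approx(-r_ab.delta_mu)
        assert r_ba.cohens_d == pytest.approx(-r_ab.cohens_d)
        assert r_ba.p_value == pytest.approx(r_ab.p_value)  # exact regime

    def test_monte_carlo_p_uses_add_one_convention(self):
        """With a huge effect the MC p equals 1/(n_perm+1), never zero."""
        rng = np.random.default_rng(5)
        a = gaussian_set("a", 10, 10, rng, sd=0.01)
        b = gaussian_set("b", 10, 10, rng, mean=5.0, sd=0.01)
        band = sp.BandDefinition("x", 0.0, 9.0)
        r = sp.band_permutation_test(a, b, band, n_perm=99, seed=7)
        assert not r.exact
        assert r.p_value == pytest.approx(1.0 / 100.0)

    def test_single_member_set_rejected(self):
        rng = np.random.default_rng(0)
        a = gaussian_set("a", 1, 10, rng)
        b = gaussian_set("b", 4, 10, rng)
        with pytest.raises(ValueError):
            sp.band_permutation_test(a, b, sp.BandDefinition("x", 0.0, 9.0), n_perm=10)


def _naive_clusters(xa, xb, alpha, max_gap):
    """Independent cluster-forming oracle: scipy t-tests per bin, explicit
    p-threshold, loop-based same-sign merging, mass over supra bins."""
    tvals, pvals = stats.ttest_ind(xb, xa, axis=0)
    supra = [i for i in range(len(tvals)) if pvals[i] < alpha]
    clusters = []
    current = []
    for i in supra:
        if current and (i - current[-1] > max_gap or np.sign(tvals[i]) != np.sign(tvals[current[-1]])):
            clusters.append(current)
            current = []
        current.append(i)
    if current:
        clusters.append(current)
    return [
        (c[0], c[-1], float(np.sum(np.abs(tvals[c]))), int(np.sign(tvals[c[0]])))
        for c in clusters
    ]


class TestClusterPermutationTest:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cluster_structure_matches_naive_oracle(self, seed):
        """Spans, masses and signs of observed clusters agree with an
        independent loop-based implementation on random data."""
        rng = np.random.default_rng(seed)
        mean = np.zeros(80)
        mean[30:40] = 1.0
        a = gaussian_set("a", 8, 80, rng)
        b = gaussian_set("b", 8, 80, rng, mean=mean)
        ours = sp.cluster_permutation_test(a, b, n_perm=50, alpha=0.05, max_gap_bins=3, seed=9)
        theirs = _naive_clusters(a.matrix, b.matrix, 0.05, 3)
        assert [(c.bin_lo, c.bin_hi, c.sign) for c in ours] == [(lo, hi, s) for lo, hi, _, s in theirs]
        for c, (_, _, mass, _) in zip(ours, theirs):
            assert c.mass == pytest.approx(mass, rel=1e-9)

    def test_gap_merging_boundary(self):
        """Two supra-threshold runs 10 bins apart merge under the default
        20-bin rule; 30 bins apart they stay separate."""
        rng = np.random.default_rng(1)
        for gap, expected in ((10, 1), (30, 2)):
            mean = np.zeros(120)
            mean[20:25] = 4.0
            mean[25 + gap : 30 + gap] = 4.0
            a = gaussian_set("a", 10, 120, rng, sd=0.5)
            b = gaussian_set("b", 10, 120, rng, mean=mean, sd=0.5)
            clusters = sp.cluster_permutation_test(a, b, n_perm=50, max_gap_bins=20, seed=2)
            big = [c for c in clusters if c.mass > 20]
            assert len(big) == expected

    def test_opposite_signs_never_merge(self):
        rng = np.random.default_rng(4)
        mean = np.zeros(60)
        mean[10:15] = 4.0
        mean[18:23] = -4.0  # 3-bin gap, opposite sign
        a = gaussian_set("a", 10, 60, rng, sd=0.5)
        b = gaussian_set("b", 10, 60, rng, mean=mean, sd=0.5)
        clusters = [c for c in sp.cluster_permutation_test(a, b, n_perm=50, seed=3) if c.mass > 20]
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {-1, 1}

    def test_injected_span_recovered_significant(self):
        rng = np.random.default_rng(8)
        mean = np.zeros(200)
        mean[80:101] = 1.5
        a = gaussian_set("a", 12, 200, rng)
        b = gaussian_set("b", 12, 200, rng, mean=mean)
        clusters = sp.cluster_permutation_test(a, b, n_perm=199, seed=5)
        sig = [c for c in clusters if c.significant]
        assert len(sig) == 1
        assert sig[0].bin_lo <= 100 and sig[0].bin_hi >= 80
        assert sig[0].sign == 1

    def test_swap_flips_signs_keeps_masses(self):
        rng = np.random.default_rng(6)
        mean = np.zeros(50)
        mean[10:20] = 2.0
        a = gaussian_set("a", 8, 50, rng)
        b = gaussian_set("b", 8, 50, rng, mean=mean)
        ab = sp.cluster_permutation_test(a, b, n_perm=50, seed=1)
        ba = sp.cluster_permutation_test(b, a, n_perm=50, seed=1)
        assert [(c.bin_lo, c.bin_hi) for c in ab] == [(c.bin_lo, c.bin_hi) for c in ba]
        assert [c.sign for c in ba] == [-c.sign for c in ab]
        for x, y in zip(ab, ba):
            assert x.mass == pytest.approx(y.mass, rel=1e-9)

    def test_monotonicity_of_effect(self):
        """A larger injected band effect never shrinks |delta-mu| or total
        significant cluster mass, in expectation over seeds."""
        band = sp.BandDefinition("inj", 10.0, 19.0)
        dmu, mass = {}, {}
        for effect in (0.5, 1.5):
            dvals, mvals = [], []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                mean = np.zeros(60)
                mean[10:20] = effect
                a = gaussian_set("a", 10, 60, rng)
                b = gaussian_set("b", 10, 60, rng, mean=mean)
                r = sp.band_permutation_test(a, b, band, n_perm=99, seed=seed)
                dvals.append(abs(r.delta_mu))
                clusters = sp.cluster_permutation_test(a, b, n_perm=99, seed=seed)
                mvals.append(sum(c.mass for c in clusters if c.significant))
            dmu[effect] = np.mean(dvals)
            mass[effect] = np.mean(mvals)
        assert dmu[1.5] > dmu[0.5]
        assert mass[1.5] > mass[0.5]

    def test_invalid_alpha_rejected(self):
        rng = np.random.default_rng(0)
        a = gaussian_set("a", 4, 10, rng)
        b = gaussian_set("b", 4, 10, rng)
        with pytest.raises(ValueError):
            sp.cluster_permutation_test(a, b, n_perm=10, alpha=1.5)


class TestKSGlobalTest:
    def test_identical_sets_statistic_zero(self):
        rng = np.random.default_rng(0)
        a = gaussian_set("a", 5, 40, rng)
        b = SpectrumSet.from_matrix("b", a.bin_freqs, a.matrix.copy())
        r = sp.ks_global_test(a, b)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_disjoint_supports_statistic_one(self):
        rng = np.random.default_rng(1)
        a = gaussian_set("a", 5, 40, rng, mean=0.0, sd=0.01)
        b = gaussian_set("b", 5, 40, rng, mean=10.0, sd=0.01)
        assert sp.ks_global_test(a, b).statistic == 1.0

    def test_statistic_matches_direct_ecdf_scan(self):
        """Sup ECDF distance on two 500-point pooled samples agrees with an
        independent scan over the pooled support to 1e-12."""
        rng = np.random.default_rng(7)
        a = gaussian_set("a", 10, 50, rng, mean=0.0)
        b = gaussian_set("b", 10, 50, rng, mean=0.3, sd=1.5)
        r = sp.ks_global_test(a, b)
        xa, xb = np.sort(a.matrix.ravel()), np.sort(b.matrix.ravel())
        grid = np.concatenate([xa, xb])
        fa = np.searchsorted(xa, grid, side="right") / xa.size
        fb = np.searchsorted(xb, grid, side="right") / xb.size
        assert r.statistic == pytest.approx(np.max(np.abs(fa - fb)), abs=1e-12)
        assert r.n_a == 500 and r.n_b == 500
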