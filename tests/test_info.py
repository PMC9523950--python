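"""Mutual information: binning, plug-in MI, Panzeri-Treves correction, bootstrap."""

import numpy as np
import pytest

from fhmnet.info import (bootstrap_significance, equipopulated_bins,
                         joint_table, mi_corrected, mutual_information,
                         panzeri_treves_correct)
from fhmnet.synth import generate_mi_dataset


class TestBinning:
    def test_exact_quantiles(self):
        r = np.arange(70, dtype=float)
        labels = equipopulated_bins(np.random.default_rng(0).permutation(r), 7)
        assert np.bincount(labels).tolist() == [10] * 7

    def test_all_ties_single_bin(self):
        with pytest.warns(RuntimeWarning):
            labels = equipopulated_bins(np.ones(50), 7)
        assert np.unique(labels).size == 1

    def test_uniform_draws_near_equal_counts(self):
        r = np.random.default_rng(1).random(700)
        counts = np.bincount(equipopulated_bins(r, 7))
        assert counts.max() - counts.min() <= 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            equipopulated_bins(np.arange(5), 7)


class TestPluginMI:
    def test_bijection_log2_7(self):
        s = np.repeat(np.arange(7), 10)
        assert mutual_information(s, s.copy()) == pytest.approx(
            np.log2(7), abs=1e-12)

    def test_independent_small_positive_bias(self):
        rng = np.random.default_rng(2)
        s = np.repeat(np.arange(7), 100)
        r = rng.integers(0, 7, size=s.size)
        mi = mutual_information(s, r)
        assert 0 <= mi < 0.1

    def test_symmetry_square_table(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 5, 400)
        r = rng.integers(0, 5, 400)
        assert mutual_information(s, r) == pytest.approx(
            mutual_information(r, s), abs=1e-12)

    def test_single_stimulus_warns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert mutual_information(np.zeros(20), np.arange(20)) == 0.0

    def test_merging_response_bins_never_increases_mi(self):
        """Data-processing inequality, brute-forced over random tables."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            s = rng.integers(0, 4, 300)
            r = rng.integers(0, 6, 300) + (s if rng.random() < 0.5 else 0)
            mi_full = mutual_information(s, r)
            merged = r.copy()
            vals = np.unique(r)
            merged[r == vals[0]] = vals[1]  # merge two response bins
            assert mutual_information(s, merged) <= mi_full + 1e-12


class TestPanzeriTreves:
    def test_bijection_correction_nonnegative(self):
        s = np.repeat(np.arange(7), 10)
        mi = mutual_information(s, s)
        corr = panzeri_treves_correct(mi, joint_table(s, s))
        assert corr <= mi

    def test_bias_scales_inversely_with_n(self):
        rng = np.random.default_rng(5)
        biases = {}
        for n_per in (25, 50):
            deltas = []
            for rep in range(80):
                s = np.repeat(np.arange(7), n_per)
                r = rng.integers(0, 7, size=s.size)
                mi = mutual_information(s, r)
                corr = panzeri_treves_correct(mi, joint_table(s, r))
                deltas.append(mi - corr)
            biases[n_per] = np.mean(deltas)
        assert biases[25] / biases[50] == pytest.approx(2.0, rel=0.2)

    def test_shuffled_pairs_centered_near_zero(self):
        rng = np.random.default_rng(6)
        vals = []
        plugins = []
        for rep in range(100):
            s = np.repeat(np.arange(5), 20)
            r = rng.permutation(s)
            est = mi_corrected(s, r.astype(float)
                               + 0.01 * rng.standard_normal(s.size), n_bins=5)
            vals.append(est.mi_corrected)
            plugins.append(est.mi)
        assert abs(np.mean(vals)) < 0.015
        assert np.mean(plugins) > 0.02  # plug-in sits at its positive bias


class TestBootstrap:
    def test_planted_dependence_significant_with_bonferroni(self):
        s, r = generate_mi_dataset(100, "planted", seed=7, snr=3.0)
        maps = np.column_stack([r] + [np.random.default_rng(8).standard_normal(r.size)
                                      for _ in range(4)])
        out = bootstrap_significance(s, maps, n_iter=200, seed=9)
        assert out[0].significant
        assert not any(e.significant for e in out[1:])

    def test_extreme_pixel_family_wise_error(self):
        """Pure-noise maps: the extreme-pixel correction keeps the FWE near
        the nominal level."""
        rng = np.random.default_rng(10)
        n_rep, fp = 60, 0
        for rep in range(n_rep):
            s = np.repeat(np.arange(5), 16)
            maps = rng.standard_normal((s.size, 12))
            out = bootstrap_significance(s, maps, n_iter=120, seed=rep,
                                         correction="extreme_pixel", n_bins=4)
            fp += any(e.significant for e in out)
        # binomial 95% upper bound around alpha = 0.05
        assert fp / n_rep <= 0.05 + 1.65 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_p_value_convention_never_zero(self):
        s = np.repeat(np.arange(7), 20)
        out = bootstrap_significance(s, s.astype(float)[:, None], n_iter=100,
                                     seed=11)
        assert out[0].p_value == pytest.approx(1.0 / 101.0)

    def test_observed_below_null_gives_p_one(self):
        rng = np.random.default_rng(12)
        s = np.repeat(np.arange(4), 25)
        flat = np.zeros(s.size) + 1e-9 * rng.standard_normal(s.size)
        out = bootstrap_significance(s, flat[:, None], n_iter=100, seed=13,
                                     n_bins=4)
        assert out[0].p_value > 0.5
        assert not out[0].significant

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_significance(np.arange(10), np.arange(10.0)[:, None],
                                   n_iter=10)


class TestMIDatasets:
    def test_high_snr_approaches_stimulus_entropy(self):
        s, r = generate_mi_dataset(50, "planted", seed=14, snr=50.0)
        est = mi_corrected(s, r, n_bins=9)
        assert est.mi_corrected > 0.9 * np.log2(9)

    def test_mi_monotone_in_snr(self):
        vals = []
        for snr in (0.2, 1.0, 5.0):
            s, r = generate_mi_dataset(80, "planted", seed=15, snr=snr)
            vals.append(mi_corrected(s, r).mi_corrected)
        assert vals[0] < vals[1] < vals[2]

    def test_null_dataset_near_zero(self):
        s, r = generate_mi_dataset(60, "none", seed=16)
        assert abs(mi_corrected(s, r).mi_corrected) < 0.05
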