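"""Raster construction, population statistics, and shuffle controls."""

import numpy as np
import pytest
from scipy import stats

import spikemaxent as sm
from spikemaxent.raster import (CorrelogramCurve, SpikeRaster, SpikeTimes,
                                cross_trial_correlogram, read_raster_txt,
                                read_spike_times, write_raster_txt)
from spikemaxent.synthetic import make_trial_raster, shared_skeletons


class TestBinarize:
    def test_spikes_collapse_into_bins(self):
        st = SpikeTimes(np.array([[0, 0.005], [0, 0.007]]), n_cells=1, duration=0.060)
        raster = sm.binarize(st, bin_width=20.0)
        # both spikes fall in bin 0 and collapse to a single 1
        assert raster.values.tolist() == [[1, 0, 0]]

    def test_boundary_spike_goes_to_next_bin(self):
        st = SpikeTimes(np.array([[0, 0.020]]), n_cells=1, duration=0.060)
        assert sm.binarize(st, 20.0).values.tolist() == [[0, 1, 0]]

    def test_empty_and_invalid_inputs(self):
        empty = sm.binarize(SpikeTimes(np.empty((0, 2)), n_cells=3, duration=0.1), 20.0)
        assert empty.values.sum() == 0 and empty.values.shape == (3, 5)
        with pytest.raises(ValueError):
            SpikeTimes(np.array([[0, -0.01]]), n_cells=1, duration=0.1)
        with pytest.raises(ValueError):
            sm.binarize(SpikeTimes(np.empty((0, 2)), 1, 0.01), bin_width=20.0)


class TestMoments:
    def test_hand_computed_two_cell_table(self):
        raster = SpikeRaster(np.array([[1, 0, 1, 0], [1, 0, 0, 0]]), 20.0)
        mom = sm.compute_moments(raster)
        assert np.allclose(mom.rates, [0.5, 0.25])
        assert np.isclose(mom.second_moments[0, 1], 0.25)
        assert np.isclose(mom.correlations[0, 1], 1 / np.sqrt(3))
        assert np.allclose(mom.pk, [0.5, 0.25, 0.25])

    def test_degenerate_rasters(self):
        zero = sm.compute_moments(SpikeRaster(np.zeros((3, 10), dtype=np.uint8), 20.0))
        assert zero.rates.sum() == 0
        assert zero.pk[0] == 1.0
        assert np.isnan(zero.correlations[0, 1])
        twin = sm.compute_moments(SpikeRaster(np.array([[1, 0, 1], [1, 0, 1]]), 20.0))
        assert np.isclose(twin.correlations[0, 1], 1.0)

    def test_pk_normalisation_and_mean(self, study_raster):
        mom = sm.compute_moments(study_raster.subset(range(20)))
        assert abs(mom.pk.sum() - 1.0) < 1e-9
        mean_k = (np.arange(mom.pk.size) * mom.pk).sum()
        assert abs(mean_k - mom.rates.sum()) < 1e-9

    def test_correlations_agree_with_direct_pearson(self, study_raster):
        sub = study_raster.subset(range(8))
        mom = sm.compute_moments(sub)
        direct = np.corrcoef(sub.values)
        assert np.nanmax(np.abs(mom.correlations - direct)) < 1e-12


class TestBootstrap:
    def test_constant_raster_has_zero_errors(self):
        raster = SpikeRaster(np.ones((3, 100), dtype=np.uint8), 20.0)
        mom = sm.bootstrap_errors(raster, n_boot=100, seed=0)
        assert np.allclose(mom.rate_se, 0.0)

    def test_rate_se_matches_binomial_formula(self):
        rng = np.random.default_rng(42)
        p, n_bins = 0.1, 20_000
        raster = SpikeRaster((rng.random((2, n_bins)) < p).astype(np.uint8), 20.0)
        mom = sm.bootstrap_errors(raster, n_boot=200, seed=1)
        expected = np.sqrt(p * (1 - p) / n_bins)
        assert np.all(np.abs(mom.rate_se - expected) < 0.2 * expected)

    def test_deterministic_and_input_validation(self):
        raster = SpikeRaster((np.random.default_rng(0).random((3, 500)) < 0.2).astype(np.uint8), 20.0)
        a = sm.bootstrap_errors(raster, n_boot=100, seed=7)
        b = sm.bootstrap_errors(raster, n_boot=100, seed=7)
        assert np.array_equal(a.corr_se, b.corr_se)
        with pytest.raises(ValueError):
            sm.bootstrap_errors(raster, n_boot=1)


class TestZScores:
    def test_identical_inputs_give_zero(self, study_raster):
        mom = sm.bootstrap_errors(study_raster.subset(range(6)), n_boot=100, seed=0)
        rep = sm.correlation_zscores(mom, mom)
        assert np.allclose(rep.values, 0.0)

    def test_two_sigma_change_scores_sqrt_two(self):
        base = sm.bootstrap_errors(
            SpikeRaster((np.random.default_rng(3).random((2, 2000)) < 0.2).astype(np.uint8), 20.0),
            n_boot=150, seed=0)
        import copy

        other = copy.deepcopy(base)
        sigma = base.corr_se[0, 1]
        # raise C by 2 sigma; with equal errors the pooled z is 2/sqrt(2)
        other.correlations = base.correlations + 2 * sigma
        z = sm.correlation_zscores(other, base)
        assert np.isclose(z.z[0, 1], np.sqrt(2.0), atol=1e-12)

    def test_null_halves_are_standard_normal(self):
        """z-scores of two halves of one i.i.d. raster follow N(0, 1)."""
        rng = np.random.default_rng(8)
        n_cells, n_bins = 12, 100_000
        values = (rng.random((n_cells, n_bins)) < 0.05).astype(np.uint8)
        a = sm.bootstrap_errors(SpikeRaster(values[:, : n_bins // 2], 20.0), n_boot=120, seed=1)
        b = sm.bootstrap_errors(SpikeRaster(values[:, n_bins // 2:], 20.0), n_boot=120, seed=2)
        z = sm.correlation_zscores(a, b).values
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestShuffle:
    def test_counts_and_rates_preserved_exactly(self, study_raster):
        sub = study_raster.subset(range(10))
        shuffled = sm.shuffle_raster(sub, seed=5)
        assert np.array_equal(shuffled.values.sum(axis=1), sub.values.sum(axis=1))

    def test_destroys_pairwise_correlation(self):
        rng = np.random.default_rng(1)
        base = (rng.random(20_000) < 0.1).astype(np.uint8)
        raster = SpikeRaster(np.vstack([base, base]), 20.0)  # perfectly correlated pair
        shuffled = sm.shuffle_raster(raster, seed=2)
        c = sm.compute_moments(shuffled).correlations[0, 1]
        assert abs(c) < 3 / np.sqrt(raster.n_bins)

    def test_seed_reproducibility(self, study_raster):
        a = sm.shuffle_raster(study_raster, seed=9)
        b = sm.shuffle_raster(study_raster, seed=9)
        assert np.array_equal(a.values, b.values)


class TestCorrelograms:
    def _iid_trial_raster(self, p=0.2, n_trials=40, trial_len=200, seed=0):
        rng = np.random.default_rng(seed)
        values = (rng.random((1, n_trials * trial_len)) < p).astype(np.uint8)
        bounds = [(i * trial_len, (i + 1) * trial_len) for i in range(n_trials)]
        return SpikeRaster(values, 20.0, trial_bounds=bounds)

    def test_iid_trials_sit_at_chance(self):
        raster = self._iid_trial_raster()
        curve = sm.shuffled_autocorrelation(raster, cell=0, max_lag=100.0)
        n_coinc = raster.n_bins * 40 * 0.2**2  # rough count scale per lag
        assert np.all(np.abs(curve.values - 1.0) < 3 / np.sqrt(n_coinc) + 0.05)

    def test_identical_trains_peak_at_inverse_rate(self):
        p, trial_len = 0.05, 400
        rng = np.random.default_rng(4)
        one = (rng.random(trial_len) < p).astype(np.uint8)
        values = np.tile(one, 10)[None, :]
        bounds = [(i * trial_len, (i + 1) * trial_len) for i in range(10)]
        raster = SpikeRaster(values, 20.0, trial_bounds=bounds)
        curve = sm.shuffled_autocorrelation(raster, cell=0, max_lag=60.0)
        lag0 = curve.values[curve.lags == 0][0]
        p_emp = one.mean()
        assert np.isclose(lag0, 1 / p_emp, rtol=0.05)

    def test_single_trial_and_silent_cell_rejected(self):
        raster = self._iid_trial_raster(n_trials=1)
        # a single trial cannot form cross-trial pairs
        with pytest.raises(ValueError):
            sm.shuffled_autocorrelation(raster, 0, 60.0)
        silent = self._iid_trial_raster()
        silent.values[:] = 0
        with pytest.raises(ValueError):
            sm.shuffled_autocorrelation(silent, 0, 60.0)


class TestReproducibilityIndex:
    def test_calibration_points(self):
        lags = np.arange(-5, 6) * 20.0
        bump = 1.0 + np.exp(-(lags / 40) ** 2)
        auto = CorrelogramCurve(lags, bump)
        assert np.isclose(sm.reproducibility_index(auto, auto, auto), 1.0)
        flat = CorrelogramCurve(lags, np.ones_like(lags))
        assert sm.reproducibility_index(auto, auto, flat) == 0.0

    def test_flat_within_condition_is_undefined(self):
        lags = np.arange(-3, 4) * 20.0
        flat = CorrelogramCurve(lags, np.ones_like(lags))
        with pytest.warns(UserWarning):
            assert np.isnan(sm.reproducibility_index(flat, flat, flat))

    def test_half_shared_conditions_fall_between_calibrations(self):
        skel_a, skel_b = shared_skeletons(6, 400, rate=0.06, shared_frac=0.5, seed=3)
        ra = make_trial_raster(skel_a, n_trials=20, jitter=10.0, drop_prob=0.2, seed=4)
        rb = make_trial_raster(skel_b, n_trials=20, jitter=10.0, drop_prob=0.2, seed=5)
        vals = []
        for cell in range(6):
            auto_a = sm.shuffled_autocorrelation(ra, cell, 200.0)
            auto_b = sm.shuffled_autocorrelation(rb, cell, 200.0)
            cross = cross_trial_correlogram(ra, rb, cell, 200.0)
            vals.append(sm.reproducibility_index(auto_a, auto_b, cross))
        vals = np.asarray(vals)
        assert np.all(vals > 0.05) and np.all(vals < 0.95)


class TestIO:
    def test_raster_roundtrip(self, tmp_path, study_raster):
        sub = study_raster.subset(range(5))
        sub.trial_bounds = [(0, 100), (100, 200)]
        path = tmp_path / "raster.txt"
        write_raster_txt(sub, path)
        back = read_raster_txt(path)
        assert np.array_equal(back.values, sub.values)
        assert back.bin_width == sub.bin_width
        assert back.trial_bounds == sub.trial_bounds

    def test_spike_times_from_text(self, tmp_path):
        path = tmp_path / "spikes.tsv"
        path.write_text("cell\ttime\n0\t0.015\n1\t0.044\n")
        st = read_spike_times(path, n_cells=2, duration=0.06)
        raster = sm.binarize(st, 20.0)
        assert raster.values.tolist() == [[1, 0, 0], [0, 0, 1]]
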