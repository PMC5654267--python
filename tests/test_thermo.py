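"""Energies, exact thermodynamics, annealed Monte Carlo, peak statistics."""

import numpy as np
import pytest

import spikemaxent as sm
from spikemaxent import _exact
from spikemaxent.maxent import MaxEntModel
from spikemaxent.synthetic import GroundTruthSpec, random_model
from spikemaxent.thermo import (ThermoCurve, annealed_specific_heat, default_t_grid,
                                exact_specific_heat_curve, exact_thermo,
                                independent_heat_analytic, peak_statistics,
                                subsample_scan)


def two_state_heat(p: float, t: float = 1.0) -> float:
    """Closed-form specific heat of one cell with rate p at temperature t."""
    h = np.log((1 - p) / p)
    q = 1 / (1 + np.exp(h / t))
    return (h / t) ** 2 * q * (1 - q)


class TestEnergy:
    def test_all_silent_state_is_the_zero_of_energy(self, gt_model_n10):
        assert sm.energy(gt_model_n10, np.zeros(10)) == 0.0

    def test_hand_computed_example(self):
        model = MaxEntModel(np.array([0.5, 1.0]), np.array([[0, -0.3], [-0.3, 0]]),
                            np.array([0.0, 0.0, 0.2]), model_class="k-pairwise")
        # 0.5 + 1.0 + 2*(-0.3) + 0.2
        assert np.isclose(sm.energy(model, np.array([1, 1])), 1.1)

    def test_partition_function_matches_brute_force(self, gt_model_n10):
        m = gt_model_n10
        bits = _exact.state_bits(10)
        z_brute = sum(np.exp(-m.energy(b)) for b in bits)
        ps = exact_thermo(m, 1.0)
        assert np.isclose(ps.log_z, np.log(z_brute), atol=1e-9)


class TestExactThermo:
    def test_single_unbiased_cell(self):
        model = MaxEntModel(np.zeros(1), np.zeros((1, 1)), np.zeros(2),
                            model_class="independent")
        for t in (0.5, 1.0, 2.0):
            ps = exact_thermo(model, t)
            assert np.isclose(np.exp(ps.log_z), 2.0)
            assert np.isclose(ps.heat_capacity, 0.0, atol=1e-14)

    def test_single_sparse_cell_closed_form(self):
        model = MaxEntModel(np.array([np.log(9)]), np.zeros((1, 1)), np.zeros(2),
                            model_class="independent")
        c = exact_thermo(model, 1.0).heat_capacity
        assert np.isclose(c, np.log(9) ** 2 * 0.09, atol=1e-12)
        assert np.isclose(c, 0.4345, atol=5e-4)

    def test_independent_heat_is_additive(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.02, 0.3, size=8)
        h = np.log((1 - p) / p)
        model = MaxEntModel(h, np.zeros((8, 8)), np.zeros(9), model_class="independent")
        for t in (0.7, 1.3):
            total = exact_thermo(model, t).heat_capacity
            assert np.isclose(total, sum(two_state_heat(pi, t) for pi in p), atol=1e-10)

    def test_large_population_rejected(self):
        model = MaxEntModel(np.zeros(22), np.zeros((22, 22)), np.zeros(23),
                            model_class="independent")
        with pytest.raises(ValueError):
            exact_thermo(model, 1.0)


class TestAnalyticIndependent:
    def test_half_rate_cells_contribute_nothing(self):
        curve = independent_heat_analytic(np.array([0.5, 0.5]), default_t_grid(10))
        assert np.allclose(curve.c, 0.0, atol=1e-14)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.01, 0.2, size=6)
        h = np.log((1 - p) / p)
        model = MaxEntModel(h, np.zeros((6, 6)), np.zeros(7), model_class="independent")
        grid = default_t_grid(15)
        analytic = independent_heat_analytic(p, grid)
        exact = exact_specific_heat_curve(model, grid)
        assert np.max(np.abs(analytic.c_total - exact.c_total)) < 1e-10

    def test_degenerate_rates_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="rate 0 or 1"):
            curve = independent_heat_analytic(np.array([0.0, 0.1]), default_t_grid(8))
        assert np.all(np.isfinite(curve.c))


class TestAnnealedMC:
    def test_zero_energy_model_has_zero_heat(self):
        model = MaxEntModel(np.zeros(6), np.zeros((6, 6)), np.zeros(7),
                            model_class="independent")
        curve = annealed_specific_heat(model, default_t_grid(8), n_runs=10,
                                       samples_per_run=200, seed=1)
        assert np.allclose(curve.c, 0.0, atol=1e-12)
        assert np.allclose(curve.mean_rate, 0.5, atol=0.05)

    def test_tracks_exact_curve(self, gt_model_n10):
        grid = default_t_grid(12)
        mc = annealed_specific_heat(gt_model_n10, grid, n_runs=40,
                                    samples_per_run=1000, seed=2)
        exact = exact_specific_heat_curve(gt_model_n10, grid)
        within = np.abs(mc.c_total - exact.c_total) <= 3 * mc.c_se * mc.n_cells
        assert within.mean() >= 0.9
        assert np.all(mc.c >= 0)

    def test_rates_rise_with_temperature(self, gt_model_n10):
        grid = np.geomspace(20.0, 0.05, 15)
        curve = annealed_specific_heat(gt_model_n10, grid, n_runs=30,
                                       samples_per_run=500, seed=3)
        # sparse model: silent at low T, half-active in the hot limit
        assert curve.mean_rate[-1] < 0.01
        assert curve.mean_rate[0] > 0.4
        rate_by_increasing_t = curve.mean_rate[::-1]
        assert np.all(np.diff(rate_by_increasing_t) > -0.02)

    def test_same_seed_reproduces_curve(self, gt_model_n10):
        grid = default_t_grid(6)
        a = annealed_specific_heat(gt_model_n10, grid, n_runs=10, samples_per_run=200, seed=7)
        b = annealed_specific_heat(gt_model_n10, grid, n_runs=10, samples_per_run=200, seed=7)
        assert np.array_equal(a.c, b.c) and np.array_equal(a.c_se, b.c_se)

    def test_grid_must_descend(self, gt_model_n10):
        with pytest.raises(ValueError):
            annealed_specific_heat(gt_model_n10, np.array([1.0, 2.0]), n_runs=4,
                                   samples_per_run=10)


class TestPeakStatistics:
    def _curve(self, c, se=None):
        t = np.linspace(3, 0.5, c.size)
        se = np.zeros_like(c) if se is None else se
        return ThermoCurve(t, c, se, np.zeros_like(c), np.zeros_like(c), n_cells=10)

    def test_known_argmax_recovered(self):
        c = np.exp(-((np.linspace(3, 0.5, 21) - 1.4) ** 2))
        curve = self._curve(c)
        t_max, c_max = peak_statistics(curve, smooth=False)
        assert np.isclose(t_max, curve.temperatures[np.argmax(c)])
        assert c_max == c.max()

    def test_flat_curve_flags_no_peak(self):
        curve = self._curve(np.zeros(10))
        assert peak_statistics(curve) == (None, None)
        assert "no_peak" in curve.peak_flags

    def test_boundary_peak_flagged(self):
        curve = self._curve(np.linspace(0, 1, 10))
        peak_statistics(curve, smooth=False)
        assert "peak_at_boundary" in curve.peak_flags

    def test_analytic_sparse_curve_has_interior_peak(self):
        curve = independent_heat_analytic(np.full(20, 0.03), default_t_grid(40))
        t_max, _ = peak_statistics(curve)
        assert t_max is not None
        assert curve.temperatures[-1] < t_max < curve.temperatures[0]
        assert not curve.peak_flags


class TestSubsampleScan:
    def test_bookkeeping_shapes(self, study_raster):
        small = study_raster.subset(range(20))
        scan = subsample_scan(small, sizes=(5, 10), n_groups=2,
                              model_class="pairwise", seed=1,
                              t_grid=default_t_grid(8), n_runs=8,
                              samples_per_run=100)
        assert set(scan.curves) == {(5, 0), (5, 1), (10, 0), (10, 1)}
        assert len(scan.summary) == 2
        assert all(len(scan.groups[(5, g)]) == 5 for g in (0, 1))

    def test_oversized_request_rejected(self, study_raster):
        with pytest.raises(ValueError):
            subsample_scan(study_raster, sizes=(100,), n_groups=1)

    def test_shuffled_input_matches_independent_form(self, study_raster):
        """After the grand shuffle the fitted curves collapse onto the
        analytic independent curve, whatever the subgroup size.

        The comparison's standard error combines the Monte-Carlo error of
        the annealed curve with the finite-data fit noise (the model soaks
        up sampling fluctuations of the shuffled moments), estimated by
        bootstrap refits.
        """
        shuffled = sm.shuffle_raster(study_raster, seed=6)
        grid = default_t_grid(10)
        rng = np.random.default_rng(12)
        for size in (8, 14):
            sub = shuffled.subset(range(size))
            mom = sm.compute_moments(sub)
            model, _ = sm.fit_maxent(mom, "k-pairwise", gradient_mode="exact", seed=2)
            mc = annealed_specific_heat(model, grid, n_runs=40, samples_per_run=800,
                                        seed=3)
            boot_curves = []
            for b in range(3):
                idx = rng.integers(0, sub.n_bins, size=sub.n_bins)
                bmom = sm.compute_moments(
                    sm.SpikeRaster(sub.values[:, idx], sub.bin_width))
                bmodel, _ = sm.fit_maxent(bmom, "k-pairwise", gradient_mode="exact",
                                          seed=4 + b)
                boot_curves.append(exact_specific_heat_curve(bmodel, grid).c)
            fit_sd = np.std(boot_curves, axis=0, ddof=1)
            total_se = np.sqrt(mc.c_se**2 + fit_sd**2)
            analytic = independent_heat_analytic(mom.rates, grid)
            dev = np.abs(mc.c - analytic.c)
            assert np.all(dev <= 3 * np.maximum(total_se, 1e-3))
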