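"""Energy-landscape probes: fields, flow, descent, dwell, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import spikemaxent as sm
from spikemaxent import _exact, _gibbs
from spikemaxent.landscape import (descent_census, dwell_time, effective_field,
                                   effective_fields, flow_overlap_profile,
                                   flow_vector, persistence_index,
                                   pi_dwell_correlation,
                                   zero_temperature_descent)
from spikemaxent.maxent import MaxEntModel
from spikemaxent.synthetic import GroundTruthSpec, random_model


def sparse_independent_model(n=6, p=0.05):
    h = np.full(n, np.log((1 - p) / p))
    return MaxEntModel(h, np.zeros((n, n)), np.zeros(n + 1), model_class="independent")


def attractor_model(strengths=(0.16, 0.21, 0.26), group_size=12, h0=3.2):
    """Disjoint cliques of mutually excitatory cells on a silent background.

    Couplings are chosen so each clique state lies above the silent state
    in energy (silence still dominates equilibrium) while the holding
    field keeps clique members active — metastable attractors of graded
    depth.
    """
    n = group_size * len(strengths)
    h = np.full(n, h0)
    J = np.zeros((n, n))
    states = []
    for gi, s in enumerate(strengths):
        idx = np.arange(gi * group_size, (gi + 1) * group_size)
        J[np.ix_(idx, idx)] = -s
        J[idx, idx] = 0.0
        st_ = np.zeros(n, np.uint8)
        st_[idx] = 1
        states.append(st_)
    return MaxEntModel(h, J, np.zeros(n + 1), model_class="pairwise"), np.array(states)


class TestEffectiveField:
    def test_hand_computed_example(self):
        model = MaxEntModel(np.ones(3), np.zeros((3, 3)),
                            np.array([0.0, 0.0, 0.5, 2.0]))
        # cell 3 silent, two others active: dE = 1 + (lambda_3 - lambda_2)
        assert np.isclose(effective_field(model, np.array([1, 1, 0]), 2), 2.5)

    def test_independent_model_field_is_h(self):
        model = sparse_independent_model()
        rng = np.random.default_rng(1)
        for _ in range(5):
            state = (rng.random(6) < 0.5).astype(np.uint8)
            for i in range(6):
                assert np.isclose(effective_field(model, state, i), model.h[i])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_energy_difference(self, seed):
        """dE_i is exactly E(r_i = 1) - E(r_i = 0) for random models/states."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        model = random_model(GroundTruthSpec(n_cells=n, seed=int(rng.integers(1e6))))
        state = (rng.random(n) < 0.4).astype(np.uint8)
        i = int(rng.integers(n))
        on, off = state.copy(), state.copy()
        on[i], off[i] = 1, 0
        brute = model.energy(on) - model.energy(off)
        assert abs(effective_field(model, state, i) - brute) < 1e-12


class TestFlowVector:
    def test_independent_flow_equals_rate_everywhere(self):
        p = 0.07
        model = sparse_independent_model(5, p)
        for state in (np.zeros(5), np.ones(5), np.array([1, 0, 1, 0, 0])):
            x = flow_vector(model, state).x
            assert np.allclose(x, p, atol=1e-12)

    def test_zero_field_gives_half(self):
        model = MaxEntModel(np.zeros(4), np.zeros((4, 4)), np.zeros(5))
        assert np.allclose(flow_vector(model, np.zeros(4)).x, 0.5)

    def test_heat_bath_stationary_distribution(self):
        """The sampler driven by the flow probabilities leaves the Boltzmann
        distribution invariant (chi-square against enumeration, N = 8)."""
        model = random_model(GroundTruthSpec(n_cells=8, mean_rate=0.08, seed=21))
        state = np.zeros(8, np.uint8)
        counts = _gibbs.gibbs_state_counts(model.h, model.J, model.lam, 1.0,
                                           state, 500, 100_000, 17)
        p = np.exp(_exact.log_probs(model.h, model.J, model.lam))
        expected = p * counts.sum()
        keep = expected >= 5
        obs = np.append(counts[keep], counts[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        # sweeps are correlated samples; thin by using the effective count
        pval = stats.chisquare(obs, exp / exp.sum() * obs.sum()).pvalue
        assert pval > 0.01


class TestDescent:
    def test_sparse_independent_population_drains_to_silence(self):
        model = sparse_independent_model(8, 0.03)
        rng = np.random.default_rng(2)
        states = (rng.random((20, 8)) < 0.5).astype(np.uint8)
        frac, minima = descent_census(model, states)
        assert frac == 1.0
        assert set(minima) == {tuple([0] * 8)}

    def test_engineered_pair_is_a_nonsilent_minimum(self):
        model = MaxEntModel(np.array([1.0, 1.0]), np.array([[0, -1.5], [-1.5, 0]]),
                            np.zeros(3), model_class="pairwise")
        res = zero_temperature_descent(model, np.array([1, 0]))
        assert res.final_state.tolist() == [1, 1]
        assert np.isclose(res.energy_trajectory[-1], -1.0)
        assert not res.reached_silence
        assert np.all(np.diff(res.energy_trajectory) < 0)

    def test_local_minimum_is_a_fixed_point(self):
        model = sparse_independent_model(5)
        res = zero_temperature_descent(model, np.zeros(5, np.uint8))
        assert res.n_flips == 0

    def test_empty_census(self, gt_model_n10):
        frac, minima = descent_census(gt_model_n10, np.empty((0, 10)))
        assert np.isnan(frac) and minima == {}

    def test_trajectories_strictly_decrease(self, gt_model_n10):
        rng = np.random.default_rng(3)
        for _ in range(10):
            state = (rng.random(10) < 0.5).astype(np.uint8)
            res = zero_temperature_descent(gt_model_n10, state)
            assert np.all(np.diff(res.energy_trajectory) < 0)


class TestFlowOverlap:
    def test_identical_models_overlap_perfectly(self, gt_model_n10):
        rng = np.random.default_rng(4)
        states = (rng.random((300, 10)) < 0.5).astype(np.uint8)
        prof = flow_overlap_profile(gt_model_n10, gt_model_n10, states,
                                    n_groups=10, min_spikes=2)
        assert np.allclose(prof.direction_overlap, 1.0, atol=1e-12)
        assert np.allclose(prof.magnitude_ratio, 1.0, atol=1e-12)

    def test_proportional_independent_models(self):
        a = sparse_independent_model(6, 0.05)
        b = sparse_independent_model(6, 0.10)
        rng = np.random.default_rng(5)
        states = (rng.random((100, 6)) < 0.5).astype(np.uint8)
        prof = flow_overlap_profile(a, b, states, n_groups=5, min_spikes=1)
        assert np.allclose(prof.direction_overlap, 1.0, atol=1e-12)
        assert np.allclose(prof.magnitude_ratio, prof.magnitude_ratio.iloc[0])

    def test_group_count_reduced_with_warning(self, gt_model_n10):
        states = np.ones((7, 10), dtype=np.uint8)
        with pytest.warns(UserWarning, match="reducing group count"):
            prof = flow_overlap_profile(gt_model_n10, gt_model_n10, states,
                                        n_groups=50, min_spikes=1)
        assert len(prof) == 7


class TestDwell:
    def test_strongly_silent_model_dissolves_in_one_sweep(self):
        model = sparse_independent_model(15, 0.0005)
        state = np.zeros(15, np.uint8)
        state[:12] = 1
        res = dwell_time(model, state, silent_target=9, max_sweeps=50,
                         n_runs=300, seed=1)
        assert res.n_censored == 0
        assert (res.dwell == 1).mean() > 0.99

    def test_pinned_cells_censor_every_run(self):
        h = np.full(12, -15.0)  # overwhelming drive to spike
        model = MaxEntModel(h, np.zeros((12, 12)), np.zeros(13),
                            model_class="independent")
        state = np.ones(12, np.uint8)
        res = dwell_time(model, state, silent_target=9, max_sweeps=20,
                         n_runs=50, seed=2)
        assert res.n_censored == 50
        assert np.isnan(res.mean)

    def test_target_exceeding_spike_count_rejected(self, gt_model_n10):
        with pytest.raises(ValueError):
            dwell_time(gt_model_n10, np.zeros(10), silent_target=9,
                       max_sweeps=10, n_runs=5)


class TestPersistenceIndex:
    def test_uniform_flow_single_spiker(self):
        model = sparse_independent_model(4, 0.1)
        state = np.array([1, 0, 0, 0])
        # x = (p, p, p, p): cos = p / (2p) = 0.5
        assert np.isclose(persistence_index(model, state), 0.5)

    def test_parallel_limit_approaches_one(self):
        h = np.array([-12.0, -12.0, 12.0, 12.0])
        model = MaxEntModel(h, np.zeros((4, 4)), np.zeros(5),
                            model_class="independent")
        state = np.array([1, 1, 0, 0])
        assert persistence_index(model, state) > 0.999

    def test_silent_state_rejected(self, gt_model_n10):
        with pytest.raises(ValueError):
            persistence_index(gt_model_n10, np.zeros(10))

    def test_always_in_unit_interval(self, gt_model_n10):
        rng = np.random.default_rng(6)
        for _ in range(20):
            state = np.zeros(10, np.uint8)
            state[rng.choice(10, rng.integers(1, 10), replace=False)] = 1
            pi = persistence_index(gt_model_n10, state)
            assert 0 < pi <= 1


class TestPiDwell:
    def test_attractor_strength_orders_dwell_times(self):
        model, clique_states = attractor_model()
        rng = np.random.default_rng(7)
        extra = np.zeros((9, model.n_cells), np.uint8)
        for i in range(9):
            extra[i, rng.choice(model.n_cells, 12, replace=False)] = 1
        states = np.vstack([clique_states, extra])
        res = pi_dwell_correlation(model, states, silent_target=9,
                                   max_sweeps=3000, n_runs=200, seed=8)
        assert res["reliable"]
        assert res["r_full"] >= 0.5
        mean_full = res["table"]["mean_dwell"].mean()
        mean_ind = res["table"]["mean_dwell_independent"].mean()
        assert mean_ind <= mean_full / 2

    def test_insufficient_states_rejected(self, gt_model_n10):
        states = np.ones((5, 10), np.uint8)
        with pytest.raises(ValueError, match="at least 10"):
            pi_dwell_correlation(gt_model_n10, states)

    def test_mixed_spike_counts_rejected(self, gt_model_n10):
        states = np.zeros((10, 10), np.uint8)
        states[:, 0] = 1
        states[0, 1] = 1
        with pytest.raises(ValueError, match="one spike count"):
            pi_dwell_correlation(gt_model_n10, states)
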