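from types import SimpleNamespace

import numpy as np
import pytest

from polikst import (
    Domain,
    LevelSet,
    PolimParameters,
    PolytomousStructure,
    em_fit,
    em_fit_constrained,
    enumerate_patterns,
    identifiability_check,
    is_delta_half_monotone,
    manhattan_metric,
    posterior_states,
    simulate_responses,
)
from polikst.em import default_init, default_rate_init
from polikst.model import marginal_pattern_prob
from polikst.monotonicity import rates_to_epsilon
from polikst.structures import ResponseData

LOGLIK_SLACK = 1e-8


def assert_trace_monotone(trace):
    diffs = np.diff(trace)
    assert np.all(diffs >= -LOGLIK_SLACK)


class TestPosterior:
    def test_identity_matrices_point_mass(self, small_structure):
        L, Q = small_structure.n_levels, small_structure.n_items
        eps = np.tile(np.eye(L), (Q, 1, 1))
        params = PolimParameters(small_structure, eps, np.full(5, 0.2))
        K = small_structure.states[1]
        data = ResponseData([K], [1])
        post = posterior_states(data, params)
        expected = np.zeros(5)
        expected[1] = 1.0
        np.testing.assert_allclose(post[0], expected)

    def test_uniform_everything_gives_uniform_posterior(self, small_structure):
        L, Q, S = (small_structure.n_levels, small_structure.n_items,
                   len(small_structure))
        eps = np.full((Q, L, L), 1 / L)
        params = PolimParameters(small_structure, eps, np.full(S, 1 / S))
        data = ResponseData([(0, 1, 2)], [1])
        np.testing.assert_allclose(posterior_states(data, params)[0],
                                   np.full(S, 1 / S))

    def test_matches_bayes_rule_by_hand(self):
        # two states, two items: P(K|R) prop. to P(R|K) pi_K
        structure = PolytomousStructure(Domain.from_count(2),
                                        LevelSet.from_count(2),
                                        [(0, 0), (1, 1)])
        params = PolimParameters.from_blim(structure, [0.1, 0.2], [0.15, 0.25],
                                           [0.3, 0.7])
        R = (1, 0)
        p_r_k0 = 0.15 * (1 - 0.25)
        p_r_k1 = (1 - 0.1) * 0.2
        expected = np.array([p_r_k0 * 0.3, p_r_k1 * 0.7])
        expected /= expected.sum()
        post = posterior_states(ResponseData([R], [1]), params)
        np.testing.assert_allclose(post[0], expected, atol=1e-14)
        assert post[0].sum() == pytest.approx(1.0)


class TestUnconstrainedEM:
    def test_single_state_closed_form(self, rng):
        structure = PolytomousStructure(Domain.from_count(2),
                                        LevelSet.from_count(3), [(1, 2)])
        rows = rng.integers(0, 3, size=(60, 2))
        data = ResponseData.from_responses(rows)
        fit = em_fit(data, structure, max_iter=50)
        assert fit.params.pi[0] == pytest.approx(1.0)
        for q in range(2):
            latent = structure.states[0][q]
            observed = np.bincount(rows[:, q], minlength=3) / 60
            np.testing.assert_allclose(fit.params.epsilon[q, latent],
                                       observed, atol=1e-9)

    def test_noiseless_patterns_recover_frequencies(self, small_structure):
        idx = [0, 0, 2, 2, 2, 4]
        rows = small_structure.states[idx]
        data = ResponseData.from_responses(rows)
        fit = em_fit(data, small_structure, tol=1e-10, max_iter=500)
        pi_hat = fit.params.pi
        assert pi_hat[0] == pytest.approx(2 / 6, abs=1e-6)
        assert pi_hat[2] == pytest.approx(3 / 6, abs=1e-6)
        assert pi_hat[4] == pytest.approx(1 / 6, abs=1e-6)

    def test_loglik_never_decreases(self, small_params, rng):
        data, _ = simulate_responses(small_params, 300, rng)
        fit = em_fit(data, small_params.structure, tol=1e-9, max_iter=400)
        assert_trace_monotone(fit.loglik_trace)

    def test_fixed_point_on_exact_expected_data(self, small_params):
        """Starting at the truth with expected pattern frequencies, one EM
        update leaves the parameters unchanged (stationarity)."""
        structure = small_params.structure
        pats = enumerate_patterns(structure.domain, structure.levels)
        probs = np.array([marginal_pattern_prob(R, small_params)
                          for R in pats])
        exact = SimpleNamespace(patterns=pats, frequencies=probs,
                                n=1.0)
        fit = em_fit(exact, structure, init=small_params, tol=0.0, max_iter=2)
        np.testing.assert_allclose(fit.params.epsilon, small_params.epsilon,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.params.pi, small_params.pi, atol=1e-8)

    def test_parameter_recovery_large_sample(self, recovery_params):
        data, _ = simulate_responses(recovery_params, 20000, seed=31)
        fit = em_fit(data, recovery_params.structure, tol=1e-8, max_iter=3000)
        assert np.abs(fit.params.epsilon - recovery_params.epsilon).max() < 0.05
        assert np.abs(fit.params.pi - recovery_params.pi).max() < 0.03

    def test_structure_mismatch_rejected(self, small_structure):
        data = ResponseData([(0, 1)], [1])
        with pytest.raises(ValueError):
            em_fit(data, small_structure)


class TestConstrainedEM:
    def make_monotone_truth(self, structure, rng):
        rates = default_rate_init(structure)
        for r in rates:
            mu, mo = ~np.isnan(r.upsilon), ~np.isnan(r.omega)
            r.upsilon[mu] = rng.uniform(0.05, 0.35, mu.sum())
            r.omega[mo] = rng.uniform(0.05, 0.35, mo.sum())
        eps = np.stack([rates_to_epsilon(r).probs for r in rates])
        S = structure.n_states
        return PolimParameters(structure, eps, np.full(S, 1 / S)), rates

    def test_rows_half_monotone_and_trace_monotone(self, small_structure, rng):
        truth, _ = self.make_monotone_truth(small_structure, rng)
        data, _ = simulate_responses(truth, 400, rng)
        fit = em_fit_constrained(data, small_structure, tol=1e-7, max_iter=150)
        assert_trace_monotone(fit.loglik_trace)
        metric = manhattan_metric(small_structure.n_levels)
        for q in range(small_structure.n_items):
            half, _ = is_delta_half_monotone(fit.params.epsilon[q], metric)
            assert half
        for r in fit.rates:
            assert r.in_open_unit_interval()

    def test_recovers_rate_truth_at_large_n(self, recovery_params, rng):
        structure = recovery_params.structure
        truth, _ = self.make_monotone_truth(structure, rng)
        data, _ = simulate_responses(truth, 20000, seed=77)
        fit = em_fit_constrained(data, structure, tol=1e-7, max_iter=800)
        assert np.abs(fit.params.epsilon - truth.epsilon).max() < 0.05
        assert np.abs(fit.params.pi - truth.pi).max() < 0.03

    def test_agrees_with_unconstrained_when_truth_monotone(
            self, recovery_params, rng):
        structure = recovery_params.structure
        truth, _ = self.make_monotone_truth(structure, rng)
        data, _ = simulate_responses(truth, 5000, seed=13)
        unc = em_fit(data, structure, tol=1e-8, max_iter=2000)
        con = em_fit_constrained(data, structure, tol=1e-8, max_iter=800)
        assert np.abs(unc.params.epsilon - con.params.epsilon).mean() < 0.01


class TestIdentifiability:
    def test_identifiable_small_model(self, recovery_params, rng):
        data, _ = simulate_responses(recovery_params, 4000, rng)
        rep = identifiability_check(data, recovery_params.structure,
                                    n_restarts=4, seed=2, tol=1e-9,
                                    max_iter=4000)
        assert rep["max_param_sd"] < 1e-3

    def test_label_swap_symmetry_flagged(self):
        # two exchangeable states (identical rows) cannot be told apart:
        # different starts land on mirrored solutions with equal likelihood
        structure = PolytomousStructure(Domain.from_count(1),
                                        LevelSet.from_count(2), [(0,), (1,)])
        rows = np.array([[0]] * 50 + [[1]] * 50)
        data = ResponseData.from_responses(rows)
        rep = identifiability_check(data, structure, n_restarts=8, seed=4,
                                    loglik_window=1e-6, tol=1e-10,
                                    max_iter=3000)
        assert rep["max_param_sd"] > 1e-2

    def test_restart_count_validated(self, small_params, rng):
        data, _ = simulate_responses(small_params, 50, rng)
        with pytest.raises(ValueError):
            identifiability_check(data, small_params.structure, n_restarts=1,
                                  seed=0)
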