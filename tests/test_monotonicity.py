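import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polikst import (
    LevelMetric,
    LevelSet,
    PairFunction,
    RateParameters,
    check_metric_axioms,
    check_modality,
    check_overall_error,
    column_view,
    epsilon_to_rates,
    hamming_metric,
    is_delta_half_monotone,
    is_delta_monotone,
    is_order_respecting,
    manhattan_metric,
    rates_to_epsilon,
    restricted_triples,
)
from polikst.model import ErrorMatrix

from conftest import DELTA1_3, DELTA1_4, DELTA2_3, F1_4, WORKED_ROW


def worked_rates():
    r = RateParameters.from_flat(None, np.full(20, 0.5), 5)
    r.upsilon[2, 0] = 0.2
    r.upsilon[2, 1] = 0.1
    r.omega[2, 3] = 0.3
    r.omega[2, 4] = 0.5
    return r


class TestMetrics:
    def test_hamming_values(self):
        m = hamming_metric(4)
        assert m(2, 2) == 0 and m(0, 3) == 1 and m(1, 2) == 1

    def test_manhattan_chain_values(self, chain4):
        m = manhattan_metric(chain4)
        assert (m(0, 1), m(0, 2), m(0, 3)) == (1, 2, 3)
        assert m(2, 2) == 0

    def test_manhattan_equals_downset_symmetric_difference(self):
        # |down(i) \ down(j) u down(j) \ down(i)| on a 5-chain
        m = manhattan_metric(5)
        for i in range(5):
            for j in range(5):
                di = set(range(i + 1))
                dj = set(range(j + 1))
                assert m(i, j) == len(di ^ dj)

    def test_axioms_pass_for_standard_metrics(self):
        for m in (manhattan_metric(5), hamming_metric(4)):
            rep = check_metric_axioms(m)
            assert rep["symmetry"] and rep["identity"] and rep["triangle"]

    def test_worked_dissimilarity_violates_triangle(self):
        rep = check_metric_axioms(LevelMetric(DELTA1_4))
        assert not rep["triangle"]
        # witness (a, b, d): 5 > 1 + 3
        assert (0, 1, 3) in rep["witnesses"]

    def test_order_respecting(self):
        ok, _ = is_order_respecting(manhattan_metric(5))
        assert ok
        ok, _ = is_order_respecting(LevelMetric(DELTA1_4))
        assert ok  # all 4 increasing triples satisfy the strict growth
        ok, bad = is_order_respecting(hamming_metric(3))
        assert not ok and bad  # constant off-diagonal violates strictness


class TestRestrictedTriples:
    def test_counts_on_the_4_chain(self):
        triples = restricted_triples(4)
        assert len(triples) == 44
        assert 4 ** 3 == 64  # out of the full triple count

    def test_count_on_the_2_chain(self):
        assert len(restricted_triples(2)) == 6

    def test_mixed_side_triples_excluded(self):
        triples = set(restricted_triples(4))
        assert (2, 3, 0) not in triples  # j above i, k below i
        assert (0, 1, 2) in triples
        assert (3, 0, 1) in triples


class TestDeltaMonotonicity:
    def test_worked_counterexample_with_witness(self):
        ok, violations = is_delta_monotone(F1_4, LevelMetric(DELTA1_4))
        assert not ok
        # the printed witness (c, d, a): delta 1 < 3 but f 4 < 7
        assert (2, 3, 0) in violations

    def test_partial_function_monotone_under_one_metric_only(self):
        f2 = PairFunction({(1, 0): 0.2, (1, 2): 0.1}, 3)
        ok1, _ = is_delta_monotone(f2, LevelMetric(DELTA1_3))
        ok2, bad2 = is_delta_monotone(f2, LevelMetric(DELTA2_3))
        assert ok1
        assert not ok2 and bad2

    def test_negated_metric_is_monotone(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        ok, _ = is_delta_monotone(-d, LevelMetric(d))
        assert ok

    def test_monotone_implies_half_monotone(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 6))
            d = manhattan_metric(n)
            f = np.exp(-d.dist) + rng.normal(0, 1e-12, (n, n))
            full, _ = is_delta_monotone(f, d)
            if full:
                half, _ = is_delta_half_monotone(f, d)
                assert half

    def test_worked_full_violation_is_not_a_restricted_triple(self):
        ok, violations = is_delta_half_monotone(F1_4, LevelMetric(DELTA1_4))
        assert (2, 3, 0) not in violations
        assert (2, 3, 0) not in set(restricted_triples(4))


class TestRowConditions:
    def test_modality_of_worked_row(self):
        E = np.tile(WORKED_ROW, (5, 1))
        # make it row-stochastic with the worked row everywhere; modality of
        # row 2 holds, rows 0/1 have their maximum off-diagonal
        assert check_modality(np.eye(4) * 0.9 + 0.1 / 3 * (1 - np.eye(4)))
        full = np.array([np.roll(WORKED_ROW, k - 2) for k in range(5)])
        assert check_modality(full)

    def test_modality_requires_strict_inequality(self):
        E = np.full((3, 3), 1 / 3)
        assert not check_modality(E)

    def test_overall_error(self):
        assert WORKED_ROW[2] > WORKED_ROW.sum() - WORKED_ROW[2]
        full = np.array([np.roll(WORKED_ROW, k - 2) for k in range(5)])
        assert check_overall_error(full)
        assert not check_overall_error(np.full((2, 2), 0.5))
        ok = np.eye(3) * 0.95 + 0.025 * (1 - np.eye(3))
        assert check_overall_error(ok)

    def test_overall_error_implies_diagonal_above_half(self, rng):
        for _ in range(20):
            E = rng.dirichlet(np.ones(4), size=4)
            if check_overall_error(E):
                assert np.all(np.diag(E) > 0.5)

    def test_column_view_is_transpose_and_involutive(self, rng):
        E = rng.dirichlet(np.ones(3), size=3)
        f = column_view(E)
        for i in range(3):
            for j in range(3):
                assert f.get(i, j) == E[j, i]
                assert f.transpose().get(i, j) == E[i, j]

    def test_dichotomous_column_monotonicity_conditions(self):
        # column monotonicity under the Manhattan metric on {0,1} is
        # beta < 1 - eta and eta < 1 - beta
        m = manhattan_metric(2)
        for beta, eta in [(0.1, 0.2), (0.6, 0.5), (0.45, 0.5)]:
            E = np.array([[1 - eta, eta], [beta, 1 - beta]])
            ok, _ = is_delta_monotone(column_view(E), m)
            assert ok == (beta < 1 - eta and eta < 1 - beta)


class TestRateReparameterization:
    def test_worked_example_row_exact(self):
        E = rates_to_epsilon(worked_rates())
        np.testing.assert_allclose(E.probs[2], WORKED_ROW, rtol=1e-14)
        assert E.probs[2].sum() == pytest.approx(1.0, abs=1e-14)

    def test_worked_row_half_but_not_fully_monotone(self):
        E = rates_to_epsilon(worked_rates())
        half, _ = is_delta_half_monotone(E.probs, manhattan_metric(5))
        assert half
        full, violations = is_delta_monotone(E.probs, manhattan_metric(5))
        assert not full
        # eps(2,4)=15/157 > eps(2,1)=10/157 breaks full monotonicity
        assert E.probs[2, 4] > E.probs[2, 1]

    def test_two_level_closed_form(self):
        x = 0.3
        r = RateParameters.from_flat(None, np.array([x, 0.5]), 2)
        E = rates_to_epsilon(r)
        np.testing.assert_allclose(E.probs[0], [1 / (1 + x), x / (1 + x)])

    def test_rate_outside_unit_interval_rejected(self):
        r = worked_rates()
        r.omega[2, 3] = 1.2
        with pytest.raises(ValueError):
            rates_to_epsilon(r)

    def test_recovers_worked_rates(self):
        E = rates_to_epsilon(worked_rates())
        back = epsilon_to_rates(E)
        assert back.upsilon[2, 0] == pytest.approx(0.2)
        assert back.upsilon[2, 1] == pytest.approx(0.1)
        assert back.omega[2, 3] == pytest.approx(0.3)
        assert back.omega[2, 4] == pytest.approx(0.5)

    def test_uniform_row_rates_flagged(self):
        E = np.full((3, 3), 1 / 3)
        back = epsilon_to_rates(E)
        assert not back.in_open_unit_interval()
        np.testing.assert_allclose(back.defined_rates(), 1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 6))
    def test_roundtrip_and_half_monotonicity(self, seed, n):
        rng = np.random.default_rng(seed)
        r = RateParameters.from_flat(None, rng.uniform(0.02, 0.98,
                                                       n * (n - 1)), n)
        E = rates_to_epsilon(r)
        np.testing.assert_allclose(E.probs.sum(axis=1), 1.0, atol=1e-12)
        half, _ = is_delta_half_monotone(E.probs, manhattan_metric(n))
        assert half
        back = rates_to_epsilon(epsilon_to_rates(E))
        np.testing.assert_allclose(back.probs, E.probs, atol=1e-12)
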