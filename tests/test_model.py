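"""Core model: testlet designs, probabilities, simulation, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicetrt.model import (
    ItemParameters,
    PersonParameters,
    TestletDesign,
    log_likelihood,
    probability_matrix,
    response_probability,
    simulate_responses,
    testlet_discrimination,
    validate_responses,
)


class TestTestletDesign:
    def test_uniform_partition(self):
        d = TestletDesign.uniform(4, 5)
        assert d.n_items == 20 and d.n_testlets == 4
        assert d.sizes.tolist() == [5, 5, 5, 5]
        assert sorted(np.concatenate([d.members(k) for k in range(4)])) == list(range(20))

    def test_from_groups_round_trip(self):
        groups = {"1": [1, 2], "2": [3, 4]}
        d = TestletDesign.from_groups(groups)
        assert d.n_testlets == 2 and d.sizes.tolist() == [2, 2]
        assert d.to_groups() == groups

    def test_empirical_design_shape(self):
        # 28 items in testlets of 8, 7, 8 and 5 (a reading-comprehension layout)
        groups = {"1": list(range(1, 9)), "2": list(range(9, 16)),
                  "3": list(range(16, 24)), "4": list(range(24, 29))}
        d = TestletDesign.from_groups(groups)
        assert d.sizes.tolist() == [8, 7, 8, 5]

    @pytest.mark.parametrize("groups", [
        {"1": [1, 2, 3], "2": [3, 4]},        # duplicated item
        {"1": [1, 2], "2": [4, 5]},           # missing item 3
        {"1": [1, 2], "3": [3, 4]},           # non-contiguous labels
    ])
    def test_invalid_partitions_rejected(self, groups):
        with pytest.raises(ValueError):
            TestletDesign.from_groups(groups)


class TestTestletDiscrimination:
    def test_constant_and_mean(self):
        d1 = TestletDesign(np.zeros(5, dtype=int))
        assert testlet_discrimination(np.ones(5), d1).tolist() == [1.0]
        d2 = TestletDesign(np.array([0, 0, 1, 1]))
        assert testlet_discrimination(np.array([1.0, 3.0, 2.0, 2.0]), d2).tolist() == [2.0, 2.0]

    def test_reading_test_estimates(self):
        # Five fitted discriminations of one five-item testlet average directly.
        a = np.array([2.0055, 0.7821, 1.5236, 1.1934, 0.6847])
        d = TestletDesign(np.zeros(5, dtype=int))
        assert testlet_discrimination(a, d)[0] == pytest.approx(1.23786, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            testlet_discrimination(np.ones(3), TestletDesign(np.array([0, 0])))


class TestResponseProbability:
    @pytest.mark.parametrize("model", ["2pl", "t2pltm", "n2pltm"])
    def test_half_probability_at_difficulty(self, model):
        p = response_probability(model, theta=0.7, a=1.4, b=0.7, eta=0.0, alpha=1.0)
        assert p == pytest.approx(0.5)

    def test_logistic_at_one(self):
        p = response_probability("n2pltm", theta=1.0, a=1.0, b=0.0, eta=0.0, alpha=2.0)
        assert p == pytest.approx(0.731059, abs=1e-6)

    def test_non_positive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            response_probability("2pl", theta=0.0, a=0.0, b=0.0)

    @given(theta=st.floats(-3, 3), b=st.floats(-3, 3), a=st.floats(0.1, 3),
           eta=st.floats(-2, 2), alpha=st.floats(0.1, 3))
    @settings(max_examples=100, deadline=None)
    def test_complement_and_monotonicity(self, theta, b, a, eta, alpha):
        p = response_probability("n2pltm", theta, a, b, eta, alpha)
        assert 0.0 < p < 1.0
        assert p + (1.0 - p) == pytest.approx(1.0, abs=1e-12)
        eps = 1e-4
        assert response_probability("n2pltm", theta + eps, a, b, eta, alpha) > p
        assert response_probability("n2pltm", theta, a, b + eps, eta, alpha) < p
        assert response_probability("n2pltm", theta, a, b, eta + eps, alpha) > p

    def test_zero_eta_reduces_to_2pl(self, rng):
        for _ in range(50):
            theta, b = rng.normal(size=2)
            a, alpha = rng.uniform(0.2, 2.5, size=2)
            assert response_probability("n2pltm", theta, a, b, 0.0, alpha) == \
                pytest.approx(response_probability("2pl", theta, a, b))

    def test_equal_discrimination_reduction(self, rng):
        """Per-testlet constant a makes n2pltm and t2pltm cellwise identical."""
        design = TestletDesign(np.array([0, 0, 1, 1, 1]))
        a = np.array([0.9, 0.9, 1.7, 1.7, 1.7])
        b = rng.normal(size=5)
        persons = PersonParameters(rng.normal(size=4), rng.normal(size=(4, 2)))
        items = ItemParameters(a, b)
        np.testing.assert_allclose(
            probability_matrix(items, persons, design, "n2pltm"),
            probability_matrix(items, persons, design, "t2pltm"),
        )


class TestSimulateResponses:
    def test_deterministic_and_binary(self, toy_state, two_testlet_design):
        y1 = simulate_responses(toy_state.items, toy_state.persons,
                                two_testlet_design, seed=123)
        y2 = simulate_responses(toy_state.items, toy_state.persons,
                                two_testlet_design, seed=123)
        np.testing.assert_array_equal(y1, y2)
        assert set(np.unique(y1)) <= {0, 1}

    def test_degenerate_probability_gives_all_ones(self, two_testlet_design):
        items = ItemParameters(np.ones(4), np.full(4, -50.0))
        persons = PersonParameters(np.zeros(6), np.zeros((6, 2)))
        y = simulate_responses(items, persons, two_testlet_design, seed=0)
        assert y.min() == 1

    def test_sample_mean_matches_probability(self):
        n = 2000
        design = TestletDesign(np.array([0]))
        items = ItemParameters(np.array([1.0]), np.array([-1.0]))
        persons = PersonParameters(np.zeros(n), np.zeros((n, 1)))
        y = simulate_responses(items, persons, design, seed=5)
        p = 0.731059
        assert abs(y.mean() - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestLogLikelihood:
    def test_single_cell(self):
        design = TestletDesign(np.array([0]))
        items = ItemParameters(np.array([1.0]), np.array([0.0]))
        persons = PersonParameters(np.zeros(1), np.zeros((1, 1)))
        ll = log_likelihood(np.array([[1]]), items, persons, design)
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_brute_force_product(self, toy_state, toy_data, two_testlet_design):
        """Cellwise product of Bernoulli likelihoods, then log."""
        p = probability_matrix(toy_state.items, toy_state.persons,
                               two_testlet_design, "n2pltm")
        brute = 1.0
        for i in range(toy_data.shape[0]):
            for j in range(toy_data.shape[1]):
                brute *= p[i, j] if toy_data[i, j] else 1 - p[i, j]
        ll = log_likelihood(toy_data, toy_state.items, toy_state.persons,
                            two_testlet_design, "n2pltm")
        assert ll == pytest.approx(np.log(brute))
        # additivity: duplicating every person doubles the log-likelihood
        doubled = PersonParameters(
            np.repeat(toy_state.persons.theta, 2),
            np.repeat(toy_state.persons.eta, 2, axis=0),
        )
        ll2 = log_likelihood(np.repeat(toy_data, 2, axis=0), toy_state.items,
                             doubled, two_testlet_design, "n2pltm")
        assert ll2 == pytest.approx(2 * ll)


class TestValidation:
    def test_non_binary_cell_located(self):
        with pytest.raises(ValueError, match="row 2, column 1"):
            validate_responses(np.array([[0, 1], [2, 0]]))

    def test_positive_discrimination_enforced(self):
        with pytest.raises(ValueError):
            ItemParameters(np.array([1.0, -0.2]), np.zeros(2))
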