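"""Slice-Gibbs machinery: auxiliary draws, truncation bounds, conjugate updates."""

import math

import numpy as np
import pytest
from scipy import stats

from slicetrt.model import (
    ItemParameters,
    PersonParameters,
    PriorConfig,
    TestletDesign,
    VarianceState,
    probability_matrix,
)
from slicetrt.sampler import (
    MCMCConfig,
    ParameterState,
    UpdateFlags,
    ability_bounds,
    difficulty_bounds,
    discrimination_bounds,
    log_unnormalized_posterior,
    run_chain,
    sample_auxiliary,
    sample_truncated_normal,
    sample_variance_a,
    sample_variance_b,
    sample_variance_eta,
    testlet_effect_bounds,
)

LOGIT_E = math.e / (1 + math.e)  # logit(LOGIT_E) = 1


def _single_item_state(theta, a=1.0, b=0.0, eta=0.0):
    return ParameterState(
        ItemParameters(np.array([a]), np.array([b]), fixed=()),
        PersonParameters(np.atleast_1d(theta),
                         np.full((np.atleast_1d(theta).size, 1), eta)),
        VarianceState(1.0, 1.0, np.ones(1)),
    )


class TestAuxiliary:
    def test_support_and_mean(self, rng):
        """lambda ~ U(0, p) on y=1 cells, phi ~ U(0, q) on y=0 cells."""
        state = _single_item_state(np.zeros(10000), a=1.0, b=-1.3863)  # p ~= 0.8
        design = TestletDesign(np.array([0]))
        Y = np.tile([[1]], (10000, 1))
        lam, phi = sample_auxiliary(Y, state, design, "n2pltm", rng)
        p = probability_matrix(state.items, state.persons, design)[0, 0]
        assert np.all(lam > 0) and np.all(lam <= p)
        assert np.isnan(phi).all()
        assert lam.mean() == pytest.approx(p / 2, abs=4 * p / np.sqrt(12 * 10000))
        lam0, phi0 = sample_auxiliary(1 - Y, state, design, "n2pltm", rng)
        assert np.all(phi0 > 0) and np.all(phi0 <= 1 - p)
        assert np.isnan(lam0).all()


class TestBounds:
    def test_vacuous_constraints(self):
        """theta = b and eta = 0 makes c = 0: no cell constrains a_j."""
        state = _single_item_state(np.zeros(3))
        lo, hi = discrimination_bounds(
            0, np.array([[1], [0], [1]]),
            np.full((3, 1), 0.3), np.full((3, 1), 0.3),
            state, TestletDesign(np.array([0])), "n2pltm")
        assert (lo, hi) == (0.0, np.inf)

    def test_single_person_discrimination(self):
        """Singleton testlet, theta-b+eta = 1: logit(lam) = 1 gives a_L = 1."""
        state = _single_item_state(np.array([1.0]))
        design = TestletDesign(np.array([0]))
        lam = np.array([[LOGIT_E]])
        lo, hi = discrimination_bounds(0, np.array([[1]]), lam,
                                       np.full((1, 1), np.nan), state, design)
        assert lo == pytest.approx(1.0) and hi == np.inf
        phi = np.array([[1 - LOGIT_E]])  # log((1-phi)/phi) = 1
        lo, hi = discrimination_bounds(0, np.array([[0]]),
                                       np.full((1, 1), np.nan), phi, state, design)
        assert lo == 0.0 and hi == pytest.approx(1.0)

    def test_sibling_cells_constrain_discrimination(self):
        """Under the n2pltm, a_j is bounded by every cell of its testlet."""
        design = TestletDesign(np.array([0, 0]))
        state = ParameterState(
            ItemParameters(np.array([1.0, 1.0]), np.zeros(2), fixed=()),
            PersonParameters(np.zeros(1), np.array([[2.0]])),
            VarianceState(1.0, 1.0, np.ones(1)),
        )
        # Item 1's own cell: c = eta/n_d = 1 > 0.  Item 2's cell also involves
        # a_1 with coefficient eta/n_d = 1.
        Y = np.array([[1, 1]])
        lam = np.full((1, 2), LOGIT_E)
        lo, hi = discrimination_bounds(0, Y, lam, np.full((1, 2), np.nan),
                                       state, design, "n2pltm")
        # own column: a*1 >= 1 - (a_2/2)*2 = 0; sibling: a*1 >= 1 - 0 - 1 = 0
        assert lo == pytest.approx(0.0) and hi == np.inf
        # flip the sibling to y=0 with a tight phi: upper bound appears
        phi = np.full((1, 2), np.nan)
        phi[0, 1] = 1 - LOGIT_E
        Y2 = np.array([[1, 0]])
        lam2 = np.full((1, 2), np.nan)
        lam2[0, 0] = LOGIT_E
        lo2, hi2 = discrimination_bounds(0, Y2, lam2, phi, state, design, "n2pltm")
        assert np.isfinite(hi2)

    def test_difficulty_bounds_symmetry(self):
        """One person, a=1, theta=0, mid-slice variables give one-sided 0 bounds."""
        state = _single_item_state(np.array([0.0]))
        design = TestletDesign(np.array([0]))
        lam = np.array([[0.5]])
        lo, hi = difficulty_bounds(0, np.array([[1]]), lam,
                                   np.full((1, 1), np.nan), state, design)
        assert lo == -np.inf and hi == pytest.approx(0.0)
        phi = np.array([[0.5]])
        lo, hi = difficulty_bounds(0, np.array([[0]]),
                                   np.full((1, 1), np.nan), phi, state, design)
        assert lo == pytest.approx(0.0) and hi == np.inf

    def test_ability_lower_bound(self):
        state = _single_item_state(np.array([0.0]))
        design = TestletDesign(np.array([0]))
        lam = np.array([[0.731059]])
        lo, hi = ability_bounds(np.array([[1]]), lam, np.full((1, 1), np.nan),
                                state, design)
        assert lo[0] == pytest.approx(1.0, abs=1e-5) and hi[0] == np.inf

    def test_testlet_effect_bounds(self):
        """Single-item testlet y=1 gives eta_L = logit(lam); all-correct
        testlets leave eta_U = +inf; the max over candidates binds."""
        state = _single_item_state(np.array([0.0]))
        design = TestletDesign(np.array([0]))
        lam = np.array([[LOGIT_E]])
        lo, hi = testlet_effect_bounds(0, np.array([[1]]), lam,
                                       np.full((1, 1), np.nan), state, design)
        assert lo[0] == pytest.approx(1.0) and hi[0] == np.inf
        # two-item testlet, candidates 0.3 and 0.7 -> max binds
        design2 = TestletDesign(np.array([0, 0]))
        state2 = ParameterState(
            ItemParameters(np.ones(2), np.zeros(2), fixed=()),
            PersonParameters(np.zeros(1), np.zeros((1, 1))),
            VarianceState(1.0, 1.0, np.ones(1)),
        )
        lam2 = np.array([[1 / (1 + np.exp(-0.3)), 1 / (1 + np.exp(-0.7))]])
        lo2, _ = testlet_effect_bounds(0, np.array([[1, 1]]), lam2,
                                       np.full((1, 2), np.nan), state2, design2)
        assert lo2[0] == pytest.approx(0.7)


class TestTruncatedNormal:
    def test_half_normal_mean(self, rng):
        x = sample_truncated_normal(0.0, 1.0, np.zeros(50000), np.full(50000, np.inf), rng)
        assert np.all(x >= 0)
        assert x.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_degenerate_interval(self, rng):
        assert sample_truncated_normal(0.0, 1.0, 1.0, 1.0 + 1e-14, rng) == \
            pytest.approx(1.0, abs=1e-9)

    def test_deep_tail_stays_in_bounds(self, rng):
        x = sample_truncated_normal(0.0, 1.0, np.full(2000, 9.0), np.full(2000, 9.5), rng)
        assert np.all((x >= 9.0) & (x <= 9.5))
        # conditional tail mean ~ lo + 1/lo for a far-tail exponential profile
        assert x.mean() == pytest.approx(9.0 + 1 / 9.0, abs=0.05)


class TestVarianceUpdates:
    def test_parameter_mapping(self, rng):
        """J=2, v1=tau1=1, a=(mu, mu+2) -> IG(2, 3); draws match IG moments."""
        prior = PriorConfig(v1=1.0, tau1=1.0, mu_a=0.5)
        draws = np.array([sample_variance_a(np.array([0.5, 2.5]), prior, rng)
                          for _ in range(20000)])
        # IG(2, 3): mean 3, no finite variance -> compare medians instead
        assert np.median(draws) == pytest.approx(stats.invgamma.median(2, scale=3),
                                                 rel=0.05)

    def test_empirical_mean_matches_inverse_gamma(self, rng):
        """IG(10.001, 10.001) from J=20, sum of squares 20."""
        a = np.full(20, 1.0)  # sum (a - 0)^2 / 2 = 10
        prior = PriorConfig()
        draws = np.array([sample_variance_a(a, prior, rng) for _ in range(50000)])
        expect = 10.001 / 9.001
        se = stats.invgamma.std(10.001, scale=10.001) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(expect, abs=3 * se)

    def test_zero_spread_gives_scale_tau(self, rng):
        prior = PriorConfig(v2=2.0, tau2=0.5, mu_b=1.0)
        draws = np.array([sample_variance_b(np.full(4, 1.0), prior, rng)
                          for _ in range(20000)])
        # IG(4, 0.5): mean tau'/(v'-1) = 0.5/3
        se = stats.invgamma.std(4, scale=0.5) / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(0.5 / 3, abs=3 * se)

    def test_eta_variance_concentrates(self, rng):
        """Large-n conjugate posterior concentrates at the empirical variance."""
        eta = rng.normal(0, 0.5, size=5000)
        prior = PriorConfig()
        draws = np.array([sample_variance_eta(eta, prior, rng) for _ in range(2000)])
        post_sd = stats.invgamma.std(2500.001, scale=(eta**2).sum() / 2 + 0.001)
        assert abs(draws.mean() - 0.25) < 3 * (post_sd + 0.25 / np.sqrt(2500))


class TestChainContracts:
    def test_seeded_determinism_and_identification(self, rng):
        design = TestletDesign.uniform(2, 5)
        items = ItemParameters(np.r_[1.0, rng.uniform(0.4, 1.6, 9)],
                               np.r_[0.0, rng.normal(size=9)])
        persons = PersonParameters(rng.normal(size=50), rng.normal(size=(50, 2)) * 0.5)
        from slicetrt.model import simulate_responses
        Y = simulate_responses(items, persons, design, seed=3)
        cfg = MCMCConfig(iterations=400, burn_in=200, chains=1, seed=99, start="fixed")
        d1 = run_chain(Y, design, "n2pltm", cfg)
        d2 = run_chain(Y, design, "n2pltm", cfg)
        for key, block in d1.blocks().items():
            np.testing.assert_array_equal(block, d2.blocks()[key])
        # identification-fixed parameters never move
        assert np.all(d1.a[:, 0] == 1.0) and np.all(d1.b[:, 0] == 0.0)

    def test_degenerate_matrix_rejected(self, two_testlet_design):
        cfg = MCMCConfig(iterations=10, burn_in=5, chains=1)
        with pytest.raises(ValueError, match="degenerate"):
            run_chain(np.ones((4, 4), dtype=np.int8), two_testlet_design,
                      "n2pltm", cfg)


class TestLogUnnormalizedPosterior:
    def test_additivity_under_duplication(self, toy_state, toy_data,
                                          two_testlet_design):
        prior = PriorConfig()
        lp = log_unnormalized_posterior(toy_state, toy_data, two_testlet_design,
                                        prior)
        assert np.isfinite(lp)
        doubled = ParameterState(
            toy_state.items,
            PersonParameters(np.repeat(toy_state.persons.theta, 2),
                             np.repeat(toy_state.persons.eta, 2, axis=0)),
            toy_state.variances,
        )
        lp2 = log_unnormalized_posterior(doubled, np.repeat(toy_data, 2, axis=0),
                                         two_testlet_design, prior)
        from slicetrt.model import log_likelihood
        ll = log_likelihood(toy_data, toy_state.items, toy_state.persons,
                            two_testlet_design)
        extra_prior = -0.5 * np.sum(toy_state.persons.theta**2) \
            - 0.5 * np.sum(toy_state.persons.eta**2) \
            - 0.5 * toy_state.persons.theta.size * 2 * np.log(1.0)
        assert lp2 - lp == pytest.approx(ll + extra_prior, rel=1e-9)

    def test_ratio_matches_brute_force(self, toy_state, toy_data,
                                       two_testlet_design):
        """Posterior ratio between two states equals the brute-force product
        of likelihood and prior density ratios on a small instance."""
        prior = PriorConfig()
        other = ParameterState(
            ItemParameters(toy_state.items.a * 1.2, toy_state.items.b + 0.1),
            toy_state.persons, toy_state.variances,
        )
        from slicetrt.model import log_likelihood
        delta = log_unnormalized_posterior(other, toy_data, two_testlet_design, prior) \
            - log_unnormalized_posterior(toy_state, toy_data, two_testlet_design, prior)
        ll_delta = (log_likelihood(toy_data, other.items, other.persons, two_testlet_design)
                    - log_likelihood(toy_data, toy_state.items, toy_state.persons,
                                     two_testlet_design))
        prior_delta = (-np.sum((other.items.a - 0)**2) / 2 - np.sum((other.items.b - 0)**2) / 2
                       + np.sum((toy_state.items.a - 0)**2) / 2
                       + np.sum((toy_state.items.b - 0)**2) / 2)
        assert delta == pytest.approx(ll_delta + prior_delta, rel=1e-9)

    def test_out_of_support(self, toy_state, toy_data, two_testlet_design):
        bad = ParameterState(
            toy_state.items, toy_state.persons,
            VarianceState(1.0, 1.0, np.ones(2)),
        )
        object.__setattr__(bad.items, "a", np.array([1.0, -0.5, 1.0, 1.0]))
        assert log_unnormalized_posterior(bad, toy_data, two_testlet_design,
                                          PriorConfig()) == -np.inf
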