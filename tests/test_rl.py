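"""Unit and property tests for the social reinforcement-learning model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collective_cognition import (
    Environment,
    NoSocialInformation,
    RLAgentParams,
    combined_choice_prob,
    conformist_prob,
    simulate_rl_group,
    softmax_choice_prob,
    update_q,
)


@pytest.mark.parametrize("q,payoff,alpha,expected", [
    (0.0, 15.0, 0.3, 4.5),
    (20.0, 20.0, 0.3, 20.0),
    (10.0, 20.0, 1.0, 20.0),
])
def test_delta_rule_update(q, payoff, alpha, expected):
    assert update_q(q, payoff, alpha) == pytest.approx(expected)


def test_delta_rule_rejects_bad_rate():
    with pytest.raises(ValueError):
        update_q(0.0, 1.0, 1.5)


def test_delta_rule_geometric_convergence():
    """Constant payoffs drive Q to the payoff at rate (1 - alpha) per trial."""
    alpha, payoff, q = 0.3, 20.0, 0.0
    for t in range(1, 11):
        q = update_q(q, payoff, alpha)
        assert q - payoff == pytest.approx((1 - alpha) ** t * (0.0 - payoff))


class TestSoftmax:
    def test_equal_values(self):
        np.testing.assert_allclose(softmax_choice_prob((5.0, 5.0), 0.18),
                                   [0.5, 0.5])

    def test_zero_beta_ignores_values(self):
        np.testing.assert_allclose(softmax_choice_prob((1.0, 0.0), 0.0),
                                   [0.5, 0.5])

    def test_two_option_example(self):
        p = softmax_choice_prob((20.0, 15.0), 0.18)
        e1, e2 = math.exp(3.6), math.exp(2.7)
        np.testing.assert_allclose(p, [e1 / (e1 + e2), e2 / (e1 + e2)],
                                   rtol=1e-12)
        assert p[0] == pytest.approx(0.7109, abs=1e-4)

    def test_overflow_safe(self):
        p = softmax_choice_prob((1e4, 0.0), 1.0)
        assert p[0] == pytest.approx(1.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax_choice_prob((np.inf, 0.0), 1.0)


class TestConformistCopying:
    def test_proportional_at_unit_exponent(self):
        np.testing.assert_allclose(conformist_prob((3, 1), 1.0), [0.75, 0.25])

    def test_strong_conformity(self):
        np.testing.assert_allclose(conformist_prob((3, 1), 5.0),
                                   [243 / 244, 1 / 244], rtol=1e-12)

    def test_tie_symmetry(self):
        for theta in (0.3, 1.0, 5.0):
            np.testing.assert_allclose(conformist_prob((2, 2), theta),
                                       [0.5, 0.5])

    def test_all_zero_counts_signalled(self):
        with pytest.raises(NoSocialInformation):
            conformist_prob((0, 0), 2.0)

    def test_rejects_bad_exponent(self):
        with pytest.raises(ValueError):
            conformist_prob((1, 1), 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(theta=st.floats(1.01, 10.0))
    def test_conformity_amplifies_majorities(self, theta):
        assert conformist_prob((3, 1), theta)[0] > 0.75

    @settings(max_examples=100, derandomize=True)
    @given(theta=st.floats(0.05, 0.99))
    def test_anticonformity_shrinks_majorities(self, theta):
        assert conformist_prob((3, 1), theta)[0] < 0.75


class TestCombinedChoiceProb:
    def test_asocial_reduction(self):
        q, counts = (18.0, 12.0), (2, 1)
        np.testing.assert_allclose(
            combined_choice_prob(q, 0.18, counts, 0.0, 1.5),
            softmax_choice_prob(q, 0.18))

    def test_pure_copying(self):
        np.testing.assert_allclose(
            combined_choice_prob((0.0, 0.0), 1.0, (3, 1), 1.0, 1.0),
            [0.75, 0.25])

    def test_mixture_example(self):
        p = combined_choice_prob((20.0, 15.0), 0.18, (1, 3), 0.3, 1.5)
        soft = softmax_choice_prob((20.0, 15.0), 0.18)[0]
        social = 1.0 / (1.0 + 3.0**1.5)
        assert p[0] == pytest.approx(0.7 * soft + 0.3 * social, rel=1e-12)
        assert p[0] == pytest.approx(0.5461, abs=1e-4)

    def test_no_social_information_falls_back_to_softmax(self):
        q = (20.0, 15.0)
        np.testing.assert_allclose(
            combined_choice_prob(q, 0.18, (0, 0), 0.7, 5.0),
            softmax_choice_prob(q, 0.18))

    def test_label_permutation_equivariance(self):
        q, counts = (17.0, 12.0), (3, 1)
        p = combined_choice_prob(q, 0.2, counts, 0.4, 2.0)
        p_swapped = combined_choice_prob(q[::-1], 0.2, counts[::-1], 0.4, 2.0)
        np.testing.assert_allclose(p, p_swapped[::-1], rtol=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    q1=st.floats(-50, 50), q2=st.floats(-50, 50),
    beta=st.floats(0, 5), sigma=st.floats(0, 1),
    theta=st.floats(0.05, 10), n1=st.integers(0, 4), n2=st.integers(0, 4),
)
def test_probabilities_normalize(q1, q2, beta, sigma, theta, n1, n2):
    p = combined_choice_prob((q1, q2), beta, (n1, n2), sigma, theta)
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p >= 0).all()


def test_agent_params_validation():
    with pytest.raises(ValueError):
        RLAgentParams(alpha=1.2, beta=0.1)
    with pytest.raises(ValueError):
        RLAgentParams(alpha=0.3, beta=-0.1)
    with pytest.raises(ValueError):
        RLAgentParams(alpha=0.3, beta=0.1, sigma=1.5)
    with pytest.raises(ValueError):
        RLAgentParams(alpha=0.3, beta=0.1, theta=0.0)


def test_environment_reversal_swaps_means():
    env = Environment(means=(15.0, 20.0), sd=3.0, n_trials=100)
    assert env.changepoint == 50
    assert env.means_at(50) == (15.0, 20.0)
    assert env.means_at(51) == (20.0, 15.0)


class TestGroupSimulation:
    def test_reproducible(self):
        env = Environment(n_trials=30)
        agents = [RLAgentParams(0.3, 0.18, 0.3, 1.5)] * 3
        a = simulate_rl_group(agents, env, seed=11, n_replicates=4)
        b = simulate_rl_group(agents, env, seed=11, n_replicates=4)
        assert np.array_equal(a.choice, b.choice)
        assert np.array_equal(a.payoff, b.payoff)

    def test_q_trajectories_satisfy_delta_rule(self, rl_weak_conformist_trace):
        tr, env = rl_weak_conformist_trace
        R, n_t, n_a = tr.choice.shape
        q = np.full((R, n_a, 2), 0.0)
        rr, aa = np.meshgrid(np.arange(R), np.arange(n_a), indexing="ij")
        for t in range(n_t):
            np.testing.assert_array_equal(tr.q_before[:, t], q)
            c = tr.choice[:, t]
            q[rr, aa, c] += 0.3 * (tr.payoff[:, t] - q[rr, aa, c])

    def test_trial_one_is_asocial(self, rl_weak_conformist_trace):
        tr, _ = rl_weak_conformist_trace
        np.testing.assert_array_equal(tr.counts_prev[:, 0], 0)
        np.testing.assert_array_equal(tr.p_combined[:, 0], tr.p_asocial[:, 0])
        assert np.isnan(tr.p_social[:, 0]).all()

    def test_counts_exclude_self_and_sum_to_group_minus_one(
            self, rl_weak_conformist_trace):
        tr, _ = rl_weak_conformist_trace
        n_a = tr.choice.shape[2]
        assert (tr.counts_prev[:, 1:].sum(axis=-1) == n_a - 1).all()
        # agent's own previous choice is not in its counts
        prev = tr.choice[:, :-1]
        for a in range(n_a):
            others = np.delete(np.arange(n_a), a)
            nA = (prev[:, :, others] == 0).sum(axis=-1)
            np.testing.assert_array_equal(tr.counts_prev[:, 1:, a, 0], nA)

    def test_sigma_zero_reduces_to_asocial_probabilities(self):
        env = Environment(n_trials=40)
        agents = [RLAgentParams(0.3, 0.18, 0.0, 1.0)] * 4
        tr = simulate_rl_group(agents, env, seed=9, n_replicates=5)
        np.testing.assert_array_equal(tr.p_combined, tr.p_asocial)

    def test_probabilities_normalized(self, rl_weak_conformist_trace):
        tr, _ = rl_weak_conformist_trace
        assert np.allclose(tr.p_combined.sum(axis=-1), 1.0, atol=1e-12)
        assert np.allclose(tr.p_asocial.sum(axis=-1), 1.0, atol=1e-12)

    def test_single_learner_locks_onto_better_option(self):
        """Noise-free payoffs and a sharp softmax: exploit the better arm.

        Optimistic initial values guarantee both arms are sampled before
        exploitation takes over.
        """
        env = Environment(means=(15.0, 20.0), sd=0.0, n_trials=40,
                          changepoint=40)  # no effective reversal window
        agents = [RLAgentParams(alpha=1.0, beta=2.0, sigma=0.0, q0=25.0)]
        tr = simulate_rl_group(agents, env, seed=13, n_replicates=1000)
        last_quarter = tr.choice[:, 30:, 0]
        assert (last_quarter == 1).mean() > 0.95
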