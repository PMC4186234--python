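import numpy as np
import pytest

from actinfer import (
    GenerativeModel,
    PolicySet,
    infer,
    init_beliefs,
    make_policy_set,
    policy_value_matrix,
    random_model,
    update_policy_expectation,
    update_precision,
    update_state_expectation,
)
from actinfer.valuation import PolicyValueMatrix
from .oracles import (
    policy_update_direct,
    precision_update_direct,
    state_update_direct,
)


def _qvm(Q, t=1):
    return PolicyValueMatrix(Q=np.asarray(Q, dtype=float), t=t)


class TestInitBeliefs:
    def test_prior_mean_precision_is_eight(self, identity_model):
        ps = make_policy_set(identity_model.horizon, 2, "stay_then_shift")
        b = init_beliefs(identity_model, ps)
        assert b.gamma_hat == 8.0  # alpha=8, beta=1

    def test_uniform_expectations(self, small_random):
        model, _ = small_random
        ps = make_policy_set(model.horizon, 2, "exhaustive")
        b = init_beliefs(model, ps)
        np.testing.assert_allclose(b.pi_hat, 1 / ps.n_policies)
        np.testing.assert_allclose(b.s_hat[0], 1 / model.n_states)


class TestStateUpdate:
    def test_zero_precision_reduces_to_prior_prediction(self):
        # uninformative likelihood and gamma=0: posterior is the renormalized
        # one-step prediction from the previous state
        J = 3
        model = GenerativeModel(
            A=np.full((J, J), 1 / J),
            B=np.stack([np.array([[0.5, 0.2, 0.1], [0.3, 0.5, 0.2], [0.2, 0.3, 0.7]])] * 2),
            c=np.full(J, 1 / J), d=np.full(J, 1 / J), horizon=3,
        )
        Q = _qvm(np.zeros((2, J)))
        prev = np.array([1.0, 0.0, 0.0])
        obs = np.array([1.0, 0.0, 0.0])
        s = update_state_expectation(model, Q, obs, prev, 0, np.full(2, 0.5), gamma_hat=0.0)
        np.testing.assert_allclose(s, model.B[0][:, 0], atol=1e-12)

    def test_identity_likelihood_dominates(self, identity_model):
        Q = _qvm(np.zeros((2, 3)))
        obs = np.array([1.0, 0.0, 0.0])
        prev = np.full(3, 1 / 3)
        s = update_state_expectation(identity_model, Q, obs, prev, 0, np.full(2, 0.5), 1.0)
        assert s[0] > 0.999

    def test_value_term_biases_ambiguous_states(self):
        # equal likelihood columns and uniform prediction: only the
        # precision-weighted value term discriminates ("optimism bias");
        # a +1 nat advantage at gamma=2 gives softmax((0, 2))_2 = 0.8808
        J = 2
        model = GenerativeModel(
            A=np.full((2, 2), 0.5),
            B=np.stack([np.full((2, 2), 0.5)] * 2),
            c=np.full(J, 0.5), d=np.full(J, 0.5), horizon=2,
        )
        Q = _qvm([[-1.0, 0.0]])
        obs = np.array([1.0, 0.0])
        s = update_state_expectation(model, Q, obs, None, None, np.array([1.0]), gamma_hat=2.0)
        assert s[1] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-10)
        assert s[1] == pytest.approx(0.8808, abs=1e-4)

    def test_rejects_non_one_hot(self, identity_model):
        Q = _qvm(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="one-hot"):
            update_state_expectation(
                identity_model, Q, np.array([0.5, 0.5, 0.0]), None, None, np.full(2, 0.5), 1.0
            )


class TestPolicyUpdate:
    def test_zero_precision_gives_uniform(self):
        Q = _qvm(np.array([[-1.0], [-5.0], [-0.2]]))
        pi = update_policy_expectation(Q, np.array([1.0]), gamma_hat=0.0)
        np.testing.assert_allclose(pi, 1 / 3)

    def test_identical_rows_give_uniform(self):
        Q = _qvm(np.tile([-0.4, -1.2], (4, 1)))
        pi = update_policy_expectation(Q, np.array([0.3, 0.7]), gamma_hat=17.0)
        np.testing.assert_allclose(pi, 0.25)

    def test_two_policy_softmax_value(self):
        Q = _qvm(np.array([[0.0], [-1.0]]))
        pi = update_policy_expectation(Q, np.array([1.0]), gamma_hat=2.0)
        np.testing.assert_allclose(pi, [0.8808, 0.1192], atol=1e-4)


class TestPrecisionUpdate:
    def test_attainable_goals_give_prior_mean(self, identity_model):
        Q = _qvm(np.zeros((2, 3)))
        beta_hat, gamma = update_precision(identity_model, Q, np.full(3, 1 / 3), np.full(2, 0.5))
        assert beta_hat == 1.0
        assert gamma == 8.0

    def test_expected_value_minus_three(self, identity_model):
        Q = _qvm(np.full((2, 3), -3.0))
        beta_hat, gamma = update_precision(identity_model, Q, np.full(3, 1 / 3), np.full(2, 0.5))
        assert beta_hat == pytest.approx(4.0)
        assert gamma == pytest.approx(2.0)

    def test_more_negative_values_reduce_precision(self, small_random):
        model, _ = small_random
        rng = np.random.default_rng(0)
        Q1 = -rng.uniform(0.1, 2.0, size=(4, model.n_states))
        s = rng.dirichlet(np.ones(model.n_states))
        pi = rng.dirichlet(np.ones(4))
        _, g1 = update_precision(model, _qvm(Q1), s, pi)
        _, g2 = update_precision(model, _qvm(2 * Q1), s, pi)
        assert g2 < g1


class TestUpdateOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_three_updates_match_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        model, _ = random_model(3, 2, 3, 4, seed=seed)
        ps = make_policy_set(model.horizon, 2, "stay_then_shift")
        Q = policy_value_matrix(model, ps, 2)
        gamma = float(rng.uniform(0.1, 8.0))
        pi = rng.dirichlet(np.ones(ps.n_policies))
        prev_s = rng.dirichlet(np.ones(model.n_states))
        obs_idx = int(rng.integers(model.n_obs))
        obs = np.zeros(model.n_obs)
        obs[obs_idx] = 1.0

        s = update_state_expectation(model, Q, obs, prev_s, 1, pi, gamma)
        s_ref = state_update_direct(model.A, model.B, model.d, obs_idx, prev_s, 1, Q.Q, pi, gamma)
        np.testing.assert_allclose(s, s_ref, atol=1e-10)

        pi_new = update_policy_expectation(Q, s, gamma)
        pi_ref = policy_update_direct(Q.Q, s, gamma)
        np.testing.assert_allclose(pi_new, pi_ref, atol=1e-10)

        beta_hat, gamma_new = update_precision(model, Q, s, pi_new)
        b_ref, g_ref = precision_update_direct(model.alpha, model.beta, Q.Q, s, pi_new)
        assert beta_hat == pytest.approx(b_ref, abs=1e-10)
        assert gamma_new == pytest.approx(g_ref, abs=1e-10)


class TestInfer:
    def test_single_state_world_converges_immediately(self):
        model = GenerativeModel(
            A=np.ones((1, 1)), B=np.ones((1, 1, 1)),
            c=np.ones(1), d=np.ones(1), horizon=3,
        )
        ps = PolicySet(policies=np.zeros((1, 2), dtype=int), scheme="stay_then_shift")
        belief, trace = infer(model, ps, [np.ones(1)], [])
        np.testing.assert_array_equal(belief.s_hat[0], [1.0])
        assert belief.gamma_hat == pytest.approx(8.0)
        assert trace.converged

    def test_converged_beliefs_are_a_fixed_point(self, small_random):
        model, _ = small_random
        ps = make_policy_set(model.horizon, 2, "stay_then_shift")
        rng = np.random.default_rng(3)
        obs = []
        for _ in range(3):
            o = np.zeros(model.n_obs)
            o[rng.integers(model.n_obs)] = 1.0
            obs.append(o)
        actions = [0, 1]
        tol = 1e-9
        belief, trace = infer(model, ps, obs, actions, tol=tol, max_iter=256)
        assert trace.converged
        Q = policy_value_matrix(model, ps, 3)
        s2 = update_state_expectation(
            model, Q, obs[-1], belief.s_hat[-2], actions[-1], belief.pi_hat, belief.gamma_hat
        )
        assert np.abs(s2 - belief.s_hat[-1]).max() < tol
        pi2 = update_policy_expectation(Q, belief.s_hat[-1], belief.gamma_hat)
        assert np.abs(pi2 - belief.pi_hat).max() < tol
        _, g2 = update_precision(model, Q, belief.s_hat[-1], belief.pi_hat)
        assert abs(g2 - belief.gamma_hat) < tol

    def test_bootstrap_matches_sequential_prior(self, small_random):
        # inferring with a carried-forward prior must equal re-inferring the
        # whole history from scratch
        model, _ = small_random
        ps = make_policy_set(model.horizon, 2, "stay_then_shift")
        obs = [np.eye(model.n_obs)[i % model.n_obs] for i in range(3)]
        actions = [0, 1]
        b1, _ = infer(model, ps, obs[:1], [])
        b2, _ = infer(model, ps, obs[:2], actions[:1], prior=b1)
        b3_inc, _ = infer(model, ps, obs, actions, prior=b2)
        b3_scratch, _ = infer(model, ps, obs, actions)
        for a, b in zip(b3_inc.s_hat, b3_scratch.s_hat):
            np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(b3_inc.pi_hat, b3_scratch.pi_hat, atol=1e-12)

    def test_normalization_every_iteration(self, small_random):
        model, _ = small_random
        ps = make_policy_set(model.horizon, 2, "exhaustive")
        obs = [np.eye(model.n_obs)[0]]
        _, trace = infer(model, ps, obs, [])
        for s, pi in zip(trace.s_hat, trace.pi_hat):
            assert s.sum() == pytest.approx(1.0, abs=1e-9)
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)
            assert (s >= 0).all() and (pi >= 0).all()

    def test_precision_bounded_by_prior_mean(self, small_random):
        model, _ = small_random
        ps = make_policy_set(model.horizon, 2, "stay_then_shift")
        bound = model.alpha / model.beta
        for i in range(model.n_obs):
            _, trace = infer(model, ps, [np.eye(model.n_obs)[i]], [])
            for g in trace.gamma_hat:
                assert 0 < g <= bound


class TestSoftmaxLimits:
    def test_large_precision_concentrates_on_best_policy(self):
        for seed in range(10):
            model, _ = random_model(3, 2, 3, 4, seed=500 + seed)
            ps = make_policy_set(model.horizon, 2, "stay_then_shift")
            Q = policy_value_matrix(model, ps, 1)
            s = np.eye(model.n_states)[0]
            pi = update_policy_expectation(Q, s, gamma_hat=1e3)
            values = Q.Q @ s
            near_best = values >= values.max() - 0.01  # e^(-1e3*0.01) ~ 5e-5
            assert pi[near_best].sum() >= 0.999

    def test_tied_best_policies_split_evenly(self):
        Q = _qvm(np.array([[-0.5], [-0.5], [-2.0]]))
        pi = update_policy_expectation(Q, np.array([1.0]), gamma_hat=1e3)
        np.testing.assert_allclose(pi[:2], 0.5, atol=1e-9)
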