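"""Q-network mechanics and offline training correctness.

The training recovery checks use a small synthetic MDP whose optimal policy
and values come from an independent tabular value-iteration oracle.
"""

import numpy as np
import pytest

from t2dreco.dqn import (
    Adam,
    DQNError,
    QNetwork,
    TrainConfig,
    loss_fn,
    soft_update,
    td_target,
    train,
)


def value_iteration(P, R, gamma, tol=1e-10):
    """Tabular oracle: P[s,a] -> next state index, R[s,a] reward."""
    n_s, n_a = R.shape
    V = np.zeros(n_s)
    while True:
        Q = R + gamma * V[P]
        V_new = Q.max(axis=1)
        if np.abs(V_new - V).max() < tol:
            return Q, V_new
        V = V_new


def make_mdp_transitions(P, R, gamma, n_state_dim, n_samples, seed):
    """Sample a uniform offline dataset from a deterministic tabular MDP,
    encoding states as one-hot vectors padded to n_state_dim."""
    rng = np.random.default_rng(seed)
    n_s, n_a = R.shape

    def enc(s):
        v = np.zeros(n_state_dim)
        v[s] = 1.0
        return v

    S = rng.integers(0, n_s, n_samples)
    A = rng.integers(0, n_a, n_samples)
    states = np.array([enc(s) for s in S])
    rewards = R[S, A]
    nxt = P[S, A]
    next_states = np.array([enc(s) for s in nxt])
    terminal = np.zeros(n_samples, bool)
    return states, A, rewards, next_states, terminal


class TestQNetworkMechanics:
    def test_dueling_aggregation_arithmetic(self):
        """Q = V + A - mean(A): checked by direct parameter surgery."""
        net = QNetwork(4, 2, hidden=(8, 4), rng=np.random.default_rng(0))
        # force the streams to constant outputs: zero weights, fixed biases
        net.params["Wv"][:] = 0.0
        net.params["bv"][:] = 2.0
        net.params["Wa"][:] = 0.0
        net.params["ba"] = np.array([1.0, -1.0])
        q = net.q_values(np.zeros((1, 4)))
        np.testing.assert_allclose(q, [[3.0, 1.0]])

    def test_advantage_shift_invariance(self):
        net = QNetwork(4, 3, rng=np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=(5, 4))
        q0 = net.q_values(x)
        net.params["ba"] = net.params["ba"] + 7.3  # constant advantage shift
        np.testing.assert_allclose(net.q_values(x), q0, atol=1e-10)

    def test_single_state_shape(self):
        net = QNetwork(6, 13, rng=np.random.default_rng(0))
        assert net.q_values(np.zeros(6)).shape == (1, 13)

    def test_width_mismatch_errors(self):
        net = QNetwork(6, 3, rng=np.random.default_rng(0))
        with pytest.raises(DQNError):
            net.q_values(np.zeros((2, 5)))

    def test_gradients_match_finite_differences(self):
        """The hand-written backward pass agrees with numeric gradients."""
        import copy

        rng = np.random.default_rng(3)
        net = QNetwork(5, 3, hidden=(7, 4), rng=np.random.default_rng(4))
        X = rng.normal(size=(12, 5))
        A = rng.integers(0, 3, 12)
        tgt = rng.normal(size=12)
        rows = np.arange(12)

        def loss_of(n):
            q, _ = n.forward(X, train=True)
            return float(np.mean((tgt - q[rows, A]) ** 2))

        q, cache = copy.deepcopy(net).forward(X, train=True)
        dq = np.zeros_like(q)
        dq[rows, A] = -2 * (tgt - q[rows, A]) / 12
        grads = copy.deepcopy(net).backward(dq, cache)
        for k in ("W1", "g1", "be1", "W2", "Wv", "Wa", "ba"):
            p = net.params[k]
            idx = tuple(0 for _ in p.shape)
            for sign in (1, -1):
                n = copy.deepcopy(net)
                n.params[k][idx] += sign * 1e-6
                if sign == 1:
                    up = loss_of(n)
                else:
                    dn = loss_of(n)
            num = (up - dn) / 2e-6
            assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTDTarget:
    def _nets(self):
        a = QNetwork(3, 2, hidden=(4, 3), rng=np.random.default_rng(0))
        return a, a.copy()

    def test_terminal_reduces_to_reward(self):
        net, tgt = self._nets()
        out = td_target(np.array([-7.0]), np.zeros((1, 3)), np.array([True]),
                        net, tgt, 0.9)
        assert out[0] == -7.0

    def test_double_dqn_formula_closed_form(self):
        """Eval net argmax selects, target net evaluates: r + gamma*Q_t(s',a*)."""
        net, tgt = self._nets()
        s_next = np.random.default_rng(1).normal(size=(1, 3))
        a_star = int(np.argmax(net.q_values(s_next)[0]))
        expected = 1.0 + 0.9 * tgt.q_values(s_next)[0, a_star]
        out = td_target(np.array([1.0]), s_next, np.array([False]), net, tgt, 0.9)
        assert out[0] == pytest.approx(expected)

    def test_gamma_zero_is_reward(self):
        net, tgt = self._nets()
        r = np.array([0.3, -1.2])
        out = td_target(r, np.zeros((2, 3)), np.array([False, False]), net, tgt, 0.0)
        np.testing.assert_allclose(out, r)

    def test_identical_nets_reduce_to_single_network_target(self):
        net, tgt = self._nets()  # tgt is an exact copy
        s_next = np.random.default_rng(2).normal(size=(4, 3))
        out = td_target(np.zeros(4), s_next, np.zeros(4, bool), net, tgt, 0.9)
        single = 0.9 * net.q_values(s_next).max(axis=1)
        np.testing.assert_allclose(out, single)


class TestLoss:
    def test_zero_loss_within_threshold(self):
        loss, td, _ = loss_fn([1.0], [1.0], [1.0], lam=0.5, r_reg=4.0)
        assert loss == 0.0 and td[0] == 0.0

    def test_penalty_beyond_threshold(self):
        loss, _, _ = loss_fn([5.0], [5.0], [1.0], lam=0.5, r_reg=4.0)
        assert loss == pytest.approx(0.5 * (5 - 4))

    def test_plain_squared_error(self):
        loss, td, _ = loss_fn([1.0], [2.0], [1.0], lam=0.0, r_reg=4.0)
        assert loss == pytest.approx(1.0) and td[0] == pytest.approx(1.0)

    def test_nonnegative_and_zero_only_when_clean(self):
        rng = np.random.default_rng(0)
        q = rng.normal(scale=3, size=50)
        t = rng.normal(scale=3, size=50)
        loss, _, _ = loss_fn(q, t, np.ones(50), 0.5, 4.0)
        assert loss > 0

    def test_non_finite_rejected(self):
        with pytest.raises(DQNError):
            loss_fn([np.nan], [0.0], [1.0], 0.5, 4.0)


class TestSoftUpdate:
    def test_limits_and_arithmetic(self):
        src = QNetwork(3, 2, rng=np.random.default_rng(0))
        tgt = QNetwork(3, 2, rng=np.random.default_rng(1))
        t1 = tgt.copy()
        soft_update(t1, src, tau=1.0)
        np.testing.assert_allclose(t1.params["W1"], src.params["W1"])
        t0 = tgt.copy()
        soft_update(t0, src, tau=0.0)
        np.testing.assert_allclose(t0.params["W1"], tgt.params["W1"])
        tm = tgt.copy()
        soft_update(tm, src, tau=0.01)
        np.testing.assert_allclose(
            tm.params["W1"], 0.01 * src.params["W1"] + 0.99 * tgt.params["W1"]
        )


# toy-MDP training: the clinical Q-magnitude penalty and the conservative
# offline regularizer are disabled so the unregularized Bellman fixed point
# (the value-iteration solution) is recoverable exactly
TOY_CONFIG = TrainConfig(
    n_iterations=4000, batch_size=512, lr=0.003, tau=0.05, seed=0,
    lam=0.0, conservative_weight=0.0, beta=1.0, target_clip=30.0,
)


class TestTrainingRecovery:
    def _mdp(self):
        # 2-state, 2-action chain: action 1 moves toward state 1 which pays
        P = np.array([[0, 1], [0, 1]])
        R = np.array([[-1.0, 0.0], [-1.0, 1.0]])
        return P, R

    def test_toy_mdp_policy_matches_value_iteration(self):
        P, R = self._mdp()
        Q_star, _ = value_iteration(P, R, 0.9)
        data = make_mdp_transitions(P, R, 0.9, 4, 2000, seed=1)
        model = train(*data, n_actions=2, config=TOY_CONFIG, hidden=(16, 8))
        enc = np.eye(2, 4)
        q = model.q_values(enc)
        assert np.array_equal(q.argmax(axis=1), Q_star.argmax(axis=1))
        assert np.abs(q - Q_star).max() < 0.1

    def test_dominant_action_ranked_first(self):
        """Terminal-only bandit data: the always-rewarding action wins."""
        rng = np.random.default_rng(5)
        n = 3000
        states = rng.random((n, 6))
        actions = rng.integers(0, 3, n)
        rewards = np.where(actions == 1, 1.0, -1.0)
        terminal = np.ones(n, bool)
        model = train(states, actions, rewards, np.zeros((n, 6)), terminal,
                      n_actions=3,
                      config=TrainConfig(n_iterations=1500, batch_size=64,
                                         lr=0.003, seed=0),
                      hidden=(16, 8))
        held_out = rng.random((200, 6))
        top = model.q_values(held_out).argmax(axis=1)
        assert (top == 1).mean() >= 0.99

    def test_same_seed_bit_identical_history(self):
        P, R = self._mdp()
        data = make_mdp_transitions(P, R, 0.9, 4, 500, seed=2)
        cfg = TrainConfig(n_iterations=200, batch_size=32, seed=9)
        h1 = train(*data, n_actions=2, config=cfg, hidden=(8, 4)).loss_history
        h2 = train(*data, n_actions=2, config=cfg, hidden=(8, 4)).loss_history
        np.testing.assert_array_equal(h1, h2)

    def test_action_out_of_range_rejected(self):
        with pytest.raises(DQNError):
            train(np.zeros((4, 3)), np.array([0, 1, 2, 5]), np.zeros(4),
                  np.zeros((4, 3)), np.ones(4, bool), n_actions=3,
                  config=TrainConfig(n_iterations=10))


class TestPriorityRefresh:
    def test_priorities_equal_new_td_plus_floor(self):
        from t2dreco.replay import PrioritizedReplay

        buf = PrioritizedReplay(10, priority_floor=1e-3)
        idx = np.array([2, 5, 7])
        td = np.array([0.5, -1.5, 0.0])
        buf.update(idx, td)
        np.testing.assert_allclose(buf.priorities[idx], np.abs(td) + 1e-3)
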