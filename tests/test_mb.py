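"""Mushroom-body circuit: sparse coding, DAN signals, plasticity, TD oracle."""

import math

import numpy as np
import pytest

from mbcx import mb as mbm, rl as rlm
from mbcx.exceptions import ConfigurationError, EmptyTraceError, ValenceError


class TestKCProjection:
    def test_exact_fan_in_per_cell(self):
        proj = mbm.KCProjection.create(n_pn=50, n_kc=200, fan_in=7, seed=1)
        assert np.all(proj.weights.sum(axis=0) == 7)
        assert set(np.unique(proj.weights)) <= {0.0, 1.0}

    def test_deterministic_given_seed(self):
        a = mbm.KCProjection.create(50, 200, 7, seed=3)
        b = mbm.KCProjection.create(50, 200, 7, seed=3)
        assert np.array_equal(a.weights, b.weights)


class TestKCEncode:
    def test_deterministic_and_k_active(self):
        proj = mbm.KCProjection.create(20, 1000, 5, seed=0)
        x = np.random.default_rng(1).uniform(0, 1, 20)
        k1 = mbm.kc_encode(x, proj, 0.05)
        k2 = mbm.kc_encode(x, proj, 0.05)
        assert np.array_equal(k1.active, k2.active)
        assert k1.k_active == math.ceil(0.05 * 1000) == 50

    def test_zero_features_silent_flag(self):
        proj = mbm.KCProjection.create(20, 100, 5, seed=0)
        k = mbm.kc_encode(np.zeros(20), proj, 0.05)
        assert k.silent and k.k_active == 0

    def test_overlap_matches_hypergeometric_expectation(self):
        """Random pattern pairs overlap like two random k-subsets:
        E[overlap] = k^2 / n_kc, checked over 200 projections."""
        n_kc, f = 1000, 0.05
        k = math.ceil(f * n_kc)
        overlaps = []
        for s in range(200):
            proj = mbm.KCProjection.create(40, n_kc, 8, seed=s)
            rng = np.random.default_rng(1000 + s)
            a = mbm.kc_encode(rng.uniform(0, 1, 40), proj, f)
            b = mbm.kc_encode(rng.uniform(0, 1, 40), proj, f)
            overlaps.append(float(a.active @ b.active))
        expect = k * k / n_kc
        sd = np.std(overlaps) / np.sqrt(len(overlaps))
        # correlated drives inflate overlap somewhat; 3-sigma band around a
        # generous multiple of the random-subset expectation
        assert np.mean(overlaps) >= expect - 3 * sd


class TestQForward:
    def test_fresh_state_is_zero(self):
        mb = mbm.MBState(n_kc=100, n_actions=4, w0=0.5)
        kc = mbm.one_hot_kc(3, 100)
        assert np.allclose(mbm.q_forward(kc, mb), 0.0)

    def test_one_hot_is_table_lookup(self):
        mb = mbm.MBState(n_kc=10, n_actions=2, w0=1.0)
        mb.w_plus[4, 1] = 1.7
        mb.w_minus[4, 1] = 0.2
        q = mbm.q_forward(mbm.one_hot_kc(4, 10), mb)
        assert q[1] == pytest.approx(1.5)
        assert q[0] == pytest.approx(0.0)

    def test_single_update_changes_q_by_alpha_delta(self):
        mb = mbm.MBState(n_kc=10, n_actions=2, w0=5.0, alpha=0.25)
        kc = mbm.one_hot_kc(2, 10)
        dan = mbm.DANSignal(d_plus=1.0, d_minus=0.0)
        mbm.apply_plasticity(mb, kc, 0, dan)
        assert mbm.q_forward(kc, mb)[0] == pytest.approx(0.25 * 1.0)


class TestSelectAction:
    def test_epsilon_zero_is_greedy(self):
        rng = np.random.default_rng(0)
        q = np.array([0.1, 0.9, 0.3])
        for _ in range(50):
            assert mbm.select_action(q, "epsilon_greedy", rng, epsilon=0.0) == 1

    def test_greedy_breaks_ties_low_index(self):
        assert mbm.select_action(np.array([0.5, 0.5, 0.2])) == 0

    def test_epsilon_one_is_uniform(self):
        rng = np.random.default_rng(123)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            counts[mbm.select_action(np.zeros(4), "epsilon_greedy", rng, epsilon=1.0)] += 1
        p = 0.25
        band = 3 * np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < band)

    def test_softmax_limit_is_argmax(self):
        rng = np.random.default_rng(5)
        picks = [
            mbm.select_action(np.array([0.0, 1.0]), "softmax", rng, beta=1000.0)
            for _ in range(1000)
        ]
        assert sum(picks) >= 999

    def test_invalid_params_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            mbm.select_action(np.zeros(2), "epsilon_greedy", rng, epsilon=1.5)
        with pytest.raises(ConfigurationError):
            mbm.select_action(np.zeros(2), "softmax", rng, beta=-1.0)


class TestDANSignals:
    @pytest.mark.parametrize("rp,rm,expect", [(0, 0, 0), (1, 0, 1), (0.3, 0.5, -0.2)])
    def test_direct_combined(self, rp, rm, expect):
        assert mbm.dan_direct(rp, rm).combined == pytest.approx(expect)

    def test_direct_rejects_negative(self):
        with pytest.raises(ValenceError):
            mbm.dan_direct(-0.1, 0.0)

    def test_rpe_full_surprise_and_learned(self):
        assert mbm.dan_rpe(1.0, 0.0, 0.0, 0.0).combined == pytest.approx(1.0)
        assert mbm.dan_rpe(1.0, 0.0, 1.0, 0.0).combined == pytest.approx(0.0)

    def test_td_terminal_and_gamma_zero_limits(self):
        tr = mbm.TraceBuffer()
        tr.prime(mbm.one_hot_kc(0, 4), 0, q_plus=1.5, q_minus=0.0)
        # terminal: q_now forced 0 -> combined = R - Q_prev
        assert mbm.dan_td(1.0, 0.0, 0.0, 0.0, tr, 0.9).combined == pytest.approx(-0.5)
        # gamma = 0: immediate-reward RPE against previous prediction
        assert mbm.dan_td(1.0, 0.0, 7.0, 3.0, tr, 0.0).combined == pytest.approx(-0.5)

    def test_td_matches_tabular_sarsa_delta(self):
        tr = mbm.TraceBuffer()
        tr.prime(mbm.one_hot_kc(0, 4), 0, q_plus=1.5, q_minus=0.0)
        got = mbm.dan_td(1.0, 0.0, 2.0, 0.0, tr, 0.9).combined
        q = np.zeros((2, 1))
        q[0, 0] = 1.5
        q[1, 0] = 2.0
        assert got == pytest.approx(rlm.sarsa_delta(q, 0, 0, 1.0, 1, 0, 0.9))
        assert got == pytest.approx(1.3)

    def test_empty_trace_raises(self):
        with pytest.raises(EmptyTraceError):
            mbm.dan_td(1.0, 0.0, 0.0, 0.0, mbm.TraceBuffer(), 0.9)


class TestPlasticity:
    def test_zero_combined_leaves_weights_unchanged(self):
        mb = mbm.MBState(n_kc=10, n_actions=2, w0=0.5)
        w_plus = mb.w_plus.copy()
        mbm.apply_plasticity(mb, mbm.one_hot_kc(0, 10), 0, mbm.DANSignal(0.0, 0.0))
        assert np.array_equal(mb.w_plus, w_plus)

    def test_weights_stay_nonnegative_under_any_sequence(self):
        rng = np.random.default_rng(6)
        mb = mbm.MBState(n_kc=50, n_actions=3, w0=0.2, alpha=0.5)
        proj = mbm.KCProjection.create(10, 50, 3, seed=0)
        for _ in range(300):
            kc = mbm.kc_encode(rng.uniform(0, 1, 10), proj, 0.1)
            dan = mbm.DANSignal(rng.uniform(0, 2), rng.uniform(0, 2))
            mbm.apply_plasticity(mb, kc, int(rng.integers(3)), dan)
            assert np.all(mb.w_plus >= 0) and np.all(mb.w_minus >= 0)
        assert mb.clip_events > 0  # tiny w0 forces clipping, and it is counted


def paired_mb_tabular_run(mdp, steps, seed, alpha=0.1, epsilon=0.2, w0=10.0,
                          variant="sarsa"):
    """Drive the MB circuit on an MDP while shadowing every transition with
    the tabular update; returns max |Q_mb - Q_tab| over the run."""
    rng = np.random.default_rng(seed)
    env = rlm.TabularEnv(mdp, rng)
    mb = mbm.MBState(mdp.n_states, mdp.n_actions, w0=w0, alpha=alpha, gamma=mdp.gamma)
    agent = mbm.MBAgent(mb, policy="epsilon_greedy", epsilon=epsilon,
                        variant=variant, rng=np.random.default_rng(seed + 1))
    qtab = np.zeros((mdp.n_states, mdp.n_actions))
    s = env.reset()
    a = agent.step(mbm.one_hot_kc(s, mdp.n_states), 0.0, 0.0)
    prev = (s, a)
    max_err = 0.0
    for _ in range(steps):
        s2, r, done = env.step(a)
        a2 = agent.step(mbm.one_hot_kc(s2, mdp.n_states), r, 0.0, terminal=done)
        ps, pa = prev
        if variant == "sarsa":
            delta = rlm.sarsa_delta(qtab, ps, pa, r, s2, a2, mdp.gamma, done)
        else:
            delta = rlm.q_learning_delta(qtab, ps, pa, r, s2, mdp.gamma, done)
        qtab[ps, pa] += alpha * delta
        max_err = max(max_err, float(np.abs((mb.w_plus - mb.w_minus) - qtab).max()))
        if done:
            s = env.reset()
            a = agent.step(mbm.one_hot_kc(s, mdp.n_states), 0.0, 0.0)
            prev = (s, a)
        else:
            prev = (s2, a2)
            a = a2
    return max_err, mb


class TestTabularEquivalence:
    def test_sarsa_equivalence_5000_steps(self):
        """One-hot MB TD circuit tracks tabular SARSA to 1e-12 step by step."""
        mdp = rlm.make_gridworld(5, 5, (4, 4), gamma=0.9)
        max_err, mb = paired_mb_tabular_run(mdp, 5000, seed=7)
        assert max_err < 1e-12
        assert mb.clip_fraction == 0.0

    def test_q_learning_equivalence(self):
        mdp = rlm.make_gridworld(4, 4, (3, 3), gamma=0.9)
        max_err, _ = paired_mb_tabular_run(mdp, 2000, seed=3, variant="q_learning")
        assert max_err < 1e-12


class TestRPEConditioning:
    def test_error_decays_geometrically(self):
        """Fixed stimulus-reward pairing: RPE after n trials = (1-alpha)^n."""
        alpha = 0.3
        mb = mbm.MBState(n_kc=20, n_actions=1, w0=5.0, alpha=alpha, gamma=0.0)
        agent = mbm.MBAgent(mb, policy="greedy", mode="rpe")
        kc = mbm.one_hot_kc(4, 20)
        errors = []
        for _ in range(12):
            agent.step(kc, 1.0, 0.0)
            errors.append(agent.last_dan.combined)
        expect = [(1 - alpha) ** n for n in range(12)]
        assert np.allclose(errors, expect, atol=1e-9)

    def test_extinction_decays_without_negative_weights(self):
        alpha = 0.3
        mb = mbm.MBState(n_kc=20, n_actions=1, w0=5.0, alpha=alpha, gamma=0.0)
        agent = mbm.MBAgent(mb, policy="greedy", mode="rpe")
        kc = mbm.one_hot_kc(4, 20)
        for _ in range(40):
            agent.step(kc, 1.0, 0.0)
        q_learned = mbm.q_forward(kc, mb)[0]
        assert q_learned == pytest.approx(1.0, abs=1e-5)
        for n in range(10):
            agent.step(kc, 0.0, 0.0)
            assert agent.last_dan.combined == pytest.approx(
                -(1 - alpha) ** n * q_learned, abs=1e-9
            )
        assert np.all(mb.w_plus >= 0) and np.all(mb.w_minus >= 0)
        assert mbm.q_forward(kc, mb)[0] < 0.05


class TestGradientWorldLearning:
    def test_mb_agent_learns_optimal_policy_one_hot(self):
        """MB TD learner matches value iteration on >= 95% of chain states."""
        mdp, _ = rlm.make_gradient_world(10, reward_states=(9,), gamma=0.9)
        _, _, pi_star = rlm.value_iteration(mdp)
        rng = np.random.default_rng(0)
        env = rlm.TabularEnv(mdp, rng)
        mb = mbm.MBState(mdp.n_states, mdp.n_actions, w0=20.0, alpha=0.2, gamma=0.9)
        agent = mbm.MBAgent(mb, policy="epsilon_greedy", epsilon=0.3,
                            rng=np.random.default_rng(1))
        for _ in range(150):
            s = env.reset()
            a = agent.step(mbm.one_hot_kc(s, mdp.n_states), 0.0, 0.0)
            for _ in range(60):
                s, r, done = env.step(a)
                a = agent.step(mbm.one_hot_kc(s, mdp.n_states), r, 0.0, terminal=done)
                if done:
                    break
        q_mb = mb.w_plus - mb.w_minus
        mask = ~mdp.terminal
        agree = np.mean(q_mb.argmax(1)[mask] == pi_star[mask])
        assert agree >= 0.95
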