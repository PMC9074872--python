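"""Population encoders, policy decoding, returns, PPO, and navigation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from samsnn import SAMParams
from samsnn.meta_rl import (
    Arena,
    NavConfig,
    collect_episodes,
    decode_action,
    discounted_returns,
    encode_position,
    encode_reward,
    ppo_update,
    run_navigation,
)
from samsnn.learning import Adam
from samsnn.network import init_weights


class TestEncoders:
    def test_peak_rate_at_preferred_value(self):
        preferred = np.linspace(0, 1, 11)
        rates = encode_position(np.array([0.5]), preferred)
        assert rates[0, 5] == pytest.approx(500.0)

    def test_rate_at_point_one_offset(self):
        rates = encode_position(np.array([0.4]), np.array([0.5]))
        assert rates[0, 0] == pytest.approx(500.0 * np.exp(-1.0), rel=1e-12)

    def test_rate_vanishes_far_from_preferred(self):
        rates = encode_position(np.array([0.0]), np.array([1.0]))
        assert rates[0, 0] < 1e-20

    def test_empirical_rate_converges_to_programmed_rate(self, rng):
        # law of large numbers: Bernoulli(rate*dt) spiking matches the tuning curve
        rate = float(encode_position(np.array([0.45]), np.array([0.5]))[0, 0])
        p = rate / 1000.0
        n = 200_000
        emp = (rng.random(n) < p).mean() * 1000.0
        assert emp == pytest.approx(rate, rel=0.05)

    @pytest.mark.parametrize(
        "r,first,second", [(0.0, 0, 0), (1.0, 8, 0), (-1.0, 0, 8), (0.5, 8, 0)]
    )
    def test_reward_groups(self, r, first, second):
        out = encode_reward(r, group_size=8)
        assert out[:8].sum() == first and out[8:].sum() == second


class TestDecodeAction:
    def test_zero_readouts_give_centered_policy(self):
        rng = np.random.default_rng(0)
        env, raw, logp, value = decode_action(np.zeros(5), rng, max_speed=10.0)
        # mean (0,0), std sigma(0) = 0.5 on both axes; value head reads lambda_5
        assert value == 0.0
        samples = np.array([decode_action(np.zeros(5), rng, 10.0)[1] for _ in range(4000)])
        assert np.allclose(samples.mean(axis=0), 0.0, atol=0.05)
        assert np.allclose(samples.std(axis=0), 0.5, atol=0.05)

    def test_large_readout_saturates_mean(self):
        rng = np.random.default_rng(0)
        _, raw, _, _ = decode_action(np.array([50.0, 0, -50.0, -50.0, 0]), rng)
        assert raw[0] == pytest.approx(1.0, abs=1e-3)

    def test_fixed_seed_reproducible(self):
        lam = np.array([0.3, -0.2, 0.1, 0.4, 0.7])
        a = decode_action(lam, np.random.default_rng(5))
        b = decode_action(lam, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and a[2] == b[2]

    def test_env_action_capped_to_max_speed(self):
        rng = np.random.default_rng(1)
        env, _, _, _ = decode_action(np.array([5.0, 5.0, 5.0, 5.0, 0]), rng, max_speed=0.02)
        assert np.linalg.norm(env) <= 0.02 + 1e-12


class TestReturns:
    def test_single_terminal_reward_geometric(self):
        T = 50
        r = np.zeros((T, 1))
        r[-1, 0] = 1.0
        omega = discounted_returns(r, 0.99)
        expected = 0.99 ** (T - 1 - np.arange(T))
        assert np.allclose(omega[:, 0], expected)

    def test_backward_recursion_matches_quadratic_definition(self, rng):
        rewards = rng.random((120, 3))
        fast = discounted_returns(rewards, 0.99)
        slow = np.zeros_like(rewards)
        for t in range(120):
            for tp in range(t, 120):
                slow[t] += 0.99 ** (tp - t) * rewards[tp]
        assert np.max(np.abs(fast - slow)) <= 1e-9

    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_zero_rewards_zero_returns(self, gamma):
        assert np.all(discounted_returns(np.zeros((20, 2)), gamma) == 0.0)


class TestPPO:
    def _setup(self, seed=0, T=60, K=3):
        params = SAMParams()
        cfg = NavConfig(n_hidden=15, K=K, T=T, goal_radius=0.2, max_speed=0.05, seed=seed)
        topo = init_weights(cfg.n_in, cfg.n_hidden, 1.0, seed=seed, params=params, n_out=5)
        arena = Arena(goal=np.array([0.75, 0.75]), goal_radius=cfg.goal_radius,
                      max_speed=cfg.max_speed)
        rng = np.random.default_rng(seed)
        batch, info = collect_episodes(topo, params, arena, cfg, rng)
        return params, cfg, topo, batch, info

    def test_rollout_shapes_and_reproducibility(self):
        _, cfg, _, batch, _ = self._setup(seed=3)
        assert batch.x.shape == (cfg.T, cfg.K, cfg.n_in)
        assert batch.rewards.shape == (cfg.T, cfg.K)
        _, _, _, batch2, _ = self._setup(seed=3)
        assert np.array_equal(batch.x, batch2.x)
        assert np.array_equal(batch.actions, batch2.actions)

    def test_zero_rewards_leave_only_value_and_rate_terms(self):
        params, cfg, topo, batch, _ = self._setup()
        batch.rewards[:] = 0.0
        batch.values[:] = 0.0
        adam = Adam(lr=cfg.lr)
        _, comps = ppo_update(topo, params, batch, cfg, adam, np.random.default_rng(0))
        # returns are all zero, advantages are zero after normalization:
        # the clipped surrogate contributes nothing; only the value regression
        # (toward zero returns) and the rate penalty remain
        assert comps["policy_loss"] == pytest.approx(0.0, abs=1e-12)
        assert comps["rate_loss"] >= 0.0
        assert comps["value_loss"] >= 0.0

    def test_ratio_is_one_for_unchanged_policy(self):
        params, cfg, topo, batch, _ = self._setup()
        ys = batch.cache["y"]
        mean = np.tanh(ys[..., 0:2])
        std = 1.0 / (1.0 + np.exp(-ys[..., 2:4]))
        logp = (-0.5 * ((batch.actions - mean) / std) ** 2 - np.log(std)
                - 0.5 * np.log(2 * np.pi)).sum(axis=-1)
        ratio = np.exp(logp - batch.logp_old)
        assert np.allclose(ratio, 1.0, atol=1e-12)

    def test_clipped_ratio_bounded(self, rng):
        eps = 0.2
        ratio = np.exp(rng.normal(0, 1, 1000))
        clipped = np.clip(ratio, 1 - eps, 1 + eps)
        assert clipped.min() >= 1 - eps and clipped.max() <= 1 + eps

    def test_update_changes_policy_and_reports_finite_losses(self):
        params, cfg, topo, batch, _ = self._setup()
        adam = Adam(lr=cfg.lr)
        before = topo.W_out.copy()
        new, comps = ppo_update(topo, params, batch, cfg, adam, np.random.default_rng(0))
        assert np.isfinite(comps["loss"])
        assert not np.array_equal(new.W_out, before)


class TestNavigationLearning:
    def test_reward_is_one_on_arrival_and_agent_relocates(self):
        arena = Arena(goal=np.array([0.5, 0.5]), goal_radius=0.1, step_noise=0.0,
                      max_speed=0.5)
        rng = np.random.default_rng(0)
        pos = np.array([[0.45, 0.45]])
        new, reward = arena.step(pos, np.array([[0.05, 0.05]]), rng)
        assert reward[0] == 1.0
        assert np.linalg.norm(new[0] - arena.goal) >= 0.0  # relocated somewhere in bounds
        pos = np.array([[0.0, 0.0]])
        _, reward = arena.step(pos, np.array([[0.01, 0.0]]), rng)
        assert reward[0] == 0.0

    def test_training_beats_untrained_baseline(self):
        # scaled-down navigation: generous goal radius, short episodes
        params = SAMParams()
        cfg = NavConfig(n_hidden=30, K=5, T=300, iterations=30, goal_radius=0.25,
                        max_speed=0.05, lr=3e-3, mu_f=1e-4, seed=0)
        _, trained = run_navigation(cfg, params, train=True)
        _, baseline = run_navigation(cfg, params, train=False)
        late = np.mean([c["goals"] for c in trained[-10:]])
        base = np.mean([c["goals"] for c in baseline])
        assert late > base
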