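"""Advantage estimation, clipped objective, gradients, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimpair.environment import EpisodeSpec, SwimmerPairEnv
from swimpair.hydro import HydroParams
from swimpair.ppo import (
    ActorCritic,
    Adam,
    Checkpoint,
    NetworkSpec,
    PPOSpec,
    RolloutBuffer,
    actor_loss_and_grad,
    clip_grad_norm,
    clipped_surrogate,
    compute_gae,
    critic_loss_and_grad,
    select_action,
    train,
    update,
)


def gae_brute_force(rewards, values, terminated, dones, gamma, lam, next_values):
    """Independent double-loop evaluation of the GAE sums."""
    T = len(rewards)
    delta = np.array(
        [
            rewards[t]
            + gamma * next_values[t] * (0.0 if terminated[t] else 1.0)
            - values[t]
            for t in range(T)
        ]
    )
    adv = np.zeros(T)
    for t in range(T):
        acc = 0.0
        w = 1.0
        for k in range(t, T):
            acc += w * delta[k]
            if dones[k]:
                break
            w *= gamma * lam
        adv[t] = acc
    return adv, adv + values[:-1]


class TestGAE:
    def test_two_step_example(self):
        adv, ret = compute_gae(
            [1.0, 0.0], [0.0, 0.0, 0.0], [False, False], [False, False], 0.5, 0.5
        )
        np.testing.assert_allclose(adv, [1.0, 0.0])
        np.testing.assert_allclose(ret, [1.0, 0.0])

    def test_lambda_one_is_discounted_return_minus_value(self):
        rng = np.random.default_rng(5)
        T = 30
        rewards = rng.normal(size=T)
        values = rng.normal(size=T + 1)
        gamma = 0.95
        adv, _ = compute_gae(
            rewards, values, np.zeros(T, bool), np.zeros(T, bool), gamma, 1.0
        )
        discounted = np.zeros(T)
        acc = values[-1]
        for t in range(T - 1, -1, -1):
            acc = rewards[t] + gamma * acc
            discounted[t] = acc
        np.testing.assert_allclose(adv, discounted - values[:-1], atol=1e-12)

    def test_matches_brute_force_with_random_terminals(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            T = int(rng.integers(5, 60))
            rewards = rng.normal(size=T)
            values = rng.normal(size=T + 1)
            next_values = rng.normal(size=T)
            dones = rng.random(T) < 0.15
            terminated = dones & (rng.random(T) < 0.5)
            gamma = float(rng.uniform(0.8, 0.9997))
            lam = float(rng.uniform(0.5, 1.0))
            adv, ret = compute_gae(
                rewards, values, terminated, dones, gamma, lam, next_values
            )
            adv_bf, ret_bf = gae_brute_force(
                rewards, values, terminated, dones, gamma, lam, next_values
            )
            np.testing.assert_allclose(adv, adv_bf, atol=1e-12)
            np.testing.assert_allclose(ret, ret_bf, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_gae([1.0], [0.0], [False], [False], 0.9, 0.9)


class TestClippedSurrogate:
    @pytest.mark.parametrize(
        "ratio, adv, eps, expected",
        [
            (1.0, 2.0, 0.2, 2.0),    # clip inactive
            (1.5, 2.0, 0.2, 2.4),    # positive advantage, clipped high
            (0.5, -1.0, 0.2, -0.8),  # negative advantage, clipped low
        ],
    )
    def test_examples(self, ratio, adv, eps, expected):
        assert clipped_surrogate(ratio, adv, eps) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(
        ratio=st.floats(0.01, 10.0),
        adv=st.floats(-5.0, 5.0),
        eps=st.floats(0.01, 0.5),
    )
    def test_pessimistic_bound_property(self, ratio, adv, eps):
        # the clipped objective never exceeds the unclipped one, and the
        # two agree whenever the ratio lies inside the clip band
        val = float(clipped_surrogate(ratio, adv, eps))
        assert val <= ratio * adv + 1e-12
        if 1 - eps <= ratio <= 1 + eps:
            assert val == pytest.approx(ratio * adv)

    def test_never_exceeds_unclipped(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(0.1, 3.0, 100)
        a = rng.normal(size=100)
        assert np.all(clipped_surrogate(r, a, 0.2) <= r * a + 1e-15)


class _FixedPolicy:
    """Stub exposing the distribution interface select_action needs."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, float)

    def log_probabilities(self, X):
        return np.log(self.probs)[None, :]


class TestSelectAction:
    def test_deterministic_tie_break_lowest_index(self):
        pol = _FixedPolicy(np.full(8, 1 / 8))
        a, logp = select_action(pol, np.zeros(5), "deterministic")
        assert a == 0
        assert logp == pytest.approx(np.log(1 / 8))

    def test_one_hot_policy_both_modes(self):
        p = np.full(8, 1e-12)
        p[3] = 1.0 - p.sum()
        pol = _FixedPolicy(p)
        rng = np.random.default_rng(0)
        assert select_action(pol, np.zeros(5), "deterministic")[0] == 3
        assert select_action(pol, np.zeros(5), "stochastic", rng)[0] == 3

    def test_sampling_frequencies_match_probabilities(self):
        probs = np.array([0.5, 0.2, 0.2, 0.05, 0.05, 0.0, 0.0, 0.0])
        probs = probs / probs.sum()
        pol = _FixedPolicy(np.maximum(probs, 1e-300))
        rng = np.random.default_rng(8)
        n = 100_000
        counts = np.zeros(8)
        for _ in range(n):
            a, _ = select_action(pol, np.zeros(5), "stochastic", rng)
            counts[a] += 1
        sigma = np.sqrt(n * probs * (1 - probs))
        assert np.all(np.abs(counts - n * probs) <= 3 * sigma + 1e-9)

    def test_stochastic_reproducible(self):
        pol = _FixedPolicy(np.full(8, 1 / 8))
        draws1 = [
            select_action(pol, np.zeros(5), "stochastic", np.random.default_rng(3))[0]
            for _ in range(5)
        ]
        draws2 = [
            select_action(pol, np.zeros(5), "stochastic", np.random.default_rng(3))[0]
            for _ in range(5)
        ]
        assert draws1 == draws2


def _random_buffer(rng, policy, T=64):
    obs = rng.normal(size=(T, policy.spec.input_dim))
    logp = policy.log_probabilities(obs)
    actions = np.array([rng.choice(policy.spec.n_actions, p=np.exp(lp)) for lp in logp])
    values = rng.normal(size=T + 1)
    buf = RolloutBuffer(
        obs=obs,
        actions=actions,
        log_probs=logp[np.arange(T), actions],
        rewards=rng.normal(size=T),
        values=values,
        next_values=values[1:].copy(),
        terminated=np.zeros(T, bool),
        dones=np.zeros(T, bool),
    )
    return buf


class TestGradients:
    def test_actor_gradient_matches_finite_differences(self):
        spec = PPOSpec(rollout_length=32, batch_size=32, entropy_coef=0.01)
        net = NetworkSpec(actor_hidden=(8, 6), critic_hidden=(8, 6))
        policy = ActorCritic(net, seed=0)
        rng = np.random.default_rng(1)
        T = 16
        X = rng.normal(size=(T, 5))
        actions = rng.integers(0, 8, T)
        old_logp = policy.log_probabilities(X)[np.arange(T), actions] + rng.normal(
            scale=0.05, size=T
        )
        adv = rng.normal(size=T)
        _, grads, _ = actor_loss_and_grad(policy, X, actions, old_logp, adv, spec)

        def loss_at(params):
            saved = policy.actor.get_flat_params()
            policy.actor.set_flat_params(params)
            val, _, _ = actor_loss_and_grad(policy, X, actions, old_logp, adv, spec)
            policy.actor.set_flat_params(saved)
            return val

        base = policy.actor.get_flat_params()
        h = 1e-6
        for pi in (0, 2, 4):  # a weight matrix, a deeper weight, a bias
            flat_idx = [(0, 0), (1, 2)] if base[pi].ndim == 2 else [(0,), (1,)]
            for ij in flat_idx:
                perturbed = [p.copy() for p in base]
                perturbed[pi][ij] += h
                up = loss_at(perturbed)
                perturbed[pi][ij] -= 2 * h
                down = loss_at(perturbed)
                fd = (up - down) / (2 * h)
                assert grads[pi][ij] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_critic_gradient_matches_finite_differences(self):
        spec = PPOSpec(rollout_length=32, batch_size=32)
        net = NetworkSpec(actor_hidden=(8, 6), critic_hidden=(8, 6))
        policy = ActorCritic(net, seed=0)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        ret = rng.normal(size=12)
        _, grads = critic_loss_and_grad(policy, X, ret, spec)
        base = policy.critic.get_flat_params()
        h = 1e-6
        perturbed = [p.copy() for p in base]
        perturbed[1][3, 2] += h
        policy.critic.set_flat_params(perturbed)
        up, _ = critic_loss_and_grad(policy, X, ret, spec)
        perturbed[1][3, 2] -= 2 * h
        policy.critic.set_flat_params(perturbed)
        down, _ = critic_loss_and_grad(policy, X, ret, spec)
        policy.critic.set_flat_params(base)
        assert grads[1][3, 2] == pytest.approx((up - down) / (2 * h), rel=1e-4)


class TestUpdate:
    def test_zero_advantages_leave_actor_unchanged(self):
        spec = PPOSpec(rollout_length=64, batch_size=32, epochs=3, entropy_coef=0.0)
        net = NetworkSpec(actor_hidden=(16, 8), critic_hidden=(16, 8))
        policy = ActorCritic(net, seed=3)
        rng = np.random.default_rng(3)
        buf = _random_buffer(rng, policy)
        buf.finalize(spec.gamma, spec.gae_lambda)
        buf.advantages = np.zeros(len(buf))
        spec_nonorm = PPOSpec(
            rollout_length=64, batch_size=32, epochs=3,
            entropy_coef=0.0, normalize_advantage=False,
        )
        before = policy.actor.get_flat_params()
        update(policy, buf, spec_nonorm, rng=rng)
        after = policy.actor.get_flat_params()
        for b, a in zip(before, after):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_update_overfits_critic_on_fixed_batch(self):
        spec = PPOSpec(
            rollout_length=64, batch_size=64, epochs=20, learning_rate=1e-2
        )
        net = NetworkSpec(actor_hidden=(16, 8), critic_hidden=(16, 8))
        policy = ActorCritic(net, seed=4)
        rng = np.random.default_rng(4)
        buf = _random_buffer(rng, policy)
        buf.finalize(spec.gamma, spec.gae_lambda)
        err_before = float(((policy.value(buf.obs) - buf.returns) ** 2).mean())
        update(policy, buf, spec, rng=rng)
        err_after = float(((policy.value(buf.obs) - buf.returns) ** 2).mean())
        assert err_after < err_before

    def test_clip_fraction_in_unit_interval(self):
        spec = PPOSpec(rollout_length=64, batch_size=32, epochs=1)
        policy = ActorCritic(NetworkSpec(actor_hidden=(8,), critic_hidden=(8,)), seed=5)
        rng = np.random.default_rng(5)
        buf = _random_buffer(rng, policy)
        buf.finalize(spec.gamma, spec.gae_lambda)
        diag = update(policy, buf, spec, rng=rng)
        assert 0.0 <= diag["clip_fraction"] <= 1.0

    def test_zero_learning_rate_changes_nothing(self):
        spec = PPOSpec(
            rollout_length=64, batch_size=32, epochs=2, learning_rate=0.0
        )
        policy = ActorCritic(NetworkSpec(actor_hidden=(8,), critic_hidden=(8,)), seed=6)
        rng = np.random.default_rng(6)
        buf = _random_buffer(rng, policy)
        buf.finalize(spec.gamma, spec.gae_lambda)
        before = policy.actor.get_flat_params() + policy.critic.get_flat_params()
        update(policy, buf, spec, rng=rng)
        after = policy.actor.get_flat_params() + policy.critic.get_flat_params()
        for b, a in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_grad_norm_clip(self):
        grads = [np.full((3,), 10.0)]
        norm = clip_grad_norm(grads, 0.5)
        assert norm == pytest.approx(np.sqrt(300.0))
        assert np.linalg.norm(grads[0]) == pytest.approx(0.5, rel=1e-6)


class TestCheckpoint:
    def test_roundtrip_reproduces_distributions(self, tmp_path):
        policy = ActorCritic(seed=7)
        ck = Checkpoint.from_policy(policy, n_steps=12345, eval_score=1.5)
        path = tmp_path / "ck.npz"
        ck.save(path)
        loaded = Checkpoint.load(path)
        assert loaded.n_steps == 12345
        assert loaded.eval_score == 1.5
        X = np.random.default_rng(0).normal(size=(10, 5))
        np.testing.assert_array_equal(
            policy.action_probabilities(X), loaded.policy().action_probabilities(X)
        )
        np.testing.assert_array_equal(policy.value(X), loaded.policy().value(X))


class TestTrainLoop:
    def test_discount_horizon_shorter_than_episode(self):
        spec = PPOSpec()
        assert 1.0 / (1.0 - spec.gamma) < EpisodeSpec().max_steps

    def test_single_rollout_training(self, fast_params):
        env = SwimmerPairEnv(
            fast_params, episode_spec=EpisodeSpec(max_steps=128), seed=0
        )
        spec = PPOSpec(rollout_length=256, batch_size=64, epochs=2)
        res = train(
            env, spec, NetworkSpec(actor_hidden=(16, 8), critic_hidden=(16, 8)),
            total_steps=256, eval_every=256, eval_episodes=1, seed=0,
        )
        assert len(res.learning_curve) == 1
        # one checkpoint from the untrained policy plus one after the update
        assert [c.n_steps for c in res.checkpoints] == [0, 256]
        assert res.best in res.checkpoints

    def test_training_bit_reproducible(self, fast_params):
        curves = []
        for _ in range(2):
            env = SwimmerPairEnv(
                fast_params, episode_spec=EpisodeSpec(max_steps=64), seed=1
            )
            spec = PPOSpec(rollout_length=128, batch_size=64, epochs=1)
            res = train(
                env, spec, NetworkSpec(actor_hidden=(8,), critic_hidden=(8,)),
                total_steps=256, eval_every=10**9, eval_episodes=1, seed=1,
            )
            curves.append(res.learning_curve)
        assert curves[0].equals(curves[1])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PPOSpec(gamma=1.0)
        with pytest.raises(ValueError):
            PPOSpec(rollout_length=100, batch_size=64)
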