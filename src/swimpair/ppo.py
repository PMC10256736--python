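"""Clipped proximal-policy optimization with generalized advantage
estimation, on small fully-connected actor/critic networks.

The actor maps the 5-dimensional encoded observation to a categorical
distribution over the 8 joint actions; the critic maps it to a scalar
value.  The two networks share no parameters.  Training alternates
fixed-length rollout collection with several epochs of minibatch Adam
updates on the clipped surrogate objective, extracts a checkpoint every
``eval_every`` environment steps, scores each checkpoint by stochastic
evaluation episodes, and keeps the best-scoring one (early stopping by
selection).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .environment import (
    OBS_DIM,
    N_ACTIONS,
    SwimmerPairEnv,
    encode_observation,
)


@dataclass
class NetworkSpec:
    """Separate actor and critic multilayer perceptrons."""

    actor_hidden: tuple[int, ...] = (128, 128, 64)
    critic_hidden: tuple[int, ...] = (128, 128, 64)
    input_dim: int = OBS_DIM
    n_actions: int = N_ACTIONS
    activation: str = "tanh"


@dataclass
class PPOSpec:
    learning_rate: float = 1e-4
    rollout_length: int = 16_384
    batch_size: int = 256
    epochs: int = 10
    gamma: float = 0.9997
    clip_range: float = 0.2
    gae_lambda: float = 0.95
    entropy_coef: float = 0.0
    value_coef: float = 0.5
    max_grad_norm: float = 0.5
    target_kl: float | None = None
    normalize_advantage: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")
        if self.clip_range <= 0:
            raise ValueError("clip_range must be positive")
        if self.rollout_length % self.batch_size != 0:
            raise ValueError("rollout_length must be divisible by batch_size")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _orthogonal(rng: np.random.Generator, rows: int, cols: int, gain: float):
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if rows < cols:
        q = q.T
    return gain * q[:rows, :cols]


class MLP:
    """Tanh multilayer perceptron with explicit forward/backward passes."""

    def __init__(self, sizes, rng, out_gain=1.0):
        self.sizes = list(sizes)
        self.W = []
        self.b = []
        for k in range(len(sizes) - 1):
            gain = out_gain if k == len(sizes) - 2 else math.sqrt(2.0)
            self.W.append(_orthogonal(rng, sizes[k], sizes[k + 1], gain))
            self.b.append(np.zeros(sizes[k + 1]))

    def forward(self, X):
        """Returns (output, cache) where cache holds layer activations."""
        A = np.asarray(X, dtype=np.float64)
        acts = [A]
        for k in range(len(self.W) - 1):
            A = np.tanh(A @ self.W[k] + self.b[k])
            acts.append(A)
        out = A @ self.W[-1] + self.b[-1]
        return out, acts

    def __call__(self, X):
        return self.forward(X)[0]

    def backward(self, acts, dout):
        """Gradients of a scalar loss given d(loss)/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for k in range(len(self.W) - 1, -1, -1):
            gW[k] = acts[k].T @ delta
            gb[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.W[k].T) * (1.0 - acts[k] ** 2)
        return gW, gb

    @property
    def params(self):
        return self.W + self.b

    def get_flat_params(self):
        return [p.copy() for p in self.params]

    def set_flat_params(self, params):
        nw = len(self.W)
        for k in range(nw):
            self.W[k] = params[k].copy()
            self.b[k] = params[nw + k].copy()


class Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(grads, max_norm):
    """Rescale a list of gradient arrays to a global L2 norm cap; returns
    the pre-clip norm."""
    total = math.sqrt(sum(float((g * g).sum()) for g in grads))
    if max_norm is not None and total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads:
            g *= scale
    return total


class ActorCritic:
    """Separate policy and value networks over encoded observations."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int | None = None):
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.actor = MLP(
            [s.input_dim, *s.actor_hidden, s.n_actions], rng, out_gain=0.01
        )
        self.critic = MLP([s.input_dim, *s.critic_hidden, 1], rng, out_gain=1.0)

    def logits(self, X):
        return self.actor(np.atleast_2d(X))

    def action_probabilities(self, X):
        z = self.logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def log_probabilities(self, X):
        z = self.logits(X)
        z = z - z.max(axis=1, keepdims=True)
        return z - np.log(np.exp(z).sum(axis=1, keepdims=True))

    def value(self, X):
        return self.critic(np.atleast_2d(X))[:, 0]


def select_action(
    policy: ActorCritic,
    encoded_obs: np.ndarray,
    mode: str = "stochastic",
    rng: np.random.Generator | None = None,
) -> tuple[int, float]:
    """Pick an action from the policy distribution.

    Stochastic mode samples the categorical distribution; deterministic
    mode takes the argmax (ties broken by lowest index).  Returns the
    action index and its log-probability under the distribution.
    """
    logp = policy.log_probabilities(encoded_obs)[0]
    if mode == "deterministic":
        a = int(np.argmax(np.exp(logp)))
    elif mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        p = np.exp(logp)
        p = p / p.sum()
        a = int(rng.choice(len(p), p=p))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return a, float(logp[a])


# ---------------------------------------------------------------------------
# advantage estimation and the PPO objective
# ---------------------------------------------------------------------------


def compute_gae(
    rewards,
    values,
    terminated,
    dones,
    gamma: float,
    lam: float,
    next_values=None,
):
    """Generalized advantage estimation over a rollout.

    ``values`` has one trailing bootstrap entry (length T+1).  ``dones``
    marks episode boundaries of either kind, cutting the advantage
    recursion; ``terminated`` marks true environment terminations, whose
    bootstrap value is zeroed (truncated episodes keep their bootstrap).
    ``next_values`` optionally overrides the per-step bootstrap values
    (needed when an episode is truncated mid-rollout and the value of the
    reached terminal state is not ``values[t+1]``).

    Returns (advantages, returns) with
    ``advantage_t = sum_k (gamma*lam)^k delta_{t+k}`` inside a segment and
    ``returns = advantages + values[:-1]``.
    """
    rewards = np.asarray(rewards, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    T = rewards.shape[0]
    if values.shape[0] != T + 1:
        raise ValueError("values must have one trailing bootstrap entry")
    terminated = np.asarray(terminated, dtype=bool)
    dones = np.asarray(dones, dtype=bool)
    if terminated.shape[0] != T or dones.shape[0] != T:
        raise ValueError("flag arrays must match rewards in length")
    nv = values[1:].copy() if next_values is None else np.asarray(next_values, float)
    adv = np.zeros(T)
    last = 0.0
    for t in range(T - 1, -1, -1):
        delta = rewards[t] + gamma * nv[t] * (0.0 if terminated[t] else 1.0) - values[t]
        last = delta + gamma * lam * (0.0 if dones[t] else 1.0) * last
        adv[t] = last
    return adv, adv + values[:-1]


def clipped_surrogate(ratio, advantage, eps):
    """Per-sample clipped PPO objective
    ``min(ratio*A, clip(ratio, 1-eps, 1+eps)*A)``."""
    ratio = np.asarray(ratio, dtype=np.float64)
    advantage = np.asarray(advantage, dtype=np.float64)
    return np.minimum(ratio * advantage, np.clip(ratio, 1 - eps, 1 + eps) * advantage)


@dataclass
class RolloutBuffer:
    obs: np.ndarray
    actions: np.ndarray
    log_probs: np.ndarray
    rewards: np.ndarray
    values: np.ndarray       # length T+1 (trailing bootstrap)
    next_values: np.ndarray  # length T, bootstrap of the state reached
    terminated: np.ndarray
    dones: np.ndarray
    advantages: np.ndarray | None = None
    returns: np.ndarray | None = None

    def __len__(self) -> int:
        return self.rewards.shape[0]

    def finalize(self, gamma: float, lam: float) -> None:
        self.advantages, self.returns = compute_gae(
            self.rewards,
            self.values,
            self.terminated,
            self.dones,
            gamma,
            lam,
            next_values=self.next_values,
        )


def actor_loss_and_grad(policy, X, actions, old_logp, adv, spec):
    """Clipped-surrogate (+ entropy bonus) loss over one minibatch and its
    gradients w.r.t. the actor parameters."""
    nb = len(actions)
    onehot = np.eye(policy.spec.n_actions)
    logits, acts = policy.actor.forward(X)
    z = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logP = z - logZ
    P = np.exp(logP)
    logp_a = logP[np.arange(nb), actions]
    ratio = np.exp(logp_a - old_logp)
    unclipped = ratio * adv
    clipped = np.clip(ratio, 1 - spec.clip_range, 1 + spec.clip_range) * adv
    surrogate = np.minimum(unclipped, clipped)
    entropy = -(P * logP).sum(axis=1)
    loss = -surrogate.mean() - spec.entropy_coef * entropy.mean()
    # gradient of the surrogate flows through the ratio only where the
    # unclipped branch is active (elsewhere the clip is flat)
    mask = (unclipped <= clipped).astype(np.float64)
    w = mask * ratio * adv / nb
    dlogits = -w[:, None] * (onehot[actions] - P)
    if spec.entropy_coef:
        dH = -P * (logP + entropy[:, None])
        dlogits += -(spec.entropy_coef / nb) * dH
    gW, gb = policy.actor.backward(acts, dlogits)
    diag = {
        "entropy": float(entropy.mean()),
        "clip_fraction": float((np.abs(ratio - 1) > spec.clip_range).mean()),
        "approx_kl": float((ratio - 1 - np.log(ratio)).mean()),
    }
    return float(loss), gW + gb, diag


def critic_loss_and_grad(policy, X, returns, spec):
    """Squared-error value loss over one minibatch and its gradients."""
    nb = len(returns)
    vout, vacts = policy.critic.forward(X)
    verr = vout[:, 0] - returns
    loss = spec.value_coef * float((verr**2).mean())
    dV = (spec.value_coef * 2.0 * verr / nb)[:, None]
    gW, gb = policy.critic.backward(vacts, dV)
    return loss, gW + gb


def update(
    policy: ActorCritic,
    buffer: RolloutBuffer,
    spec: PPOSpec,
    actor_opt: Adam | None = None,
    critic_opt: Adam | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """One PPO update: ``epochs`` passes of shuffled minibatch gradient
    steps on the clipped surrogate (actor) and squared error to the GAE
    returns (critic).  Returns diagnostics."""
    if buffer.advantages is None:
        buffer.finalize(spec.gamma, spec.gae_lambda)
    rng = rng or np.random.default_rng()
    actor_opt = actor_opt or Adam(policy.actor.params, spec.learning_rate)
    critic_opt = critic_opt or Adam(policy.critic.params, spec.learning_rate)

    adv = buffer.advantages.copy()
    if spec.normalize_advantage:
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
    T = len(buffer)
    B = spec.batch_size
    diag = {"policy_loss": [], "value_loss": [], "entropy": [], "clip_fraction": [],
            "approx_kl": []}

    for _ in range(spec.epochs):
        perm = rng.permutation(T)
        for start in range(0, T, B):
            idx = perm[start : start + B]
            X = buffer.obs[idx]

            policy_loss, agrads, adiag = actor_loss_and_grad(
                policy, X, buffer.actions[idx], buffer.log_probs[idx], adv[idx], spec
            )
            if not np.isfinite(policy_loss):
                raise FloatingPointError(
                    f"non-finite policy loss; diagnostics so far: {diag}"
                )
            clip_grad_norm(agrads, spec.max_grad_norm)
            actor_opt.step(policy.actor.params, agrads)

            value_loss, cgrads = critic_loss_and_grad(
                policy, X, buffer.returns[idx], spec
            )
            if not np.isfinite(value_loss):
                raise FloatingPointError(
                    f"non-finite value loss; diagnostics so far: {diag}"
                )
            clip_grad_norm(cgrads, spec.max_grad_norm)
            critic_opt.step(policy.critic.params, cgrads)

            diag["policy_loss"].append(policy_loss)
            diag["value_loss"].append(value_loss)
            diag["entropy"].append(adiag["entropy"])
            diag["clip_fraction"].append(adiag["clip_fraction"])
            diag["approx_kl"].append(adiag["approx_kl"])
    return {k: float(np.mean(v)) for k, v in diag.items()}


# ---------------------------------------------------------------------------
# checkpoints, evaluation, training loop
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


@dataclass(eq=False)
class Checkpoint:
    """Snapshot of the policy at a point in training, scored by
    stochastic evaluation episodes."""

    actor_params: list
    critic_params: list
    net_spec: NetworkSpec
    n_steps: int
    eval_score: float | None = None

    @classmethod
    def from_policy(
        cls, policy: ActorCritic, n_steps: int, eval_score: float | None = None
    ) -> "Checkpoint":
        return cls(
            actor_params=policy.actor.get_flat_params(),
            critic_params=policy.critic.get_flat_params(),
            net_spec=policy.spec,
            n_steps=n_steps,
            eval_score=eval_score,
        )

    def policy(self) -> ActorCritic:
        p = ActorCritic(self.net_spec, seed=0)
        p.actor.set_flat_params(self.actor_params)
        p.critic.set_flat_params(self.critic_params)
        return p

    def save(self, path) -> None:
        arrays = {}
        for i, a in enumerate(self.actor_params):
            arrays[f"actor_{i}"] = a
        for i, a in enumerate(self.critic_params):
            arrays[f"critic_{i}"] = a
        meta = {
            "version": CHECKPOINT_VERSION,
            "n_actor": len(self.actor_params),
            "n_critic": len(self.critic_params),
            "n_steps": int(self.n_steps),
            "eval_score": self.eval_score,
            "net_spec": {
                **asdict(self.net_spec),
                "actor_hidden": list(self.net_spec.actor_hidden),
                "critic_hidden": list(self.net_spec.critic_hidden),
            },
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            ns = meta["net_spec"]
            spec = NetworkSpec(
                actor_hidden=tuple(ns["actor_hidden"]),
                critic_hidden=tuple(ns["critic_hidden"]),
                input_dim=ns["input_dim"],
                n_actions=ns["n_actions"],
                activation=ns["activation"],
            )
            return cls(
                actor_params=[data[f"actor_{i}"] for i in range(meta["n_actor"])],
                critic_params=[data[f"critic_{i}"] for i in range(meta["n_critic"])],
                net_spec=spec,
                n_steps=meta["n_steps"],
                eval_score=meta["eval_score"],
            )


def evaluate_policy(
    policy: ActorCritic,
    env: SwimmerPairEnv,
    episodes: int = 5,
    mode: str = "stochastic",
    seed: int = 0,
) -> float:
    """Mean undiscounted episodic reward over fixed-seed evaluation
    episodes (no learning)."""
    totals = []
    rng = np.random.default_rng(seed)
    for ep in range(episodes):
        obs, _ = env.reset(seed=seed + 1000 * ep)
        total = 0.0
        while True:
            x = encode_observation(obs, env.reward_spec)
            a, _ = select_action(policy, x, mode, rng)
            obs, r, term, trunc, _ = env.step(a)
            total += r
            if term or trunc:
                break
        totals.append(total)
    return float(np.mean(totals))


@dataclass
class TrainResult:
    checkpoints: list
    learning_curve: pd.DataFrame
    best: Checkpoint


def _collect_rollout(env, policy, spec, rng, episode_rewards, carry):
    """Collect ``spec.rollout_length`` steps, resetting on episode ends.
    ``carry`` holds (obs, running episodic reward) across rollouts."""
    T = spec.rollout_length
    obs_feat = np.empty((T, OBS_DIM))
    actions = np.empty(T, dtype=np.int64)
    log_probs = np.empty(T)
    rewards = np.empty(T)
    values = np.empty(T + 1)
    next_values = np.empty(T)
    terminated = np.zeros(T, dtype=bool)
    dones = np.zeros(T, dtype=bool)

    obs, ep_ret = carry
    for t in range(T):
        x = encode_observation(obs, env.reward_spec)
        obs_feat[t] = x
        values[t] = policy.value(x)[0]
        a, lp = select_action(policy, x, "stochastic", rng)
        actions[t] = a
        log_probs[t] = lp
        obs, r, term, trunc, _ = env.step(a)
        rewards[t] = r
        ep_ret += r
        if term or trunc:
            terminated[t] = term
            dones[t] = True
            xt = encode_observation(obs, env.reward_spec)
            next_values[t] = policy.value(xt)[0]
            episode_rewards.append(ep_ret)
            ep_ret = 0.0
            obs, _ = env.reset()
        else:
            next_values[t] = np.nan  # filled below
    values[T] = policy.value(encode_observation(obs, env.reward_spec))[0]
    fill = np.isnan(next_values)
    next_values[fill] = values[1:][fill]
    buf = RolloutBuffer(
        obs=obs_feat,
        actions=actions,
        log_probs=log_probs,
        rewards=rewards,
        values=values,
        next_values=next_values,
        terminated=terminated,
        dones=dones,
    )
    return buf, (obs, ep_ret)


def train(
    env: SwimmerPairEnv,
    ppo_spec: PPOSpec | None = None,
    network_spec: NetworkSpec | None = None,
    total_steps: int = 5_400_000,
    eval_every: int = 200_000,
    eval_episodes: int = 5,
    seed: int = 0,
    eval_env_factory=None,
    verbose: bool = False,
) -> TrainResult:
    """Full training loop with periodic checkpoint extraction.

    Alternates rollout collection and PPO updates until ``total_steps``
    environment steps, recording the 100-episode moving-average reward.
    Every ``eval_every`` steps (and once before training) the current
    policy is snapshot and scored with ``eval_episodes`` stochastic
    episodes in a fresh environment; the best-scoring checkpoint is
    returned as the early-stopped model.
    """
    ppo_spec = ppo_spec or PPOSpec()
    network_spec = network_spec or NetworkSpec()
    if total_steps < ppo_spec.rollout_length:
        raise ValueError("total_steps must be at least one rollout")
    if eval_env_factory is None:
        def eval_env_factory():
            return SwimmerPairEnv(
                hydro_params=env.hydro_params,
                reward_spec=env.reward_spec,
                episode_spec=env.episode_spec,
                seed=seed + 77,
            )

    policy = ActorCritic(network_spec, seed=seed)
    actor_opt = Adam(policy.actor.params, ppo_spec.learning_rate)
    critic_opt = Adam(policy.critic.params, ppo_spec.learning_rate)
    rng = np.random.default_rng(seed + 1)
    update_rng = np.random.default_rng(seed + 2)

    episode_rewards: list[float] = []
    curve_rows = []
    checkpoints: list[Checkpoint] = []

    def extract(n_steps):
        score = evaluate_policy(
            policy,
            eval_env_factory(),
            episodes=eval_episodes,
            mode="stochastic",
            seed=seed + 31,
        )
        ck = Checkpoint.from_policy(policy, n_steps, score)
        checkpoints.append(ck)
        if verbose:
            print(f"checkpoint at N_t={n_steps}: eval score {score:.3f}")
        return score

    extract(0)  # random-policy baseline
    obs, _ = env.reset(seed=seed)
    carry = (obs, 0.0)
    n_t = 0
    next_eval = eval_every
    while n_t < total_steps:
        buf, carry = _collect_rollout(
            env, policy, ppo_spec, rng, episode_rewards, carry
        )
        buf.finalize(ppo_spec.gamma, ppo_spec.gae_lambda)
        update(policy, buf, ppo_spec, actor_opt, critic_opt, update_rng)
        n_t += ppo_spec.rollout_length
        moving = float(np.mean(episode_rewards[-100:])) if episode_rewards else np.nan
        score = None
        if n_t >= next_eval or n_t >= total_steps:
            score = extract(n_t)
            next_eval += eval_every
        curve_rows.append(
            {"N_t": n_t, "moving_avg_reward": moving, "eval_score": score}
        )
        if verbose:
            print(f"N_t={n_t}: moving avg episodic reward {moving:.3f}")
    curve = pd.DataFrame(curve_rows)
    best = max(checkpoints, key=lambda c: (c.eval_score, c.n_steps))
    return TrainResult(checkpoints=checkpoints, learning_curve=curve, best=best)
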