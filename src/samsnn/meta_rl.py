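"""Spiking reinforcement meta-learning: 2D navigation with a PPO-trained SAM net.

An agent moves in the unit square toward an invisible goal.  Its position is
population-coded by Gaussian tuning curves (peak rate 500 Hz), rewards are
signalled by two synchronously spiking neuron groups (one for positive, one
for negative reward), and five leaky readouts parameterize a diagonal-Gaussian
policy over 2D velocities plus a value estimate:

    mean  = (tanh(l1), tanh(l2)),  std = (sigmoid(l3), sigmoid(l4)),  value = l5.

Training minimizes the clipped PPO surrogate averaged over K episodes of T
steps, plus a value-regression term and the common rate regularization; each
iteration takes one ADAM step followed by deep rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .learning import Adam, backward_pass, forward_pass, rate_regularization
from .network import SIGNED_MATRICES, NetworkTopology, init_weights, rewire_step
from .neuron import SAMParams

__all__ = [
    "Arena",
    "NavConfig",
    "EpisodeBatch",
    "encode_position",
    "encode_reward",
    "decode_action",
    "discounted_returns",
    "ppo_update",
    "collect_episodes",
    "run_navigation",
]


@dataclass
class Arena:
    """Unit-square navigation arena with a fixed goal per episode.

    The agent's velocity is capped at ``max_speed`` per step, Gaussian
    positional noise of standard deviation ``step_noise`` perturbs each move,
    positions are clamped to the bounds, and reaching within ``goal_radius``
    of the goal yields reward 1 and teleports the agent to a uniform random
    position (the goal itself stays fixed for the whole episode).
    """

    goal: np.ndarray
    step_noise: float = 0.03
    max_speed: float = 0.02
    goal_radius: float = 0.05
    lo: float = 0.0
    hi: float = 1.0

    def sample_position(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=(n, 2))

    def step(self, pos: np.ndarray, action: np.ndarray, rng: np.random.Generator
             ) -> Tuple[np.ndarray, np.ndarray]:
        """Advance ``n`` agents; returns (new positions, rewards in {0, 1})."""
        speed = np.linalg.norm(action, axis=-1, keepdims=True)
        capped = np.where(speed > self.max_speed, action * (self.max_speed / np.maximum(speed, 1e-12)), action)
        new = pos + capped + self.step_noise * rng.standard_normal(pos.shape)
        new = np.clip(new, self.lo, self.hi)
        arrived = np.linalg.norm(new - self.goal, axis=-1) < self.goal_radius
        if arrived.any():
            new = np.where(arrived[:, None], self.sample_position(rng, pos.shape[0]), new)
        return new, arrived.astype(float)


@dataclass
class NavConfig:
    n_pos: int = 10            # position-tuned neurons per coordinate axis
    r_max: float = 500.0       # peak tuning-curve rate, Hz
    n_reward: int = 8          # neurons per reward group
    n_hidden: int = 50
    connectivity: float = 1.0
    frac_inhibitory: float = 0.2
    K: int = 10                # episodes per iteration
    T: int = 2000              # steps per episode
    iterations: int = 100
    gamma: float = 0.99        # discount factor
    clip_eps: float = 0.2
    value_coef: float = 0.5
    mu_f: float = 1e-4
    f0: float = 10.0
    k_damp: float = 0.3
    lr: float = 2e-3
    l1: float = 0.01
    rewire: bool = True
    ppo_epochs: int = 1
    max_speed: float = 0.02
    goal_radius: float = 0.05
    step_noise: float = 0.03
    seed: int = 0

    @property
    def n_in(self) -> int:
        return 2 * self.n_pos + 2 * self.n_reward


def encode_position(pos: np.ndarray, preferred: np.ndarray, r_max: float = 500.0) -> np.ndarray:
    """Gaussian population rate code: ``r_max * exp(-100 * (xi_i - xi)^2)`` per neuron.

    ``pos`` is ``(..., )`` coordinate values, ``preferred`` the neurons'
    preferred values; returns rates in Hz with shape ``pos.shape + preferred.shape``.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    pos = np.asarray(pos, dtype=float)
    return r_max * np.exp(-100.0 * (preferred - pos[..., None]) ** 2)


def encode_reward(r: float, group_size: int = 8) -> np.ndarray:
    """Synchronous volley code for instantaneous reward on two neuron groups.

    Positive reward fires every neuron of the first group once; negative
    reward fires the second group; zero reward is silent.
    """
    out = np.zeros(2 * group_size)
    if r > 0:
        out[:group_size] = 1.0
    elif r < 0:
        out[group_size:] = 1.0
    return out


def decode_action(
    readouts: np.ndarray, rng: np.random.Generator, max_speed: float = 0.02
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample a velocity from the readout-parameterized diagonal Gaussian.

    ``readouts`` has shape ``(..., 5)``.  Returns ``(env_action, raw_action,
    log_prob, value)``: the raw sample comes from N(tanh(l1,2), sigmoid(l3,4)^2),
    the environment action is the raw sample capped to Euclidean norm
    ``max_speed``, and the log-probability refers to the raw sample.
    """
    lam = np.asarray(readouts, dtype=float)
    mean = np.tanh(lam[..., 0:2])
    std = 1.0 / (1.0 + np.exp(-lam[..., 2:4]))
    raw = mean + std * rng.standard_normal(mean.shape)
    logp = (-0.5 * ((raw - mean) / std) ** 2 - np.log(std) - 0.5 * np.log(2 * np.pi)).sum(axis=-1)
    speed = np.linalg.norm(raw, axis=-1, keepdims=True)
    env = np.where(speed > max_speed, raw * (max_speed / np.maximum(speed, 1e-12)), raw)
    return env, raw, logp, lam[..., 4]


def discounted_returns(rewards: np.ndarray, gamma: float = 0.99) -> np.ndarray:
    """Discounted return ``Omega[t] = sum_{t'>=t} gamma^(t'-t) * omega(t')`` along axis 0."""
    out = np.zeros_like(np.asarray(rewards, dtype=float))
    acc = np.zeros(out.shape[1:]) if out.ndim > 1 else 0.0
    for t in range(out.shape[0] - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


@dataclass
class EpisodeBatch:
    """Rollout storage for one PPO iteration: K parallel episodes of T steps."""

    x: np.ndarray          # (T, K, n_in) input spikes
    actions: np.ndarray    # (T, K, 2) raw sampled velocities
    rewards: np.ndarray    # (T, K)
    values: np.ndarray     # (T, K)
    logp_old: np.ndarray   # (T, K)
    cache: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        T, K = self.rewards.shape
        for name, arr, shape in (
            ("x", self.x, (T, K)), ("actions", self.actions, (T, K, 2)),
            ("values", self.values, (T, K)), ("logp_old", self.logp_old, (T, K)),
        ):
            if arr.shape[: len(shape)] != shape:
                raise ValueError(f"{name} has shape {arr.shape}, inconsistent with T={T}, K={K}")


def collect_episodes(
    topology: NetworkTopology,
    params: SAMParams,
    arena: Arena,
    cfg: NavConfig,
    rng: np.random.Generator,
) -> Tuple[EpisodeBatch, dict]:
    """Closed-loop rollout of K episodes, caching the unroll for BPTT.

    Episodes run in parallel lanes; at each step the position is
    population-coded, the previous step's reward is volley-coded, the network
    advances one step, and the sampled (capped) velocity drives the arena.
    """
    K, T, H = cfg.K, cfg.T, topology.n_hidden
    n_in = cfg.n_in
    preferred = np.linspace(0.0, 1.0, cfg.n_pos)
    mu, lam_a, kappa = params.mu, params.lam, params.mu
    W, d = topology.weights, topology.delays
    dt_s = params.dt / 1000.0

    pos = arena.sample_position(rng, K)
    prev_reward = np.zeros(K)

    V = np.zeros((K, H)); Ve = np.zeros((K, H)); Vi = np.zeros((K, H))
    tau = np.zeros((K, H)); z = np.zeros((K, H)); ref = np.zeros((K, H), dtype=np.int64)
    y = np.zeros((K, 5))

    xs = np.zeros((T, K, n_in))
    zs = np.zeros((T, K, H))
    Vs = np.empty((T, K, H)); gammas = np.empty((T, K, H)); gates = np.ones((T, K, H))
    ys = np.zeros((T, K, 5))
    actions = np.zeros((T, K, 2)); rewards = np.zeros((T, K))
    values = np.zeros((T, K)); logps = np.zeros((T, K))
    path_lengths: List[int] = []
    steps_since_goal = np.zeros(K, dtype=np.int64)

    for t in range(T):
        rates = np.concatenate(
            [encode_position(pos[:, 0], preferred, cfg.r_max),
             encode_position(pos[:, 1], preferred, cfg.r_max)], axis=1)
        x_t = np.empty((K, n_in))
        x_t[:, : 2 * cfg.n_pos] = rng.random((K, 2 * cfg.n_pos)) < np.clip(rates * dt_s, 0, 1)
        x_t[:, 2 * cfg.n_pos :] = np.stack([encode_reward(r, cfg.n_reward) for r in prev_reward])
        xs[t] = x_t

        I_s = np.zeros((K, H)); I_e = np.zeros((K, H)); I_i = np.zeros((K, H))
        if t - d["W_rec_soma"] >= 0:
            I_s += zs[t - d["W_rec_soma"]] @ W["W_rec_soma"]
        if t - d["W_in_e"] >= 0:
            I_e += xs[t - d["W_in_e"]] @ W["W_in_e"]
        if t - d["W_rec_e"] >= 0:
            I_e += zs[t - d["W_rec_e"]] @ W["W_rec_e"]
        if t - d["W_in_i"] >= 0:
            I_i += xs[t - d["W_in_i"]] @ W["W_in_i"]
        if t - d["W_rec_i"] >= 0:
            I_i += zs[t - d["W_rec_i"]] @ W["W_rec_i"]

        tau = lam_a * tau + (1.0 - lam_a) * z
        gamma = params.tau0 + params.eta * tau
        V = mu * V + (1.0 - mu) * params.R_m * I_s \
            + (1.0 - mu) * params.g_exc * (Ve - params.V_exc) \
            + (1.0 - mu) * params.g_inh * (Vi - params.V_inh) - gamma * z
        Ve = mu * Ve + (1.0 - mu) * params.R_me * I_e
        Vi = mu * Vi + (1.0 - mu) * params.R_mi * I_i
        gate = ref == 0
        fire = gate & (V > gamma)
        z = fire.astype(float)
        ref = np.where(fire, params.n_ref, np.maximum(ref - 1, 0))
        y = kappa * y + (1.0 - kappa) * (z @ topology.W_out + topology.b_out)

        zs[t] = z; Vs[t] = V; gammas[t] = gamma; gates[t] = gate; ys[t] = y

        env_a, raw_a, logp, value = decode_action(y, rng, cfg.max_speed)
        pos, reward = arena.step(pos, env_a, rng)
        steps_since_goal += 1
        for k in np.flatnonzero(reward > 0):
            path_lengths.append(int(steps_since_goal[k]))
            steps_since_goal[k] = 0
        actions[t] = raw_a; rewards[t] = reward; values[t] = value; logps[t] = logp
        prev_reward = reward

    cache = {"z": zs, "V": Vs, "gamma": gammas, "gate": gates, "y": ys, "x": xs,
             "k_damp": cfg.k_damp, "smooth": False}
    batch = EpisodeBatch(x=xs, actions=actions, rewards=rewards, values=values,
                         logp_old=logps, cache=cache)
    info = {
        "goals": float(rewards.sum()),
        "mean_path_length": float(np.mean(path_lengths)) if path_lengths else float(T),
    }
    return batch, info


def _policy_grads(
    ys: np.ndarray, batch: EpisodeBatch, advantages: np.ndarray, returns: np.ndarray,
    cfg: NavConfig,
) -> Tuple[float, float, np.ndarray]:
    """Clipped-surrogate and value losses with their gradient w.r.t. the readouts."""
    T, K, _ = ys.shape
    mean = np.tanh(ys[..., 0:2])
    std = 1.0 / (1.0 + np.exp(-ys[..., 2:4]))
    a = batch.actions
    logp = (-0.5 * ((a - mean) / std) ** 2 - np.log(std) - 0.5 * np.log(2 * np.pi)).sum(axis=-1)
    ratio = np.exp(logp - batch.logp_old)
    clipped = np.clip(ratio, 1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps)
    obj = np.minimum(ratio * advantages, clipped * advantages)
    policy_loss = float(-obj.mean())
    # gradient flows only where the unclipped branch attains the minimum
    flow = (ratio * advantages <= clipped * advantages).astype(float)
    dL_dlogp = -advantages * ratio * flow / (T * K)

    dlogp_dmean = (a - mean) / std**2
    dlogp_dstd = ((a - mean) ** 2 / std**2 - 1.0) / std
    dL_dy = np.zeros_like(ys)
    dL_dy[..., 0:2] = dL_dlogp[..., None] * dlogp_dmean * (1.0 - mean**2)
    dL_dy[..., 2:4] = dL_dlogp[..., None] * dlogp_dstd * std * (1.0 - std)

    v = ys[..., 4]
    value_loss = float(cfg.value_coef * np.mean((v - returns) ** 2))
    dL_dy[..., 4] = 2.0 * cfg.value_coef * (v - returns) / (T * K)
    return policy_loss, value_loss, dL_dy


def ppo_update(
    topology: NetworkTopology,
    params: SAMParams,
    batch: EpisodeBatch,
    cfg: NavConfig,
    adam: Adam,
    rng: np.random.Generator,
) -> Tuple[NetworkTopology, Dict[str, float]]:
    """One PPO iteration: clipped surrogate + value + rate losses, one ADAM step.

    With ``ppo_epochs=1`` the update reuses the rollout's cached unroll
    (probability ratio 1, clip inactive), matching a single optimizer step per
    iteration; further epochs re-unroll under the current parameters with the
    stored inputs and actions.
    """
    returns = discounted_returns(batch.rewards, cfg.gamma)
    adv = returns - batch.values
    adv = (adv - adv.mean()) / (adv.std() + 1e-8)

    topo = topology
    components: Dict[str, float] = {}
    for epoch in range(cfg.ppo_epochs):
        cache = batch.cache if epoch == 0 else forward_pass(topo, params, np.swapaxes(batch.x, 0, 1), k_damp=cfg.k_damp)
        policy_loss, value_loss, dL_dy = _policy_grads(cache["y"], batch, adv, returns, cfg)
        rate_loss, dL_dz = rate_regularization(cache["z"], cfg.f0, cfg.mu_f, params.dt)
        if not np.isfinite(policy_loss + value_loss + rate_loss):
            raise FloatingPointError("non-finite PPO loss")
        grads = backward_pass(topo, params, cache, dL_dy=dL_dy, dL_dz=dL_dz if cfg.mu_f else None)
        updates = adam.step(grads)
        if cfg.rewire:
            topo = rewire_step(topo, {k: updates[k] for k in SIGNED_MATRICES if k in updates},
                               l1=cfg.lr * cfg.l1, rng=rng)
        else:
            topo = topo.copy()
            for name in SIGNED_MATRICES:
                if name in updates:
                    topo.weights[name] = np.where(topo.masks[name], topo.weights[name] + updates[name], 0.0)
        topo.W_out = topo.W_out + updates["W_out"]
        topo.b_out = topo.b_out + updates["b_out"]
        components = {"policy_loss": policy_loss, "value_loss": value_loss,
                      "rate_loss": rate_loss, "loss": policy_loss + value_loss + rate_loss}
    return topo, components


def run_navigation(
    cfg: NavConfig,
    params: Optional[SAMParams] = None,
    topology: Optional[NetworkTopology] = None,
    train: bool = True,
    metrics_fh=None,
) -> Tuple[NetworkTopology, List[dict]]:
    """Full training loop; returns the topology and per-iteration curves.

    Each record holds the goals reached, total loss L(theta) and mean path
    length for one iteration of K episodes.  With ``train=False`` the policy
    is rolled out without updates (the untrained baseline).
    """
    params = params or SAMParams()
    rng = np.random.default_rng(cfg.seed)
    env_rng = np.random.default_rng(rng.integers(2**31))
    if topology is None:
        topology = init_weights(cfg.n_in, cfg.n_hidden, cfg.connectivity,
                                cfg.frac_inhibitory, seed=int(rng.integers(2**31)),
                                params=params, n_out=5)
    arena = Arena(goal=np.array([0.75, 0.75]), step_noise=cfg.step_noise,
                  max_speed=cfg.max_speed, goal_radius=cfg.goal_radius)
    adam = Adam(lr=cfg.lr)
    curves: List[dict] = []
    for it in range(cfg.iterations):
        batch, info = collect_episodes(topology, params, arena, cfg, env_rng)
        components = {"loss": float("nan")}
        if train:
            topology, components = ppo_update(topology, params, batch, cfg, adam, rng)
        record = {"iteration": it, "goals": info["goals"],
                  "mean_path_length": info["mean_path_length"], **components}
        curves.append(record)
        if metrics_fh is not None:
            from .config import write_metrics_record

            write_metrics_record(metrics_fh, record)
    return topology, curves
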