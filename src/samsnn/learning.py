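"""Spike-driven gradient training of SAM networks.

Backpropagation through time is implemented as an explicit adjoint recursion
through the discrete SAM dynamics.  The non-differentiable spike function is
replaced, in the backward pass only, by the pseudo-derivative

    dz/dv = k * max(0, 1 - |v|),      v = (V - Gamma) / Gamma,

so gradient flows through both the membrane potential (factor ``1/Gamma``) and
the adaptive threshold (factor ``-V/Gamma^2``, and onward through the
adaptation trace), which is what lets slow threshold dynamics participate in
learning.  The same backward code computes the exact gradient of a smoothed
network in which spikes are the integral of the pseudo-derivative; that
variant is what finite-difference oracles check.

The supervised loss is the cross entropy between labels and the softmax of
the readout averaged over a trailing window, plus a rate-regularization term
``mu_f * sum_j (rate_j - f0)^2`` pulling every hidden neuron toward a target
rate (``f0`` = 10 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .neuron import SAMParams
from .network import SIGNED_MATRICES, NetworkTopology, rewire_step

__all__ = [
    "TrainConfig",
    "pseudo_derivative",
    "normalized_potential",
    "smoothed_spike",
    "Adam",
    "forward_pass",
    "backward_pass",
    "cross_entropy_readout",
    "rate_regularization",
    "train_classifier",
]

#: Normalized potentials are clipped to this magnitude before the hinge; the
#: hinge is zero beyond |v| = 1 anyway, so this only guards intermediates.
V_NORM_CLIP = 10.0


def pseudo_derivative(v_norm: np.ndarray, k_damp: float = 0.3) -> np.ndarray:
    """Surrogate spike derivative ``k * max(0, 1 - |v|)`` w.r.t. the normalized potential."""
    v = np.asarray(v_norm, dtype=float)
    return k_damp * np.maximum(0.0, 1.0 - np.abs(v))


def normalized_potential(V: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """Threshold-normalized membrane potential ``(V - Gamma) / Gamma`` (requires Gamma > 0)."""
    Gamma = np.asarray(Gamma, dtype=float)
    if np.any(Gamma <= 0):
        raise ValueError("Gamma must be positive")
    return (np.asarray(V, dtype=float) - Gamma) / Gamma


def smoothed_spike(v_norm: np.ndarray, k_damp: float = 0.3) -> np.ndarray:
    """Antiderivative of the pseudo-derivative; the spike function of the smoothed network.

    Piecewise quadratic: 0 below v=-1, saturating at ``k_damp`` above v=1, C1
    everywhere, with slope exactly ``pseudo_derivative``.
    """
    v = np.clip(np.asarray(v_norm, dtype=float), -1.0, 1.0)
    return k_damp * np.where(v <= 0.0, (v + 1.0) ** 2 / 2.0, 1.0 - (1.0 - v) ** 2 / 2.0)


@dataclass
class TrainConfig:
    k_damp: float = 0.3
    lr: float = 1e-3
    batch: int = 10
    epochs: int = 50
    f0: float = 10.0          # target rate, Hz
    mu_f: float = 0.0         # rate-regularization weight
    readout_window: int = 56  # steps averaged for the decision
    seed: int = 0
    l1: float = 0.01          # deep-rewiring L1 coefficient
    rewire: bool = True
    temperature: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.k_damp <= 1.0:
            raise ValueError(f"k_damp must be in (0, 1], got {self.k_damp}")
        if self.readout_window < 1:
            raise ValueError("readout_window must be >= 1")


class Adam:
    """Minimal ADAM optimizer over a dict of named arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        """Return additive updates ``-lr * m_hat / (sqrt(v_hat) + eps)`` per array."""
        self.t += 1
        updates = {}
        for name, g in grads.items():
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            updates[name] = -self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return updates


def forward_pass(
    topology: NetworkTopology,
    params: SAMParams,
    x: np.ndarray,
    k_damp: float = 0.3,
    smooth: bool = False,
) -> Dict[str, np.ndarray]:
    """Batched unroll of the SAM network, caching everything backward needs.

    ``x`` has shape ``(B, T, n_in)``.  With ``smooth=True`` the hard threshold
    and refractory gate are replaced by the differentiable spike function
    :func:`smoothed_spike`, making the whole unrolled graph C1 -- the
    configuration used by finite-difference gradient checks.
    """
    B, T, n_in = x.shape
    if n_in != topology.n_in:
        raise ValueError(f"input has {n_in} channels, topology expects {topology.n_in}")
    H = topology.n_hidden
    n_out = 0 if topology.W_out is None else topology.W_out.shape[1]
    mu, lam, kappa = params.mu, params.lam, params.mu
    W, d = topology.weights, topology.delays

    V = np.zeros((B, H))
    Ve = np.zeros((B, H))
    Vi = np.zeros((B, H))
    tau = np.zeros((B, H))
    z = np.zeros((B, H))
    ref = np.zeros((B, H), dtype=np.int64)
    y = np.zeros((B, n_out))

    zs = np.zeros((T, B, H))
    Vs = np.empty((T, B, H))
    gammas = np.empty((T, B, H))
    gates = np.ones((T, B, H))
    ys = np.zeros((T, B, n_out))
    xs = np.ascontiguousarray(np.swapaxes(x, 0, 1)).astype(float)  # (T, B, n_in)

    use_soma_in = topology.masks["W_in_soma"].any()
    for t in range(T):
        I_s = np.zeros((B, H))
        I_e = np.zeros((B, H))
        I_i = np.zeros((B, H))
        if use_soma_in and t - d["W_in_soma"] >= 0:
            I_s += xs[t - d["W_in_soma"]] @ W["W_in_soma"]
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

        tau = lam * tau + (1.0 - lam) * z
        gamma = params.tau0 + params.eta * tau
        V = mu * V + (1.0 - mu) * params.R_m * I_s \
            + (1.0 - mu) * params.g_exc * (Ve - params.V_exc) \
            + (1.0 - mu) * params.g_inh * (Vi - params.V_inh) - gamma * z
        Ve = mu * Ve + (1.0 - mu) * params.R_me * I_e
        Vi = mu * Vi + (1.0 - mu) * params.R_mi * I_i

        if smooth:
            v_norm = np.clip((V - gamma) / gamma, -V_NORM_CLIP, V_NORM_CLIP)
            z = smoothed_spike(v_norm, k_damp)
        else:
            gate = ref == 0
            fire = gate & (V > gamma)
            z = fire.astype(float)
            ref = np.where(fire, params.n_ref, np.maximum(ref - 1, 0))
            gates[t] = gate

        zs[t] = z
        Vs[t] = V
        gammas[t] = gamma
        if n_out:
            y = kappa * y + (1.0 - kappa) * (z @ topology.W_out + topology.b_out)
            ys[t] = y

    return {"z": zs, "V": Vs, "gamma": gammas, "gate": gates, "y": ys, "x": xs,
            "k_damp": k_damp, "smooth": smooth}


def backward_pass(
    topology: NetworkTopology,
    params: SAMParams,
    cache: Dict[str, np.ndarray],
    dL_dy: Optional[np.ndarray] = None,
    dL_dz: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Adjoint recursion through the cached unroll; returns summed weight gradients.

    ``dL_dy`` and ``dL_dz`` are the direct loss gradients w.r.t. the readout
    traces and hidden spikes, shape ``(T, B, n_out)`` / ``(T, B, H)``.  The
    spike nonlinearity contributes the pseudo-derivative through both V
    (``psi / Gamma``) and Gamma (``-psi * V / Gamma^2``); the threshold's
    dependence on past spikes via the adaptation trace is fully propagated.
    """
    zs, Vs, gammas, gates, ys, xs = (cache[k] for k in ("z", "V", "gamma", "gate", "y", "x"))
    k_damp = cache["k_damp"]
    T, B, H = zs.shape
    n_out = ys.shape[2]
    mu, lam, kappa = params.mu, params.lam, params.mu
    W, d = topology.weights, topology.delays
    use_soma_in = topology.masks["W_in_soma"].any()

    v_norm = np.clip((Vs - gammas) / gammas, -V_NORM_CLIP, V_NORM_CLIP)
    hinge = k_damp * np.maximum(0.0, 1.0 - np.abs(v_norm)) * gates
    dz_dV = hinge / gammas
    dz_dG = -hinge * Vs / gammas**2

    gV = np.zeros((T + 1, B, H))
    gVe = np.zeros((T + 1, B, H))
    gVi = np.zeros((T + 1, B, H))
    gtau = np.zeros((T + 1, B, H))
    gy_run = np.zeros((B, n_out))

    grads = {name: np.zeros_like(W[name]) for name in SIGNED_MATRICES}
    gW_out = np.zeros_like(topology.W_out) if n_out else None
    gb_out = np.zeros(n_out) if n_out else None

    ce = (1.0 - mu) * params.R_me
    ci = (1.0 - mu) * params.R_mi
    cs = (1.0 - mu) * params.R_m

    for t in range(T - 1, -1, -1):
        gz = np.zeros((B, H))
        if dL_dz is not None:
            gz += dL_dz[t]
        if n_out:
            gy_run = (dL_dy[t] if dL_dy is not None else 0.0) + kappa * gy_run
            gz += (1.0 - kappa) * (gy_run @ topology.W_out.T)
        # spikes feed the delayed recurrent drives ...
        if t + d["W_rec_e"] < T:
            gz += (ce * gVe[t + d["W_rec_e"]]) @ W["W_rec_e"].T
        if t + d["W_rec_i"] < T:
            gz += (ci * gVi[t + d["W_rec_i"]]) @ W["W_rec_i"].T
        if t + d["W_rec_soma"] < T:
            gz += (cs * gV[t + d["W_rec_soma"]]) @ W["W_rec_soma"].T
        # ... the next step's soft reset and adaptation trace
        if t + 1 < T:
            gz += -gammas[t + 1] * gV[t + 1] + (1.0 - lam) * gtau[t + 1]

        gV[t] = dz_dV[t] * gz + mu * gV[t + 1]
        z_prev = zs[t - 1] if t > 0 else 0.0
        gG = dz_dG[t] * gz - z_prev * gV[t]
        gtau[t] = params.eta * gG + lam * gtau[t + 1]
        gVe[t] = (1.0 - mu) * params.g_exc * gV[t + 1] + mu * gVe[t + 1]
        gVi[t] = (1.0 - mu) * params.g_inh * gV[t + 1] + mu * gVi[t + 1]

        # weight gradients at step t
        if t - d["W_rec_e"] >= 0:
            grads["W_rec_e"] += zs[t - d["W_rec_e"]].T @ (ce * gVe[t])
        if t - d["W_in_e"] >= 0:
            grads["W_in_e"] += xs[t - d["W_in_e"]].T @ (ce * gVe[t])
        if t - d["W_rec_i"] >= 0:
            grads["W_rec_i"] += zs[t - d["W_rec_i"]].T @ (ci * gVi[t])
        if t - d["W_in_i"] >= 0:
            grads["W_in_i"] += xs[t - d["W_in_i"]].T @ (ci * gVi[t])
        if t - d["W_rec_soma"] >= 0:
            grads["W_rec_soma"] += zs[t - d["W_rec_soma"]].T @ (cs * gV[t])
        if use_soma_in and t - d["W_in_soma"] >= 0:
            grads["W_in_soma"] += xs[t - d["W_in_soma"]].T @ (cs * gV[t])
        if n_out:
            gW_out += zs[t].T @ ((1.0 - kappa) * gy_run)
            gb_out += (1.0 - kappa) * gy_run.sum(axis=0)

    # gradients exist only where synapses are active
    for name in grads:
        grads[name] = np.where(topology.masks[name], grads[name], 0.0)
    if n_out:
        grads["W_out"] = gW_out
        grads["b_out"] = gb_out
    return grads


def cross_entropy_readout(
    y_hist: np.ndarray, labels: np.ndarray, window: int
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Cross entropy of the softmax of the readout averaged over the last ``window`` steps.

    Returns ``(loss, dL_dy, predictions)`` with ``dL_dy`` shaped like ``y_hist``.
    """
    T, B, n_out = y_hist.shape
    window = min(window, T)
    logits = y_hist[-window:].mean(axis=0)            # (B, n_out)
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    loss = float(-np.log(probs[np.arange(B), labels] + 1e-12).mean())
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    dL_dy = np.zeros_like(y_hist)
    dL_dy[-window:] = dlogits / window
    return loss, dL_dy, probs.argmax(axis=1)


def rate_regularization(
    zs: np.ndarray, f0: float, mu_f: float, dt: float
) -> Tuple[float, np.ndarray]:
    """Squared deviation of each neuron's empirical rate (Hz) from the target ``f0``.

    Returns ``(loss, dL_dz)``; exactly zero when every rate equals ``f0``.
    """
    T, B, H = zs.shape
    scale = 1000.0 / (T * B * dt)                     # spikes -> Hz
    rates = zs.sum(axis=(0, 1)) * scale
    loss = float(mu_f * np.sum((rates - f0) ** 2))
    dL_dz = np.broadcast_to(2.0 * mu_f * (rates - f0) * scale, (T, B, H)).copy()
    return loss, dL_dz


def train_classifier(
    topology: NetworkTopology,
    X: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    params: Optional[SAMParams] = None,
    X_val: Optional[np.ndarray] = None,
    labels_val: Optional[np.ndarray] = None,
    target_acc: Optional[float] = None,
) -> Tuple[NetworkTopology, List[dict]]:
    """Train a SAM network on labeled spike sequences ``X`` of shape (N, T, n_in).

    Per batch: unroll, evaluate the windowed cross entropy plus rate
    regularization, backpropagate with the surrogate gradient, take one ADAM
    step, and apply deep rewiring to the sign-constrained pathways (L1 drift
    ``lr * l1``, conserving the active-synapse count).  Returns the trained
    topology and per-epoch metrics; training stops early once ``target_acc``
    is reached on the training set.
    """
    params = params or SAMParams()
    rng = np.random.default_rng(cfg.seed)
    adam = Adam(lr=cfg.lr)
    topo = topology.copy()
    N = X.shape[0]
    metrics: List[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(N)
        losses, correct = [], 0
        for start in range(0, N, cfg.batch):
            idx = order[start : start + cfg.batch]
            cache = forward_pass(topo, params, X[idx], k_damp=cfg.k_damp)
            loss, dL_dy, preds = cross_entropy_readout(cache["y"], labels[idx], cfg.readout_window)
            dL_dz = None
            if cfg.mu_f:
                reg, dL_dz = rate_regularization(cache["z"], cfg.f0, cfg.mu_f, params.dt)
                loss += reg
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start} (samples {idx.tolist()})"
                )
            grads = backward_pass(topo, params, cache, dL_dy=dL_dy, dL_dz=dL_dz)
            updates = adam.step(grads)
            if cfg.rewire:
                topo = rewire_step(
                    topo,
                    {k: updates[k] for k in SIGNED_MATRICES if k in updates},
                    l1=cfg.lr * cfg.l1,
                    temperature=cfg.temperature,
                    rng=rng,
                )
            else:
                for name in SIGNED_MATRICES:
                    if name in updates:
                        topo.weights[name] = np.where(
                            topo.masks[name], topo.weights[name] + updates[name], 0.0
                        )
            if "W_out" in updates:
                topo.W_out = topo.W_out + updates["W_out"]
                topo.b_out = topo.b_out + updates["b_out"]
            losses.append(loss)
            correct += int((preds == labels[idx]).sum())

        record = {"epoch": epoch, "loss": float(np.mean(losses)), "acc": correct / N}
        if X_val is not None:
            record["val_acc"] = evaluate_classifier(topo, X_val, labels_val, cfg, params)
        metrics.append(record)
        if target_acc is not None and record["acc"] >= target_acc:
            break
    return topo, metrics


def evaluate_classifier(
    topology: NetworkTopology,
    X: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    params: Optional[SAMParams] = None,
    batch: int = 32,
) -> float:
    """Classification accuracy of the windowed-softmax readout on ``X``."""
    params = params or SAMParams()
    correct = 0
    for start in range(0, X.shape[0], batch):
        cache = forward_pass(topology, params, X[start : start + batch], k_damp=cfg.k_damp)
        _, _, preds = cross_entropy_readout(
            cache["y"], labels[start : start + batch], cfg.readout_window
        )
        correct += int((preds == labels[start : start + batch]).sum())
    return correct / X.shape[0]
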