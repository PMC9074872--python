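"""Recurrent SAM network: sparse signed topology, delays, simulation, rewiring.

The architecture has three layers.  Input spike trains reach the hidden SAM
population through three feedforward pathways (one per compartment) and the
hidden population feeds back on itself through three recurrent pathways; the
soma receives no feedforward current by default, only recurrent input.  A
linear leaky readout integrates hidden spikes.

Weights obey a Dale-like sign constraint: each presynaptic neuron is assigned
a fixed sign and every outgoing synapse carries it.  Sparse connectivity is
maintained by deep rewiring: weights whose signed magnitude would cross zero
become dormant and an equal number of dormant synapses is re-activated, so the
active-synapse count is conserved while signs are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from .neuron import SAMParams

__all__ = ["SpikeRaster", "NetworkTopology", "init_weights", "forward", "rewire_step"]

#: Weight matrices subject to the presynaptic sign constraint and rewiring,
#: with the population providing their rows.
SIGNED_MATRICES = {
    "W_in_soma": "in",
    "W_in_e": "in",
    "W_in_i": "in",
    "W_rec_soma": "rec",
    "W_rec_e": "rec",
    "W_rec_i": "rec",
}

#: Spectral radius the somatic recurrent loop is scaled to at initialization.
SPECTRAL_RADIUS = 0.9

#: Magnitude given to freshly re-activated synapses during rewiring.
REWIRE_EPSILON = 1e-12


@dataclass
class SpikeRaster:
    """Time-indexed binary spike events of a neuron population.

    ``events`` is an ``(n_events, 2)`` integer array of ``(step, neuron)``
    pairs with at most one event per pair.
    """

    events: np.ndarray
    n_neurons: int
    n_steps: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if ev.size:
            if ev[:, 0].min() < 0 or ev[:, 0].max() >= self.n_steps:
                raise ValueError("spike step out of range")
            if ev[:, 1].min() < 0 or ev[:, 1].max() >= self.n_neurons:
                raise ValueError("spike neuron index out of range")
            keys = ev[:, 0] * self.n_neurons + ev[:, 1]
            if np.unique(keys).size != keys.size:
                raise ValueError("duplicate (step, neuron) events")
        self.events = ev

    @classmethod
    def from_dense(cls, dense: np.ndarray) -> "SpikeRaster":
        dense = np.asarray(dense)
        steps, neurons = np.nonzero(dense)
        return cls(np.column_stack([steps, neurons]), dense.shape[1], dense.shape[0])

    def to_dense(self) -> np.ndarray:
        out = np.zeros((self.n_steps, self.n_neurons), dtype=np.int8)
        if self.events.size:
            out[self.events[:, 0], self.events[:, 1]] = 1
        return out

    @property
    def n_spikes(self) -> int:
        return self.events.shape[0]

    def save(self, path) -> None:
        """Two-column delimited event file with a header carrying the shape."""
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={self.n_neurons} n_steps={self.n_steps}\n")
            fh.write("step\tneuron\n")
            for step, neuron in self.events:
                fh.write(f"{step}\t{neuron}\n")

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline().strip()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
            fh.readline()  # column names
            rows = [line.split() for line in fh if line.strip()]
        events = np.asarray(rows, dtype=np.int64).reshape(-1, 2)
        return cls(events, int(meta["n_neurons"]), int(meta["n_steps"]))


@dataclass
class NetworkTopology:
    """Signed sparse weights for the six pathways, with per-pathway delays.

    Matrices are stored dense with shape ``(n_pre, n_post)``; the boolean
    ``masks`` mark active synapses (inactive entries are exactly zero).
    ``sign_in`` / ``sign_rec`` hold the per-presynaptic-neuron signs, which
    dormant synapses inherit on reconnection.  ``W_out`` is the unconstrained
    readout matrix with bias ``b_out``.
    """

    n_in: int
    n_hidden: int
    weights: Dict[str, np.ndarray]
    masks: Dict[str, np.ndarray]
    sign_in: np.ndarray
    sign_rec: np.ndarray
    delays: Dict[str, int]
    W_out: Optional[np.ndarray] = None
    b_out: Optional[np.ndarray] = None

    def sign_of(self, name: str) -> np.ndarray:
        """Column vector of presynaptic signs for matrix ``name``."""
        signs = self.sign_in if SIGNED_MATRICES[name] == "in" else self.sign_rec
        return signs[:, None]

    def active_counts(self) -> Dict[str, int]:
        return {k: int(m.sum()) for k, m in self.masks.items()}

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            n_in=self.n_in,
            n_hidden=self.n_hidden,
            weights={k: v.copy() for k, v in self.weights.items()},
            masks={k: v.copy() for k, v in self.masks.items()},
            sign_in=self.sign_in.copy(),
            sign_rec=self.sign_rec.copy(),
            delays=dict(self.delays),
            W_out=None if self.W_out is None else self.W_out.copy(),
            b_out=None if self.b_out is None else self.b_out.copy(),
        )

    def save(self, path) -> None:
        arrays = {f"weights/{k}": v for k, v in self.weights.items()}
        arrays.update({f"masks/{k}": v for k, v in self.masks.items()})
        arrays.update(sign_in=self.sign_in, sign_rec=self.sign_rec)
        arrays.update({f"delays/{k}": np.asarray(v) for k, v in self.delays.items()})
        arrays.update(meta=np.asarray([self.n_in, self.n_hidden]))
        if self.W_out is not None:
            arrays.update(W_out=self.W_out, b_out=self.b_out)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "NetworkTopology":
        data = np.load(path)
        weights = {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("weights/")}
        masks = {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("masks/")}
        delays = {k.split("/", 1)[1]: int(data[k]) for k in data.files if k.startswith("delays/")}
        n_in, n_hidden = data["meta"]
        return cls(
            n_in=int(n_in), n_hidden=int(n_hidden), weights=weights, masks=masks,
            sign_in=data["sign_in"], sign_rec=data["sign_rec"], delays=delays,
            W_out=data["W_out"] if "W_out" in data.files else None,
            b_out=data["b_out"] if "b_out" in data.files else None,
        )


def init_weights(
    n_in: int,
    n_hidden: int,
    connectivity: float,
    frac_inhibitory: float = 0.2,
    seed: int = 0,
    params: Optional[SAMParams] = None,
    n_out: int = 0,
    input_to_soma: bool = False,
) -> NetworkTopology:
    """Draw a signed sparse topology.

    Magnitudes come from ``(w0 / sqrt(n_pre)) * |N(0, 1)|`` with the scaling
    factor ``w0 = dt / R_m``; each presynaptic neuron receives a random sign
    (inhibitory with probability ``frac_inhibitory``), the somatic recurrent
    matrix is rescaled to spectral radius < 1 and self-connections there are
    removed, and every pathway is thinned by an independent Bernoulli mask at
    the requested ``connectivity``.
    """
    if not 0.0 < connectivity <= 1.0:
        raise ValueError(f"connectivity must be in (0, 1], got {connectivity}")
    if not 0.0 <= frac_inhibitory <= 1.0:
        raise ValueError(f"frac_inhibitory must be in [0, 1], got {frac_inhibitory}")
    params = params or SAMParams()
    rng = np.random.default_rng(seed)
    w0 = params.dt / params.R_m

    sign_in = np.where(rng.random(n_in) < frac_inhibitory, -1.0, 1.0)
    sign_rec = np.where(rng.random(n_hidden) < frac_inhibitory, -1.0, 1.0)

    weights: Dict[str, np.ndarray] = {}
    masks: Dict[str, np.ndarray] = {}
    for name, pre in SIGNED_MATRICES.items():
        n_pre = n_in if pre == "in" else n_hidden
        signs = sign_in if pre == "in" else sign_rec
        mag = np.abs(rng.standard_normal((n_pre, n_hidden))) * (w0 / np.sqrt(n_pre))
        W = mag * signs[:, None]
        mask = rng.random((n_pre, n_hidden)) < connectivity
        if name == "W_rec_soma":
            np.fill_diagonal(mask, False)
        if name == "W_in_soma" and not input_to_soma:
            mask[:] = False
        weights[name] = np.where(mask, W, 0.0)
        masks[name] = mask

    # Stabilize the somatic feedback loop.
    eig = np.linalg.eigvals(weights["W_rec_soma"])
    radius = float(np.abs(eig).max()) if eig.size else 0.0
    if radius > 0:
        scale = SPECTRAL_RADIUS / radius if radius >= 1.0 else 1.0
        weights["W_rec_soma"] = weights["W_rec_soma"] * scale

    delays = {
        "W_in_soma": params.delay_steps("d_input"),
        "W_in_e": params.delay_steps("d_input_e"),
        "W_in_i": params.delay_steps("d_input_i"),
        "W_rec_soma": params.delay_steps("d_rec"),
        "W_rec_e": params.delay_steps("d_rec_e"),
        "W_rec_i": params.delay_steps("d_rec_i"),
    }

    W_out = b_out = None
    if n_out:
        W_out = rng.standard_normal((n_hidden, n_out)) / np.sqrt(n_hidden)
        b_out = np.zeros(n_out)

    return NetworkTopology(
        n_in=n_in, n_hidden=n_hidden, weights=weights, masks=masks,
        sign_in=sign_in, sign_rec=sign_rec, delays=delays, W_out=W_out, b_out=b_out,
    )


def _delayed(dense: np.ndarray, t: int, d: int) -> Optional[np.ndarray]:
    return dense[t - d] if t - d >= 0 else None


def forward(
    topology: NetworkTopology,
    input_raster: SpikeRaster,
    params: SAMParams,
    n_steps: Optional[int] = None,
) -> Tuple[SpikeRaster, np.ndarray, np.ndarray, int]:
    """Simulate the network on an input raster.

    Returns ``(hidden_raster, readout_traces, gamma_traces, synops)`` where the
    readout is a leaky integrator with the membrane time constant and SynOps
    counts one operation per spike and outgoing active synapse (readout fan-out
    included for hidden spikes).
    """
    if input_raster.n_neurons != topology.n_in:
        raise ValueError(
            f"input raster has {input_raster.n_neurons} channels, topology expects {topology.n_in}"
        )
    n_steps = n_steps if n_steps is not None else input_raster.n_steps
    if any(d >= n_steps for d in topology.delays.values()):
        raise ValueError("all delays must be shorter than the simulation horizon")

    H = topology.n_hidden
    n_out = 0 if topology.W_out is None else topology.W_out.shape[1]
    x = np.zeros((n_steps, topology.n_in), dtype=np.int8)
    dense_in = input_raster.to_dense()
    x[: dense_in.shape[0]] = dense_in[:n_steps]

    mu, lam = params.mu, params.lam
    kappa = mu  # readout leak shares the membrane time constant
    W = topology.weights
    d = topology.delays

    V = np.zeros(H)
    Ve = np.zeros(H)
    Vi = np.zeros(H)
    tau = np.zeros(H)
    z = np.zeros(H)
    ref = np.zeros(H, dtype=np.int64)
    y = np.zeros(n_out)

    z_hist = np.zeros((n_steps, H), dtype=np.int8)
    gamma_hist = np.empty((n_steps, H))
    y_hist = np.zeros((n_steps, n_out))

    for t in range(n_steps):
        xs = _delayed(x, t, d["W_in_soma"])
        xe = _delayed(x, t, d["W_in_e"])
        xi = _delayed(x, t, d["W_in_i"])
        zs = _delayed(z_hist, t, d["W_rec_soma"])
        ze = _delayed(z_hist, t, d["W_rec_e"])
        zi = _delayed(z_hist, t, d["W_rec_i"])

        I_s = np.zeros(H)
        I_e = np.zeros(H)
        I_i = np.zeros(H)
        if xs is not None:
            I_s += xs @ W["W_in_soma"]
        if zs is not None:
            I_s += zs @ W["W_rec_soma"]
        if xe is not None:
            I_e += xe @ W["W_in_e"]
        if ze is not None:
            I_e += ze @ W["W_rec_e"]
        if xi is not None:
            I_i += xi @ W["W_in_i"]
        if zi is not None:
            I_i += zi @ W["W_rec_i"]

        tau = lam * tau + (1.0 - lam) * z
        gamma = params.tau0 + params.eta * tau
        V = mu * V + (1.0 - mu) * params.R_m * I_s \
            + (1.0 - mu) * params.g_exc * (Ve - params.V_exc) \
            + (1.0 - mu) * params.g_inh * (Vi - params.V_inh) - gamma * z
        Ve = mu * Ve + (1.0 - mu) * params.R_me * I_e
        Vi = mu * Vi + (1.0 - mu) * params.R_mi * I_i
        fire = (ref == 0) & (V > gamma)
        z = fire.astype(float)
        ref = np.where(fire, params.n_ref, np.maximum(ref - 1, 0))

        z_hist[t] = fire
        gamma_hist[t] = gamma
        if n_out:
            y = kappa * y + (1.0 - kappa) * (z @ topology.W_out + topology.b_out)
            y_hist[t] = y

    # SynOps: every spike costs one operation per outgoing active synapse.
    in_fanout = sum(topology.masks[k].sum(axis=1) for k in ("W_in_soma", "W_in_e", "W_in_i"))
    rec_fanout = sum(topology.masks[k].sum(axis=1) for k in ("W_rec_soma", "W_rec_e", "W_rec_i"))
    if n_out:
        rec_fanout = rec_fanout + n_out
    synops = int(x.sum(axis=0) @ in_fanout + z_hist.sum(axis=0) @ rec_fanout)

    return SpikeRaster.from_dense(z_hist), y_hist, gamma_hist, synops


def rewire_step(
    topology: NetworkTopology,
    gradients: Dict[str, np.ndarray],
    l1: float,
    temperature: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NetworkTopology:
    """One deep-rewiring update of the sign-constrained pathways.

    ``gradients`` holds per-weight additive updates (e.g. the negative
    optimizer step).  Active weights receive the update plus an L1 drift of
    magnitude ``l1`` toward zero (and, for ``temperature > 0``, Gaussian noise
    of standard deviation ``sqrt(2*temperature)``); any weight whose signed
    magnitude would cross zero is set dormant, and per matrix an equal number
    of dormant synapses is re-activated at random with the stored presynaptic
    sign, conserving the active count exactly.
    """
    if l1 < 0 or temperature < 0:
        raise ValueError("l1 and temperature must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    new = topology.copy()
    for name in SIGNED_MATRICES:
        W = new.weights[name]
        mask = new.masks[name]
        if not mask.any() and name == "W_in_soma":
            continue
        signs = new.sign_of(name)
        upd = gradients.get(name)
        cand = W.copy()
        if upd is not None:
            cand = cand + np.where(mask, upd, 0.0)
        if l1:
            cand = cand - l1 * np.where(mask, signs, 0.0)
        if temperature:
            cand = cand + np.where(mask, np.sqrt(2.0 * temperature) * rng.standard_normal(W.shape), 0.0)

        crossed = mask & (cand * signs <= 0.0)
        n_crossed = int(crossed.sum())
        cand[crossed] = 0.0
        mask = mask & ~crossed

        if n_crossed:
            dormant = ~mask
            if name == "W_rec_soma":
                diag = np.eye(mask.shape[0], mask.shape[1], dtype=bool)
                dormant = dormant & ~diag
            slots = np.flatnonzero(dormant.ravel())
            k = min(n_crossed, slots.size)
            chosen = rng.choice(slots, size=k, replace=False)
            rows, cols = np.unravel_index(chosen, mask.shape)
            mask[rows, cols] = True
            cand[rows, cols] = REWIRE_EPSILON * signs[rows, 0]

        new.weights[name] = np.where(mask, cand, 0.0)
        new.masks[name] = mask
    return new
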