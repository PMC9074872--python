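"""Discrete-time integration of the self-adaptive multicompartment (SAM) neuron.

A SAM neuron is a leaky integrate-and-fire soma coupled to two lumped dendritic
compartments (one excitatory, one inhibitory) with a spike-frequency-adaptive
firing threshold.  With membrane decay ``mu = exp(-dt/tau_v)`` and adaptation
decay ``lam = exp(-dt/tau_a)`` the per-step update is::

    tau(t+dt)   = lam*tau(t) + (1-lam)*z(t)                 # adaptation trace
    Gamma(t+dt) = tau0 + eta*tau(t+dt)                      # dynamic threshold
    V(t+dt)     = mu*V(t) + (1-mu)*R_m*I_soma(t)
                  + (1-mu)*[g_exc*(Ve(t)-V_exc) + g_inh*(Vi(t)-V_inh)]
                  - Gamma(t+dt)*z(t)                        # soft reset
    Ve(t+dt)    = mu*Ve(t) + (1-mu)*R_me*I_exc(t)
    Vi(t+dt)    = mu*Vi(t) + (1-mu)*R_mi*I_inh(t)
    z(t+dt)     = 1  iff  V(t+dt) > Gamma(t+dt) and not refractory

All quantities are in normalized model units; nominal "nA" drive amplitudes map
one-to-one onto the dimensionless drive.  The update is fully deterministic:
no randomness lives in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SAMParams",
    "SAMState",
    "DriveVector",
    "step_neuron",
    "dendrite_fixed_point",
    "dendrite_transient",
    "threshold_fixed_points",
]


@dataclass(frozen=True)
class SAMParams:
    """Constants of the SAM neuron (normalized model units, times in ms).

    Defaults are the reference parameter set: unit membrane resistances,
    ``tau_v`` = 20 ms, ``tau_a`` = 700 ms, ``eta`` = 1.8, ``tau0`` = 0.01,
    unit dendro-somatic couplings with zero reversal potentials, 1-ms step
    and 5-ms synaptic delays.  The refractory duration ``t_ref`` (7 ms) is a
    model choice calibrated so that the excitatory f-I curve saturates near
    its reported plateau; the plateau level is sensitive to it.
    """

    R_m: float = 1.0
    R_me: float = 1.0
    R_mi: float = 1.0
    tau_v: float = 20.0
    tau_a: float = 700.0
    eta: float = 1.8
    tau0: float = 0.01
    g_exc: float = 1.0
    g_inh: float = 1.0
    V_exc: float = 0.0
    V_inh: float = 0.0
    dt: float = 1.0
    t_ref: float = 7.0
    d_input: float = 5.0
    d_rec: float = 5.0
    d_input_e: float = 5.0
    d_input_i: float = 5.0
    d_rec_e: float = 5.0
    d_rec_i: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tau_v", "tau_a", "dt", "tau0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.eta < 0:
            raise ValueError(f"eta must be non-negative, got {self.eta}")
        if self.t_ref < 0:
            raise ValueError(f"t_ref must be non-negative, got {self.t_ref}")
        for name in ("d_input", "d_rec", "d_input_e", "d_input_i", "d_rec_e", "d_rec_i"):
            d = getattr(self, name)
            if d < 0:
                raise ValueError(f"{name} must be non-negative, got {d}")
            steps = d / self.dt
            if abs(steps - round(steps)) > 1e-9:
                raise ValueError(f"{name}={d} is not an integer multiple of dt={self.dt}")

    # -- derived discrete-time constants ------------------------------------
    @property
    def mu(self) -> float:
        """Membrane decay per step, exp(-dt/tau_v)."""
        return float(np.exp(-self.dt / self.tau_v))

    @property
    def lam(self) -> float:
        """Adaptation decay per step, exp(-dt/tau_a)."""
        return float(np.exp(-self.dt / self.tau_a))

    @property
    def n_ref(self) -> int:
        """Refractory duration in steps."""
        return int(round(self.t_ref / self.dt))

    def delay_steps(self, name: str) -> int:
        return int(round(getattr(self, name) / self.dt))

    def with_(self, **kw) -> "SAMParams":
        return replace(self, **kw)


@dataclass
class SAMState:
    """Per-neuron dynamic variables of a SAM population."""

    V: np.ndarray
    V_den_e: np.ndarray
    V_den_i: np.ndarray
    tau_trace: np.ndarray
    Gamma: np.ndarray
    z: np.ndarray
    ref_count: np.ndarray

    @classmethod
    def zeros(cls, n: int, params: SAMParams) -> "SAMState":
        """Resting state: all potentials and traces at zero, threshold at tau0."""
        return cls(
            V=np.zeros(n),
            V_den_e=np.zeros(n),
            V_den_i=np.zeros(n),
            tau_trace=np.zeros(n),
            Gamma=np.full(n, params.tau0),
            z=np.zeros(n, dtype=np.int8),
            ref_count=np.zeros(n, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]


@dataclass
class DriveVector:
    """Input currents for one step: somatic, excitatory- and inhibitory-dendritic."""

    I_soma: np.ndarray
    I_exc: np.ndarray
    I_inh: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "DriveVector":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))


def step_neuron(state: SAMState, drive: DriveVector, params: SAMParams) -> SAMState:
    """Advance a SAM population by one time step.

    Order of operations: the adaptation trace and threshold are refreshed with
    the previous step's spikes first, the soma is integrated against the *old*
    dendritic potentials (with the soft reset using the refreshed threshold),
    then the dendrites absorb this step's currents, and finally the spike test
    ``V > Gamma`` is evaluated outside the refractory window.
    """
    n = state.n
    for name, arr in (("I_soma", drive.I_soma), ("I_exc", drive.I_exc), ("I_inh", drive.I_inh)):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (n,):
            raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")

    mu, lam = params.mu, params.lam
    z_prev = state.z.astype(float)

    tau_new = lam * state.tau_trace + (1.0 - lam) * z_prev
    gamma_new = params.tau0 + params.eta * tau_new
    V_new = (
        mu * state.V
        + (1.0 - mu) * params.R_m * drive.I_soma
        + (1.0 - mu) * params.g_exc * (state.V_den_e - params.V_exc)
        + (1.0 - mu) * params.g_inh * (state.V_den_i - params.V_inh)
        - gamma_new * z_prev
    )
    Ve_new = mu * state.V_den_e + (1.0 - mu) * params.R_me * drive.I_exc
    Vi_new = mu * state.V_den_i + (1.0 - mu) * params.R_mi * drive.I_inh

    open_gate = state.ref_count == 0
    z_new = (open_gate & (V_new > gamma_new)).astype(np.int8)
    ref_new = np.where(z_new == 1, params.n_ref, np.maximum(state.ref_count - 1, 0))

    return SAMState(
        V=V_new,
        V_den_e=Ve_new,
        V_den_i=Vi_new,
        tau_trace=tau_new,
        Gamma=gamma_new,
        z=z_new,
        ref_count=ref_new,
    )


def dendrite_fixed_point(I: float, R: float, params: SAMParams) -> float:
    """Steady state of the dendritic recursion under constant current: ``R * I``."""
    return R * I


def dendrite_transient(I: float, R: float, params: SAMParams, t_steps: int, v0: float = 0.0) -> float:
    """Dendritic potential after ``t_steps`` under constant current, from ``v0``.

    Closed form of the linear recursion: ``R*I + (v0 - R*I) * mu**t``.
    """
    mu = params.mu
    return R * I + (v0 - R * I) * mu**t_steps


def threshold_fixed_points(spike_pattern: Sequence[int], params: SAMParams) -> float:
    """Cycle-averaged limiting threshold for a periodically repeated spike pattern.

    The adaptation trace obeys ``tau(t+1) = lam*tau(t) + (1-lam)*z(t)``.  For a
    pattern of period P the limit cycle start value has the closed form
    ``tau* = c / (1 - lam**P)`` where ``c`` is the pattern's accumulated input
    over one period; the function returns the mean of ``tau0 + eta*tau`` over
    the limit cycle.  For a constant pattern this reduces to ``tau0 + eta*z``.
    """
    z = np.asarray(spike_pattern, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("spike_pattern must be a non-empty 1-D sequence")
    if not np.all((z == 0) | (z == 1)):
        raise ValueError("spike_pattern must be binary")
    lam = params.lam
    P = z.size
    # Accumulated increment over one period, and the limit-cycle start value.
    powers = lam ** np.arange(P - 1, -1, -1.0)
    c = (1.0 - lam) * float(powers @ z)
    tau_start = c / (1.0 - lam**P)
    # Iterate one period from the fixed point and average Gamma over the cycle.
    taus = np.empty(P)
    tau = tau_start
    for i in range(P):
        tau = lam * tau + (1.0 - lam) * z[i]
        taus[i] = tau
    return float(params.tau0 + params.eta * taus.mean())
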