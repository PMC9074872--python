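"""Single-neuron characterization: f-I curves, threshold saturation, parameter grids.

The protocols here are current-clamp experiments on one SAM neuron.  Because
the soma only receives recurrent input in the network architecture, constant
test currents are injected into the dendritic compartments: the excitatory
dendrite alone (``excitatory_only``), the inhibitory dendrite alone with a
hyperpolarizing sign (``inhibitory_only``), or both at once (``simultaneous``).
In the paired protocol the inhibitory amplitude is ``inh_ratio`` times the
excitatory one; with the symmetric default couplings an equal-and-opposite
pair would cancel exactly in the soma, so the default ratio is 0.15, the value
implied by the reported shift of the f-I saturation point.

Everything is deterministic: repeated runs with the same configuration are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .neuron import SAMParams

__all__ = ["SweepResult", "fi_curve", "detect_knee", "param_grid", "simulate_constant_drive"]

#: Parameters that may serve as grid axes in :func:`param_grid`.
GRID_PARAMS = ("eta", "tau0", "tau_v", "R_m")

#: Default knee-detection tolerance, Hz per grid step.
KNEE_EPSILON = 0.5


@dataclass
class SweepResult:
    """f-I sweep outcome: steady rates and saturated thresholds per drive."""

    drive_values: np.ndarray
    rates: np.ndarray          # Hz
    gamma_sat: np.ndarray      # time-averaged threshold, last second
    knee: Optional[float]      # smallest drive on the rate plateau, None if no plateau
    mode: str


def simulate_constant_drive(
    I_exc: np.ndarray,
    I_inh: np.ndarray,
    params: SAMParams,
    n_steps: int,
    *,
    tau_v: Optional[np.ndarray] = None,
    eta: Optional[np.ndarray] = None,
    tau0: Optional[np.ndarray] = None,
    R_scale: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate a bank of independent SAM neurons under constant dendritic drive.

    Each lane of the vector arguments is one independent neuron; the optional
    per-lane parameter vectors override the scalar values in ``params``
    (``R_scale`` scales the common membrane resistance of all compartments).
    Returns ``(spikes, gammas)`` with shape ``(n_steps, n_lanes)``.

    This is the same recursion as :func:`samsnn.neuron.step_neuron` specialized
    to constant currents; equivalence is covered by the test suite.
    """
    I_exc = np.atleast_1d(np.asarray(I_exc, dtype=float))
    I_inh = np.atleast_1d(np.asarray(I_inh, dtype=float))
    n = I_exc.shape[0]

    tau_v_v = np.full(n, params.tau_v) if tau_v is None else np.asarray(tau_v, float)
    eta_v = np.full(n, params.eta) if eta is None else np.asarray(eta, float)
    tau0_v = np.full(n, params.tau0) if tau0 is None else np.asarray(tau0, float)
    R_v = np.ones(n) if R_scale is None else np.asarray(R_scale, float)

    mu = np.exp(-params.dt / tau_v_v)
    lam = params.lam
    n_ref = params.n_ref

    V = np.zeros(n)
    Ve = np.zeros(n)
    Vi = np.zeros(n)
    tau = np.zeros(n)
    z = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)

    spikes = np.zeros((n_steps, n), dtype=np.int8)
    gammas = np.empty((n_steps, n))
    for t in range(n_steps):
        tau = lam * tau + (1.0 - lam) * z
        gamma = tau0_v + eta_v * tau
        V = mu * V + (1.0 - mu) * (params.g_exc * (Ve - params.V_exc)
                                   + params.g_inh * (Vi - params.V_inh)) - gamma * z
        Ve = mu * Ve + (1.0 - mu) * (R_v * params.R_me) * I_exc
        Vi = mu * Vi + (1.0 - mu) * (R_v * params.R_mi) * I_inh
        fire = (ref == 0) & (V > gamma)
        z = fire.astype(float)
        ref = np.where(fire, n_ref, np.maximum(ref - 1, 0))
        spikes[t] = fire
        gammas[t] = gamma
    return spikes, gammas


def fi_curve(
    mode: str,
    current_grid: Sequence[float],
    params: SAMParams,
    t_sim: float = 10_000.0,
    t_discard: float = 3_000.0,
    inh_ratio: float = 0.15,
    knee_epsilon: float = KNEE_EPSILON,
) -> SweepResult:
    """Steady-state firing rate and saturated threshold across a drive sweep.

    ``t_sim`` and ``t_discard`` are in ms; the rate is the spike count after
    the transient divided by the retained duration, and the saturated
    threshold is the time average of Gamma over the final second.
    """
    if mode not in ("excitatory_only", "inhibitory_only", "simultaneous"):
        raise ValueError(f"unknown f-I mode {mode!r}")
    if t_sim <= t_discard:
        raise ValueError(f"t_sim ({t_sim}) must exceed t_discard ({t_discard})")
    grid = np.asarray(current_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("current_grid must be a 1-D ascending sequence")

    if mode == "excitatory_only":
        I_e, I_i = grid, np.zeros_like(grid)
    elif mode == "inhibitory_only":
        # Hyperpolarizing drive delivered through the inhibitory dendrite.
        I_e, I_i = np.zeros_like(grid), -grid
    else:
        I_e, I_i = grid, -inh_ratio * grid

    n_steps = int(round(t_sim / params.dt))
    n_discard = int(round(t_discard / params.dt))
    spikes, gammas = simulate_constant_drive(I_e, I_i, params, n_steps)

    retained_s = (n_steps - n_discard) * params.dt / 1000.0
    rates = spikes[n_discard:].sum(axis=0) / retained_s
    n_last = max(int(round(1000.0 / params.dt)), 1)
    gamma_sat = gammas[-n_last:].mean(axis=0)

    result = SweepResult(drive_values=grid, rates=rates, gamma_sat=gamma_sat,
                         knee=None, mode=mode)
    result.knee = detect_knee(result, epsilon=knee_epsilon)
    return result


def detect_knee(sweep: SweepResult, epsilon: float = KNEE_EPSILON) -> Optional[float]:
    """Smallest drive whose rate is within ``epsilon`` of the plateau rate.

    A plateau exists when the trailing grid points (10% of the grid, at least
    three) all sit within ``epsilon`` of the maximum rate; otherwise the sweep
    has not saturated and ``None`` is returned.
    """
    rates = np.asarray(sweep.rates, dtype=float)
    if rates.size < 3:
        return None
    plateau = rates.max()
    if plateau <= 0:
        return None
    n_tail = max(3, rates.size // 10)
    if np.any(rates[-n_tail:] < plateau - epsilon):
        return None
    idx = int(np.argmax(rates >= plateau - epsilon))
    return float(sweep.drive_values[idx])


def param_grid(
    param_x: Tuple[str, Sequence[float]],
    param_y: Tuple[str, Sequence[float]],
    observable: str,
    base: SAMParams,
    drive: float,
    t_sim: float = 10_000.0,
    t_discard: float = 3_000.0,
) -> np.ndarray:
    """Two-parameter sensitivity grid of the saturated threshold or steady rate.

    ``param_x``/``param_y`` are ``(name, grid)`` pairs with names from
    ``{'eta', 'tau0', 'tau_v', 'R_m'}``; the constant ``drive`` is injected
    into the excitatory dendrite and the matrix entry ``[i, j]`` corresponds to
    ``(param_y[i], param_x[j])``.  The ``R_m`` axis varies the common membrane
    resistance of all three compartments, which Table-1-style parameter sets
    share.
    """
    if observable not in ("gamma_sat", "steady_rate"):
        raise ValueError(f"unknown observable {observable!r}")
    name_x, grid_x = param_x
    name_y, grid_y = param_y
    for name in (name_x, name_y):
        if name not in GRID_PARAMS:
            raise ValueError(f"unknown parameter {name!r}; expected one of {GRID_PARAMS}")
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)

    X, Y = np.meshgrid(grid_x, grid_y)
    flat = {name_x: X.ravel(), name_y: Y.ravel()}
    n = X.size

    kw = {}
    for name, key in (("tau_v", "tau_v"), ("eta", "eta"), ("tau0", "tau0"), ("R_m", "R_scale")):
        if name in flat:
            kw[key] = flat[name]

    n_steps = int(round(t_sim / base.dt))
    n_discard = int(round(t_discard / base.dt))
    spikes, gammas = simulate_constant_drive(
        np.full(n, drive), np.zeros(n), base, n_steps, **kw
    )
    if observable == "gamma_sat":
        n_last = max(int(round(1000.0 / base.dt)), 1)
        values = gammas[-n_last:].mean(axis=0)
    else:
        retained_s = (n_steps - n_discard) * base.dt / 1000.0
        values = spikes[n_discard:].sum(axis=0) / retained_s
    return values.reshape(X.shape)
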