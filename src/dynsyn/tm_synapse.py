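"""Phenomenological model of short-term synaptic plasticity.

Two representations of the same synapse are provided:

* a continuous three-state resource model (recovered ``x``, active ``y``,
  inactive ``z``; the total ``x + y + z`` is conserved) with a release
  probability ``u`` that facilitates on each presynaptic spike, integrated
  event-wise with exact exponential relaxation between spikes; and
* a one-step discrete map in ``(x, u)`` suitable as the synaptic update of
  a binary network evolving in Monte Carlo steps (MCS), where released
  resources act instantaneously.

Time units are milliseconds for the continuous model and MCS for the
discrete map (1 MCS corresponds to roughly 5 ms, the duration of a
refractory period).

Note on the facilitation equation: ``u`` relaxes *toward* its baseline
``U`` between spikes and jumps by ``U * (1 - u)`` on each spike, so
``u`` lives in ``[U, 1]``.  (Accompanying prose descriptions sometimes say
``u`` "increases toward U"; the dynamics implemented here follow the
equation, not the prose.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TMParams",
    "TMSynapseState",
    "SpikeTrain",
    "integrate_ode",
    "step_discrete",
    "steady_state",
    "postsynaptic_current",
]

logger = logging.getLogger(__name__)

#: synapse operating modes
MODES = ("full", "depression_only", "static")


@dataclass(frozen=True)
class TMParams:
    """Parameters of the dynamic synapse.

    Parameters
    ----------
    U : float
        Baseline release probability, ``0 < U <= 1``.
    tau_rec : float
        Recovery time constant of depleted resources (ms for the ODE,
        MCS for the discrete map).
    tau_fac : float
        Facilitation time constant (same units).  ``0`` disables
        facilitation (``u`` clamped at ``U``).
    tau_in : float
        Inactivation time constant of released neurotransmitter (ms,
        continuous model only).
    A : float
        Maximal synaptic efficacy in pA (cortical scale ~40 pA).
    mode : str
        ``"full"`` -- depression and facilitation active;
        ``"depression_only"`` -- ``u`` clamped at 1 (pure depression);
        ``"static"`` -- ``x`` clamped at 1 and ``u`` at ``U`` (no
        short-term plasticity).  Explicit clamps are used instead of
        limiting parameter values to avoid division by small time
        constants.
    """

    U: float = 0.5
    tau_rec: float = 100.0
    tau_fac: float = 0.0
    tau_in: float = 3.0
    A: float = 40.0
    mode: str = "full"

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        for name in ("tau_rec", "tau_fac", "tau_in"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not math.isfinite(self.A):
            raise ValueError("A must be finite")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class TMSynapseState:
    """Instantaneous synapse state.

    ``x`` (recovered), ``y`` (active) and ``z`` (inactive) are resource
    fractions summing to one in the continuous representation; the
    discrete map carries only ``x`` and ``u`` (``y`` and ``z`` are then 0).
    ``u`` is the instantaneous release probability.
    """

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    u: float = 0.5

    def validate(self, params: TMParams | None = None, atol: float = 1e-9) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not (-atol <= v <= 1.0 + atol):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.x + self.y + self.z - 1.0) > 1e-6 and (self.y or self.z):
            raise ValueError("x + y + z must equal 1 in the continuous model")
        if params is not None and params.mode == "full":
            if not (params.U - atol <= self.u <= 1.0 + atol):
                raise ValueError(f"u={self.u} outside [U, 1]")


class SpikeTrain:
    """An ordered sequence of presynaptic spike times (ms).

    For the discrete map use a plain binary sequence instead.
    """

    __slots__ = ("times",)

    def __init__(self, times: Iterable[float]):
        t = np.asarray(list(times), dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if t.size > 1 and np.any(np.diff(t) <= 0.0):
            raise ValueError("spike times must be strictly increasing")
        self.times = t

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self):
        return iter(self.times)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpikeTrain(n={len(self)})"


def _relax(state: TMSynapseState, params: TMParams, dt: float) -> TMSynapseState:
    """Exact linear relaxation over an inter-spike interval of length dt.

    Between spikes the system is linear:  y decays with tau_in, z receives
    y/tau_in and decays with tau_rec, x absorbs the balance (conservation),
    u relaxes toward U with tau_fac.
    """
    if dt <= 0.0:
        return replace(state)
    a = 1.0 / params.tau_in
    b = 1.0 / params.tau_rec if params.tau_rec > 0 else math.inf
    y0, z0, u0 = state.y, state.z, state.u

    y = y0 * math.exp(-a * dt)
    if not math.isfinite(b):  # tau_rec == 0: instantaneous recovery
        z = 0.0
    elif abs(a - b) > 1e-12 * max(a, b):
        k = a * y0 / (b - a)
        z = (z0 - k) * math.exp(-b * dt) + k * math.exp(-a * dt)
    else:  # degenerate tau_in == tau_rec
        z = (z0 + a * y0 * dt) * math.exp(-a * dt)
    x = 1.0 - y - z

    if params.mode == "static":
        return TMSynapseState(x=1.0, y=y, z=z, u=params.U)
    if params.mode == "depression_only":
        u = 1.0
    elif params.tau_fac > 0.0:
        u = params.U + (u0 - params.U) * math.exp(-dt / params.tau_fac)
    else:
        u = params.U
    return TMSynapseState(x=x, y=y, z=z, u=u)


def _spike_jump(state: TMSynapseState, params: TMParams) -> TMSynapseState:
    """Atomic spike update: release u*x into the active pool, facilitate u."""
    u = state.u
    if params.mode == "depression_only":
        u = 1.0
    elif params.mode == "static":
        u = params.U
    rel = u * state.x
    x = state.x - rel
    y = state.y + rel
    z = state.z
    if params.mode == "static":
        # no depression: the recovered pool is clamped at 1, so resource
        # conservation does not apply in this mode
        x = 1.0
        u_new = params.U
    elif params.mode == "depression_only":
        u_new = 1.0
    else:
        u_new = u + params.U * (1.0 - u)
    return TMSynapseState(x=x, y=y, z=z, u=u_new)


def integrate_ode(
    state: TMSynapseState,
    params: TMParams,
    spikes: SpikeTrain,
    t_end: float,
    dt: float,
) -> np.ndarray:
    """Integrate the continuous synapse model.

    Spike-triggered jumps are applied exactly at spike times (event
    driven), interleaved with exact exponential relaxation, so there is
    no delta-function discretization error; the dt grid only controls
    output sampling.

    Parameters
    ----------
    state : TMSynapseState
        Initial condition (must satisfy the invariants).
    params : TMParams
    spikes : SpikeTrain
        Presynaptic spike times in (0, t_end].
    t_end, dt : float
        Duration and output sampling step in ms.

    Returns
    -------
    numpy.ndarray
        Structured-free float array of shape (n_steps + 1, 5) with columns
        ``(t, x, y, z, u)``; row 0 is the initial condition at t=0.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if params.tau_in > 0 and dt >= params.tau_in:
        raise ValueError(
            f"dt={dt} must be smaller than tau_in={params.tau_in} to resolve "
            "the active-fraction transient"
        )
    state.validate(params)

    spike_times = spikes.times[(spikes.times > 0) & (spikes.times <= t_end)]
    n_steps = int(round(t_end / dt))
    out = np.empty((n_steps + 1, 5), dtype=float)
    out[0] = (0.0, state.x, state.y, state.z, state.u)

    s = replace(state)
    t = 0.0
    k = 0  # next spike index
    for i in range(1, n_steps + 1):
        t_next = i * dt
        while k < spike_times.size and spike_times[k] <= t_next:
            ts = spike_times[k]
            s = _relax(s, params, ts - t)
            s = _spike_jump(s, params)
            t = ts
            k += 1
        s = _relax(s, params, t_next - t)
        t = t_next
        out[i] = (t, s.x, s.y, s.z, s.u)
    return out


def step_discrete(
    state: TMSynapseState, params: TMParams, fired: int
) -> TMSynapseState:
    """One Monte Carlo step of the discrete (x, u) map.

    ``x' = x + (1 - x)/tau_rec - u * x * s`` and
    ``u' = u + (U - u)/tau_fac + U * (1 - u) * s``, with the release term
    using the *current* ``u``.  Requires ``tau_rec, tau_fac >= 1`` step
    (or a clamping mode).  Clipping to the legal ranges is applied only as
    a floating-point guard and is logged if it actually triggers.
    """
    if fired not in (0, 1):
        raise ValueError(f"fired must be 0 or 1, got {fired!r}")
    x, u = step_discrete_arrays(
        np.asarray([state.x]), np.asarray([state.u]),
        np.asarray([fired], dtype=float), params,
    )
    return TMSynapseState(x=float(x[0]), y=0.0, z=0.0, u=float(u[0]))


def step_discrete_arrays(
    x: np.ndarray, u: np.ndarray, s: np.ndarray, params: TMParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized discrete map update over arrays of synapses."""
    if params.mode == "static":
        return np.ones_like(x), np.full_like(u, params.U)
    if params.mode == "full":
        if params.tau_rec < 1.0 or params.tau_fac < 1.0:
            raise ValueError(
                "discrete map requires tau_rec, tau_fac >= 1 MCS "
                "(use mode='static' or 'depression_only' for limits)"
            )
        u_new = u + (params.U - u) / params.tau_fac + params.U * (1.0 - u) * s
    else:  # depression_only
        if params.tau_rec < 1.0:
            raise ValueError("discrete map requires tau_rec >= 1 MCS")
        u = np.ones_like(u)
        u_new = u
    x_new = x + (1.0 - x) / params.tau_rec - u * x * s

    lo_u = 1.0 if params.mode == "depression_only" else params.U
    clipped = (x_new < 0) | (x_new > 1) | (u_new < lo_u) | (u_new > 1)
    if np.any(clipped):
        logger.warning(
            "discrete map clipped %d value(s) to legal range (float guard)",
            int(np.count_nonzero(clipped)),
        )
        x_new = np.clip(x_new, 0.0, 1.0)
        u_new = np.clip(u_new, lo_u, 1.0)
    return x_new, u_new


def steady_state(params: TMParams, f_n: float) -> tuple[float, float]:
    """Asymptotic release probability and recovered fraction under Poisson
    drive at rate ``f_n``.

    ``u_inf = U (1 + tau_fac f_n) / (1 + U tau_fac f_n)`` and
    ``x_inf = 1 / (1 + u_inf tau_rec f_n)``.  Rate units are the inverse
    of the time-constant units (kHz when time constants are in ms).
    """
    if f_n < 0.0:
        raise ValueError("rate f_n must be >= 0")
    if params.mode == "static":
        return params.U, 1.0
    if params.mode == "depression_only":
        u_inf = 1.0
    else:
        u_inf = (
            params.U * (1.0 + params.tau_fac * f_n)
            / (1.0 + params.U * params.tau_fac * f_n)
        )
    x_inf = 1.0 / (1.0 + u_inf * params.tau_rec * f_n)
    return u_inf, x_inf


def postsynaptic_current(A: float, y_values: Sequence[float]) -> float:
    """Total postsynaptic current ``sum_j A * y_j`` in pA."""
    y = np.asarray(y_values, dtype=float)
    if y.size and (y.min() < 0.0 or y.max() > 1.0):
        raise ValueError("active fractions must lie in [0, 1]")
    return float(A * y.sum())
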