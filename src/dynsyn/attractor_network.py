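"""Stochastic binary attractor network with per-neuron dynamic synapses.

The network stores binary activity patterns in static Hebbian (covariance)
weights; transmission is modulated multiplicatively by one depression
variable ``x_j`` and one facilitation variable ``u_j`` *per neuron*, so the
effective weight is ``w_ij(t) = w_bar_ij * x_j(t) * u_j(t)``.  Neurons are
updated synchronously (Little dynamics) with a thermal acceptance rule at
temperature ``T``.  Time is measured in Monte Carlo steps (MCS, ~5 ms).

With static synapses the model is the classical associative-memory
network: stored patterns are stable attractors at low ``T``.  Depression
destabilizes them, producing quasi-periodic switching between a pattern
and its anti-pattern ("dynamic memories").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dynsyn.tm_synapse import TMParams, step_discrete_arrays

__all__ = [
    "PatternSet",
    "NetworkConfig",
    "NetworkState",
    "OverlapTrace",
    "SimulationResult",
    "generate_patterns",
    "hebbian_weights",
    "local_fields",
    "thresholds",
    "update_neurons",
    "overlap",
    "run_simulation",
    "permanence_times",
]

THETA_MODES = ("zero", "half_row_sum", "custom")


@dataclass
class PatternSet:
    """P stored binary patterns of N neurons with mean activity ``a``."""

    xi: np.ndarray  # (P, N) entries in {0, 1}
    a: float

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi)
        if self.xi.ndim != 2:
            raise ValueError("xi must be a P x N matrix")
        if not np.isin(self.xi, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        if not (0.0 < self.a < 1.0):
            raise ValueError("a must be in (0, 1)")

    @property
    def P(self) -> int:
        return self.xi.shape[0]

    @property
    def N(self) -> int:
        return self.xi.shape[1]


@dataclass
class NetworkConfig:
    """Simulation configuration for the binary network."""

    N: int = 120
    T: float = 0.025
    steps: int = 10_000
    synapse: TMParams = field(default_factory=lambda: TMParams(
        U=1.0, tau_rec=26.0, tau_fac=1.0, mode="depression_only"))
    theta_mode: str = "zero"
    theta_custom: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.theta_mode not in THETA_MODES:
            raise ValueError(f"theta_mode must be one of {THETA_MODES}")


@dataclass
class NetworkState:
    """Microscopic network state: activities, synaptic variables, weights."""

    s: np.ndarray       # (N,) binary
    x: np.ndarray       # (N,) recovered fraction per neuron
    u: np.ndarray       # (N,) release probability per neuron
    w_bar: np.ndarray   # (N, N) static weights, symmetric, zero diagonal


@dataclass
class OverlapTrace:
    """Per-step order parameters of a simulation.

    ``m`` has shape (steps + 1, P); the sublattice means ``x_plus`` /
    ``x_minus`` (and likewise for ``u``) average the synaptic variables
    over neurons active / quiescent in each pattern.
    """

    t: np.ndarray
    m: np.ndarray
    x_plus: np.ndarray
    x_minus: np.ndarray
    u_plus: np.ndarray
    u_minus: np.ndarray


@dataclass
class SimulationResult:
    raster: np.ndarray       # (n_events, 2) columns (t, neuron_id)
    trace: OverlapTrace
    config: NetworkConfig


def generate_patterns(
    N: int, P: int, a: float, balanced: bool = True, seed: int | None = 0
) -> PatternSet:
    """Draw P random binary patterns with mean activity ``a``.

    In balanced mode every pattern has exactly ``round(a*N)`` active
    neurons, which makes the self-overlap exactly 1; unbalanced mode
    draws i.i.d. Bernoulli(a) entries.
    """
    if not (0.0 < a < 1.0):
        raise ValueError("a must be in (0, 1)")
    if P < 1:
        raise ValueError("P must be >= 1")
    rng = np.random.default_rng(seed)
    if balanced:
        n_on = int(round(a * N))
        if n_on < 1:
            raise ValueError("a * N < 1: balanced patterns would be empty")
        xi = np.zeros((P, N), dtype=np.int8)
        for mu in range(P):
            xi[mu, rng.choice(N, size=n_on, replace=False)] = 1
    else:
        xi = (rng.random((P, N)) < a).astype(np.int8)
    return PatternSet(xi=xi, a=a)


def hebbian_weights(patterns: PatternSet) -> np.ndarray:
    """Covariance-rule weights ``w_bar_ij = sum_mu (xi_i - a)(xi_j - a) /
    (N a (1-a))`` with zero diagonal."""
    xi = patterns.xi.astype(float)
    a = patterns.a
    N = patterns.N
    d = xi - a
    w = d.T @ d / (N * a * (1.0 - a))
    np.fill_diagonal(w, 0.0)
    return w


def local_fields(state: NetworkState) -> np.ndarray:
    """Synaptic fields ``h_i = sum_j w_bar_ij x_j u_j s_j``."""
    return state.w_bar @ (state.x * state.u * state.s)


def thresholds(
    w_bar: np.ndarray, mode: str = "zero", custom: np.ndarray | None = None
) -> np.ndarray:
    """Firing thresholds: all-zero, half row sums of the static weights,
    or a user-supplied vector."""
    N = w_bar.shape[0]
    if mode == "zero":
        return np.zeros(N)
    if mode == "half_row_sum":
        return 0.5 * w_bar.sum(axis=1)
    if mode == "custom":
        if custom is None:
            raise ValueError("theta_mode='custom' requires a threshold vector")
        theta = np.asarray(custom, dtype=float)
        if theta.shape != (N,):
            raise ValueError("custom thresholds must have shape (N,)")
        return theta
    raise ValueError(f"unknown theta mode {mode!r}")


def update_neurons(
    h: np.ndarray, theta: np.ndarray, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Parallel stochastic update: fire with probability
    ``1/2 [1 + tanh(2 (h - theta)/T)]``; at T=0 this is the deterministic
    sign rule with fair-coin tie breaking."""
    d = h - theta
    if T > 0:
        p = 0.5 * (1.0 + np.tanh(2.0 * d / T))
    else:
        p = np.where(d > 0, 1.0, np.where(d < 0, 0.0, 0.5))
    return (rng.random(d.shape) < p).astype(np.int8)


def overlap(s: np.ndarray, pattern: np.ndarray, a: float) -> float:
    """Normalized pattern overlap ``m = sum_i (xi_i - a) s_i / (N a (1-a))``."""
    s = np.asarray(s, dtype=float)
    pattern = np.asarray(pattern, dtype=float)
    if s.shape != pattern.shape:
        raise ValueError("state and pattern lengths differ")
    N = s.size
    return float((pattern - a) @ s / (N * a * (1.0 - a)))


def _sublattice_means(
    values: np.ndarray, xi: np.ndarray, a: float
) -> tuple[np.ndarray, np.ndarray]:
    """Averages of per-neuron values over active/quiescent sites of each
    pattern (rows of xi)."""
    N = values.size
    act = xi.astype(bool)
    plus = (act @ values) / (N * a)
    minus = ((~act) @ values) / (N * (1.0 - a))
    return plus, minus


def run_simulation(
    config: NetworkConfig,
    patterns: PatternSet,
    init: int | str = 0,
) -> SimulationResult:
    """Monte Carlo simulation of the network.

    Per-step update order: fields from the current (s, x, u) -> all
    neurons drawn in parallel -> synaptic variables advanced one MCS
    using the *pre-update* activity s(t).

    ``init`` is a stored-pattern index, ``"random"`` for an i.i.d.
    Bernoulli(a) initial state, or an explicit binary N-vector.
    """
    rng = np.random.default_rng(config.seed)
    N, P, a = config.N, patterns.P, patterns.a
    if patterns.N != N:
        raise ValueError("pattern size does not match config.N")

    w_bar = hebbian_weights(patterns)
    theta = thresholds(w_bar, config.theta_mode, config.theta_custom)

    if isinstance(init, np.ndarray):
        if init.shape != (N,):
            raise ValueError("explicit init state must have shape (N,)")
        s = init.astype(np.int8).copy()
    elif init == "random":
        s = (rng.random(N) < a).astype(np.int8)
    else:
        mu = int(init)
        if not (0 <= mu < P):
            raise IndexError(f"init pattern index {mu} out of range [0, {P})")
        s = patterns.xi[mu].astype(np.int8).copy()

    p = config.synapse
    x = np.ones(N)
    u = np.full(N, 1.0 if p.mode == "depression_only" else p.U)

    steps = config.steps
    m = np.empty((steps + 1, P))
    xp = np.empty((steps + 1, P)); xm = np.empty((steps + 1, P))
    up = np.empty((steps + 1, P)); um = np.empty((steps + 1, P))
    events: list[np.ndarray] = []

    norm = (patterns.xi - a) / (N * a * (1.0 - a))  # (P, N)

    def record(t: int) -> None:
        m[t] = norm @ s
        xp[t], xm[t] = _sublattice_means(x, patterns.xi, a)
        up[t], um[t] = _sublattice_means(u, patterns.xi, a)
        idx = np.nonzero(s)[0]
        events.append(np.column_stack([np.full(idx.size, t), idx]))

    record(0)
    for t in range(1, steps + 1):
        h = w_bar @ (x * u * s)
        s_new = update_neurons(h, theta, config.T, rng)
        x, u = step_discrete_arrays(x, u, s.astype(float), p)
        s = s_new
        record(t)

    trace = OverlapTrace(
        t=np.arange(steps + 1), m=m, x_plus=xp, x_minus=xm, u_plus=up, u_minus=um
    )
    raster = (np.concatenate(events, axis=0) if events
              else np.empty((0, 2), dtype=int))
    return SimulationResult(raster=raster, trace=trace, config=config)


def permanence_times(
    m: np.ndarray | OverlapTrace,
    threshold: float = 0.8,
    min_dwell: int = 1,
    pattern: int = 0,
) -> dict[str, list[int]]:
    """Dwell durations near the pattern (m > threshold) and anti-pattern
    (m < -threshold).

    Runs shorter than ``min_dwell`` are merged into their preceding run
    (or following run at the trace start).  Returns lists of run lengths
    keyed by ``"pattern"`` and ``"anti_pattern"``.
    """
    if isinstance(m, OverlapTrace):
        m = m.m[:, pattern]
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        raise ValueError("empty overlap trace")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")

    labels = np.zeros(m.size, dtype=int)
    labels[m > threshold] = 1
    labels[m < -threshold] = -1

    # run-length encode
    change = np.nonzero(np.diff(labels))[0] + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [labels.size]]))
    runs = [[int(v), int(ln)] for v, ln in zip(labels[starts], lengths)]

    # merge runs shorter than min_dwell into their left neighbor (right
    # neighbor at the trace start), then re-fuse equal adjacent labels
    while True:
        short = next(
            (i for i, (_, ln) in enumerate(runs) if ln < min_dwell and len(runs) > 1),
            None,
        )
        if short is None:
            break
        if short > 0:
            runs[short - 1][1] += runs[short][1]
        else:
            runs[1][1] += runs[0][1]
        del runs[short]
        fused = [runs[0]]
        for v, ln in runs[1:]:
            if v == fused[-1][0]:
                fused[-1][1] += ln
            else:
                fused.append([v, ln])
        runs = fused

    out: dict[str, list[int]] = {"pattern": [], "anti_pattern": []}
    for v, ln in runs:
        if v == 1:
            out["pattern"].append(ln)
        elif v == -1:
            out["anti_pattern"].append(ln)
    return out
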