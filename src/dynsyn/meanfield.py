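"""Mean-field theory of the binary attractor network with dynamic synapses.

Two levels of description are implemented:

* the vanishing-load (``alpha -> 0``) order-parameter map for a single
  condensed pattern: six sublattice averages ``(m+, m-, x+, x-, u+, u-)``
  evolve under a deterministic discrete map obtained by averaging the
  microscopic dynamics over the sites active/quiescent in the pattern and
  factorizing ``<x u s> = <x><u><s>`` per sublattice.  Fixed points,
  their local stability and the resulting memory / oscillatory /
  no-memory phase diagram are computed from this map; and
* the zero-noise (``T = 0``) storage-capacity equation at finite load
  ``alpha = P/N``: depression and facilitation enter only through
  ``gamma = U * tau_rec`` and ``gamma' = (1 + tau_fac)/(1 + U tau_fac)``,
  combined in ``Delta = gamma + 1/gamma' - 1``.  The largest ``alpha``
  admitting a solution with nonzero condensed overlap is the maximum
  storage capacity ``alpha_c`` (``~0.138`` in the static limit
  ``Delta = 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy import optimize
from scipy.special import erf

from dynsyn.tm_synapse import TMParams

__all__ = [
    "OrderParams",
    "PhaseDiagram",
    "mf_map_step",
    "iterate_map",
    "find_fixed_points",
    "stability",
    "classify_phase",
    "phase_diagram",
    "capacity_gamma",
    "capacity_gamma_prime",
    "capacity_alpha_c",
    "capacity_alpha_c_fixed_point",
]

PHASES = ("memory", "oscillatory", "no-memory")


@dataclass
class OrderParams:
    """Sublattice order parameters for a single condensed pattern."""

    m_plus: float
    m_minus: float
    x_plus: float = 1.0
    x_minus: float = 1.0
    u_plus: float = 1.0
    u_minus: float = 1.0

    def to_array(self) -> np.ndarray:
        return np.array([self.m_plus, self.m_minus, self.x_plus,
                         self.x_minus, self.u_plus, self.u_minus])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "OrderParams":
        return cls(*map(float, v))

    @property
    def m(self) -> float:
        """Condensed overlap (exact for a = 1/2)."""
        return self.m_plus - self.m_minus


@dataclass
class PhaseDiagram:
    """Grid of phase labels over two swept parameters."""

    axes: tuple[str, str]
    values: tuple[np.ndarray, np.ndarray]
    labels: np.ndarray  # (n1, n2) array of strings from PHASES


def _clamped_xu(v: np.ndarray, params: TMParams) -> np.ndarray:
    if params.mode == "static":
        v[2:4] = 1.0
        v[4:6] = params.U
    elif params.mode == "depression_only":
        v[4:6] = 1.0
    return v


def mf_map_step(
    v: OrderParams | np.ndarray,
    params: TMParams,
    T: float,
    a: float = 0.5,
    theta: float = 0.0,
) -> np.ndarray:
    """One step of the six-dimensional order-parameter map.

    Fields on the two sublattices are ``h+ = (1-a) M`` and ``h- = -a M``
    with ``M = x+ u+ m+ - x- u- m-``; firing fractions follow the thermal
    rule and the synaptic averages follow the discrete synapse map with
    the firing indicator replaced by the sublattice firing fraction.
    """
    if isinstance(v, OrderParams):
        v = v.to_array()
    mp, mm, xp, xm, up, um = v
    M = xp * up * mp - xm * um * mm
    hp = (1.0 - a) * M
    hm = -a * M

    def fire(h: float) -> float:
        d = h - theta
        if T > 0:
            return 0.5 * (1.0 + np.tanh(2.0 * d / T))
        return 1.0 if d > 0 else (0.0 if d < 0 else 0.5)

    mp_n, mm_n = fire(hp), fire(hm)

    if params.mode == "static":
        xp_n = xm_n = 1.0
        up_n = um_n = params.U
    else:
        xp_n = xp + (1.0 - xp) / params.tau_rec - up * xp * mp
        xm_n = xm + (1.0 - xm) / params.tau_rec - um * xm * mm
        if params.mode == "depression_only":
            up_n = um_n = 1.0
        else:
            up_n = up + (params.U - up) / params.tau_fac + params.U * (1.0 - up) * mp
            um_n = um + (params.U - um) / params.tau_fac + params.U * (1.0 - um) * mm
    return np.array([mp_n, mm_n, xp_n, xm_n, up_n, um_n])


def iterate_map(
    v0: OrderParams | np.ndarray,
    params: TMParams,
    T: float,
    steps: int,
    a: float = 0.5,
    theta: float = 0.0,
) -> np.ndarray:
    """Iterate the map, returning the full (steps + 1, 6) trajectory."""
    v = v0.to_array() if isinstance(v0, OrderParams) else np.asarray(v0, float).copy()
    out = np.empty((steps + 1, 6))
    out[0] = v
    for t in range(1, steps + 1):
        v = mf_map_step(v, params, T, a, theta)
        out[t] = v
    return out


def _stationary_xu(m: float, params: TMParams) -> tuple[float, float]:
    """Fixed point of the synaptic map at constant firing fraction m."""
    if params.mode == "static":
        return 1.0, params.U
    if params.mode == "depression_only":
        u = 1.0
    else:
        u = (params.U * (1.0 + params.tau_fac * m)
             / (1.0 + params.U * params.tau_fac * m))
    x = 1.0 / (1.0 + u * params.tau_rec * m)
    return x, u


def _default_starts(params: TMParams) -> list[np.ndarray]:
    starts = []
    for mp, mm in ((1.0, 0.0), (0.0, 1.0), (0.5, 0.5), (0.9, 0.1), (0.1, 0.9)):
        xp, up = _stationary_xu(mp, params)
        xm, um = _stationary_xu(mm, params)
        starts.append(np.array([mp, mm, xp, xm, up, um]))
    return starts


def find_fixed_points(
    params: TMParams,
    T: float,
    a: float = 0.5,
    theta: float = 0.0,
    n_starts: int | None = None,
    tol: float = 1e-10,
    starts: list[np.ndarray] | None = None,
) -> list[OrderParams]:
    """Locate fixed points of the map from deterministic initial guesses.

    Damped iteration captures stable points; a Newton solve from each
    start also captures unstable ones (e.g. the symmetric point between
    two retrieval states).  Results are deduplicated within ``10 * tol``
    and verified to satisfy ``||F(v) - v||_inf < tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if starts is None:
        starts = _default_starts(params)
    if n_starts is not None:
        starts = starts[:n_starts]

    def residual(v: np.ndarray) -> np.ndarray:
        return mf_map_step(v, params, T, a, theta) - v

    found: list[np.ndarray] = []

    def add(v: np.ndarray) -> None:
        if np.max(np.abs(residual(v))) >= tol:
            return
        for w in found:
            if np.max(np.abs(v - w)) < 10 * tol:
                return
        found.append(v)

    for v0 in starts:
        # damped fixed-point iteration (converges to stable points)
        v = v0.copy()
        for _ in range(5000):
            v_next = 0.5 * v + 0.5 * mf_map_step(v, params, T, a, theta)
            if np.max(np.abs(v_next - v)) < 0.1 * tol:
                v = v_next
                break
            v = v_next
        add(v)
        if T > 0:  # Newton needs a smooth map
            for guess in (v0, v):
                sol = optimize.root(residual, guess, method="hybr",
                                    options={"xtol": 1e-13})
                if sol.success:
                    add(sol.x)

    if not found:
        warnings.warn("no fixed point converged from any start", RuntimeWarning)
    return [OrderParams.from_array(v) for v in found]


def stability(
    v: OrderParams | np.ndarray,
    params: TMParams,
    T: float,
    a: float = 0.5,
    theta: float = 0.0,
    fp_tol: float = 1e-6,
) -> tuple[bool, float]:
    """Linear stability of a fixed point: spectral radius of the
    central-difference Jacobian of the map; stable iff < 1."""
    v = v.to_array() if isinstance(v, OrderParams) else np.asarray(v, float)
    if np.max(np.abs(mf_map_step(v, params, T, a, theta) - v)) > fp_tol:
        raise ValueError("v is not a fixed point within tolerance")
    h = 1e-6
    J = np.empty((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        J[:, j] = (mf_map_step(v + e, params, T, a, theta)
                   - mf_map_step(v - e, params, T, a, theta)) / (2 * h)
    rho = float(np.max(np.abs(np.linalg.eigvals(J))))
    return rho < 1.0, rho


def classify_phase(
    params: TMParams,
    T: float,
    a: float = 0.5,
    theta: float = 0.0,
    m_memory: float = 0.5,
    osc_amplitude: float = 0.1,
    transient: int = 2000,
    window: int = 2000,
) -> str:
    """Classify parameters as memory / oscillatory / no-memory.

    Memory: a stable fixed point with ``|m| > m_memory`` exists.
    Otherwise oscillatory if the long-run map iteration started near the
    pattern has peak-to-peak overlap amplitude above ``osc_amplitude``;
    else no-memory.
    """
    for fp in find_fixed_points(params, T, a, theta, tol=1e-9):
        if abs(fp.m) > m_memory:
            try:
                is_stable, _ = stability(fp, params, T, a, theta, fp_tol=1e-6)
            except ValueError:
                continue
            if is_stable:
                return "memory"
    mp0 = 0.95
    xp, up = _stationary_xu(mp0, params)
    xm, um = _stationary_xu(0.05, params)
    v0 = np.array([mp0, 0.05, xp, xm, up, um])
    traj = iterate_map(v0, params, T, transient + window, a, theta)
    m_tail = traj[transient:, 0] - traj[transient:, 1]
    if np.ptp(m_tail) > osc_amplitude:
        return "oscillatory"
    # a stable large-|m| state may be reached only asymptotically
    if abs(m_tail[-1]) > m_memory:
        return "memory"
    return "no-memory"


def phase_diagram(
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    params: TMParams,
    T: float | None = None,
    a: float = 0.5,
    theta: float = 0.0,
    **kwargs,
) -> PhaseDiagram:
    """Phase label on a rectangular grid.

    Each axis is ``(name, values)`` with name in ``{"T", "tau_rec",
    "tau_fac", "U"}``; remaining parameters come from ``params`` / ``T``.
    """
    from dataclasses import replace as dc_replace

    names = (axis1[0], axis2[0])
    vals = (np.asarray(axis1[1], float), np.asarray(axis2[1], float))
    for n in names:
        if n not in ("T", "tau_rec", "tau_fac", "U"):
            raise ValueError(f"cannot sweep parameter {n!r}")
    labels = np.empty((vals[0].size, vals[1].size), dtype=object)
    for i, v1 in enumerate(vals[0]):
        for j, v2 in enumerate(vals[1]):
            p, t = params, T
            for name, val in zip(names, (v1, v2)):
                if name == "T":
                    t = float(val)
                else:
                    p = dc_replace(p, **{name: float(val)})
            if t is None:
                raise ValueError("temperature T must be given or swept")
            labels[i, j] = classify_phase(p, t, a, theta, **kwargs)
    return PhaseDiagram(axes=names, values=vals, labels=labels)


# ---------------------------------------------------------------------------
# T = 0 storage capacity
# ---------------------------------------------------------------------------

def capacity_gamma(U: float, tau_rec: float) -> float:
    """Depression parameter ``gamma = U * tau_rec``."""
    return U * tau_rec


def capacity_gamma_prime(U: float, tau_fac: float) -> float:
    """Facilitation parameter ``gamma' = (1 + tau_fac)/(1 + U tau_fac)``."""
    return (1.0 + tau_fac) / (1.0 + U * tau_fac)


def _delta(U: float, tau_rec: float, tau_fac: float) -> float:
    g = capacity_gamma(U, tau_rec)
    gp = capacity_gamma_prime(U, tau_fac)
    return (1.0 + g * gp - gp) / gp


def _self_interaction(y: np.ndarray) -> np.ndarray:
    """C(y) = (2/sqrt(pi)) y exp(-y^2)/erf(y), the zero-noise limit of the
    susceptibility term beta gamma_eff (1 - q)."""
    return (2.0 / np.sqrt(np.pi)) * y * np.exp(-y * y) / erf(y)


def _capacity_excess(alpha: float, Delta: float, y: np.ndarray) -> np.ndarray:
    """Excess of the squared rescaled noise budget over its requirement.

    A retrieval solution at load ``alpha`` exists iff this is >= 0 for
    some y > 0:  erf(y)^2/(2 y^2 alpha) - Delta^2 - 1/(1 - C(y))^2.
    """
    C = _self_interaction(y)
    G = erf(y) ** 2 / (2.0 * y * y * alpha) - Delta * Delta - 1.0 / (1.0 - C) ** 2
    G[C >= 1.0] = -np.inf
    return G


_Y_GRID = np.linspace(1e-4, 6.0, 8001)


def _has_retrieval_solution(alpha: float, Delta: float) -> bool:
    G = _capacity_excess(alpha, Delta, _Y_GRID)
    i = int(np.argmax(G))
    if G[i] > 0:
        return True
    # refine the maximum locally in case the grid straddles a tangency
    lo = _Y_GRID[max(i - 1, 0)]
    hi = _Y_GRID[min(i + 1, _Y_GRID.size - 1)]
    res = optimize.minimize_scalar(
        lambda y: -_capacity_excess(alpha, Delta, np.array([y]))[0],
        bounds=(lo, hi), method="bounded",
    )
    return -res.fun > 0


def capacity_alpha_c(
    U: float, tau_rec: float, tau_fac: float, resolution: float = 1e-4
) -> float:
    """Maximum storage capacity at T = 0 and a = 1/2.

    Located by bisection on ``alpha`` of the existence of a positive
    condensed-overlap solution of the zero-noise mean-field system; the
    synapse parameters enter only through ``Delta(gamma, gamma')``.
    Returns 0 if no load supports retrieval.  Static limit: ~0.138.
    """
    if min(U, tau_rec, tau_fac) < 0:
        raise ValueError("parameters must be >= 0")
    Delta = _delta(U, tau_rec, tau_fac)
    lo = 1e-6
    if not _has_retrieval_solution(lo, Delta):
        return 0.0
    hi = 0.2
    while _has_retrieval_solution(hi, Delta):  # pragma: no cover - alpha_c <= 0.139
        hi *= 2.0
    while hi - lo > resolution / 4.0:
        mid = 0.5 * (lo + hi)
        if _has_retrieval_solution(mid, Delta):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def capacity_alpha_c_fixed_point(
    U: float, tau_rec: float, tau_fac: float, resolution: float = 1e-4
) -> float:
    """Independent route to ``alpha_c``: damped fixed-point iteration of
    the coupled (M, r) zero-noise equations, bisecting on the survival of
    a nonzero condensed overlap."""
    Delta = _delta(U, tau_rec, tau_fac)

    def converged_overlap(alpha: float) -> float:
        M, r = 1.0, 1.0
        for _ in range(4000):
            sigma = np.sqrt(alpha * (r + Delta * Delta))
            y = M / (np.sqrt(2.0) * sigma)
            if y < 1e-9:
                return 0.0
            M_new = float(erf(y))
            C = float(_self_interaction(np.array([y]))[0])
            if C >= 1.0:
                return 0.0
            r_new = 1.0 / (1.0 - C) ** 2
            M_next = 0.5 * M + 0.5 * M_new
            r_next = 0.5 * r + 0.5 * r_new
            if abs(M_next - M) < 1e-12 and abs(r_next - r) < 1e-9:
                M, r = M_next, r_next
                break
            M, r = M_next, r_next
        return M

    lo, hi = 1e-6, 0.2
    if converged_overlap(lo) <= 1e-3:
        return 0.0
    while hi - lo > resolution / 4.0:
        mid = 0.5 * (lo + hi)
        if converged_overlap(mid) > 1e-3:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
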