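"""Stochastic bistable rate model of cortical up-down transitions.

A population rate ``nu(t)`` relaxes toward a sigmoidal transfer of its own
recurrent input ``J nu x - theta``, where the synaptic resource ``x(t)``
depresses with activity and recovers on the slow timescale ``tau_r``;
both equations carry additive white noise (amplitudes ``sigma_nu`` and
``D/tau_r``).  Depending on ``(D, tau_r)`` the model produces no
transitions (phase P), exponentially distributed permanence times (E),
power-law distributed ones -- a signature of criticality -- (C), or a
regime where the rate is slaved to the synaptic fluctuations (S).

Units: time is measured in ``tau_nu``; ``tau_r`` is a multiple of
``tau_nu``.  The sigmoid argument is computed as ``J * x * nu/nu_scale -
theta`` in volts, with ``nu_scale`` defaulting to ``nu_m`` -- i.e. the
printed coupling ``J`` (order 1 V) acts on the rate normalized by its
ceiling.  The noise amplitude ``sigma_nu`` is a calibration parameter (it
drives the switching when ``D = 0``) and is not taken from any reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _signal
from scipy.special import erfc

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

__all__ = [
    "RateModelParams",
    "RateTrajectory",
    "PermanenceStats",
    "PermanenceFit",
    "sigmoid",
    "simulate",
    "effective_potential",
    "detect_states",
    "histogram_modes",
    "fit_permanence",
    "classify_updown_phase",
]


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of the stochastic rate model (time in tau_nu units)."""

    J: float = 1.2            # synaptic strength (V)
    theta: float = 0.44       # threshold (V); calibrated, not a printed value
    delta: float = 0.3        # sigmoid width (V)
    nu_m: float = 5e-3        # maximum rate
    tau_nu: float = 1.0
    tau_r: float = 1000.0
    U: float = 0.6
    D: float = 0.0            # synaptic noise amplitude
    sigma_nu: float = 4e-4    # rate-equation noise amplitude (calibrated)
    dt: float = 0.01
    seed: int = 0
    nu_scale: float | None = None   # rate unit of the sigmoid argument
    boundary: str = "clip"          # "clip" or "reflect" at x in [0, 1]

    def __post_init__(self) -> None:
        if min(self.tau_nu, self.tau_r, self.dt) <= 0:
            raise ValueError("tau_nu, tau_r, dt must be positive")
        if self.D < 0 or self.sigma_nu < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not (0.0 <= self.U <= 1.0):
            raise ValueError("U must be in [0, 1]")
        if self.boundary not in ("clip", "reflect"):
            raise ValueError("boundary must be 'clip' or 'reflect'")

    @property
    def rate_unit(self) -> float:
        return self.nu_m if self.nu_scale is None else self.nu_scale


@dataclass
class RateTrajectory:
    t: np.ndarray
    nu: np.ndarray
    x: np.ndarray
    n_clips: int = 0
    sample_dt: float = 0.0


@dataclass
class PermanenceFit:
    model: str              # "exponential" or "power_law"
    rate: float             # exponential MLE on the full sample
    exponent: float         # power-law MLE exponent on the tail
    x_min: float
    loglik_ratio: float     # power_law minus exponential, on the tail
    p_value: float          # normalized (Vuong) significance
    n_tail: int


@dataclass
class PermanenceStats:
    up_durations: np.ndarray
    down_durations: np.ndarray
    no_transitions: bool = False
    thresholds: tuple[float, float] | None = None
    fit: PermanenceFit | None = None


def sigmoid(X: float | np.ndarray, delta: float) -> float | np.ndarray:
    """Sigmoidal excitability ``S(X) = (1 + tanh(X/delta))/2``.

    S(0) = 1/2, S(+inf) = 1, S(-inf) = 0.  The tanh form (rather than a
    logistic of the same width) is required for the printed couplings
    J ~ 1.1-1.2 V with delta = 0.3 V to place the model in the bistable
    regime: the maximal loop gain is J/(2 delta) instead of J/(4 delta).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return 0.5 * (1.0 + np.tanh(np.asarray(X, dtype=float) / delta))


@njit(cache=True)
def _em_loop(nu0, x0, n_steps, record_every, dt, tau_nu, tau_r, U, nu_m,
             J_eff, theta, delta, sig_nu_sq, sig_x_sq, reflect, noise):
    n_rec = n_steps // record_every + 1
    nu_out = np.empty(n_rec)
    x_out = np.empty(n_rec)
    nu, x = nu0, x0
    nu_out[0] = nu
    x_out[0] = x
    clips = 0
    k = 1
    for i in range(n_steps):
        S = 0.5 * (1.0 + math.tanh((J_eff * nu * x - theta) / delta))
        nu_new = nu + (dt / tau_nu) * (-nu + nu_m * S) + sig_nu_sq * noise[2 * i]
        x_new = x + dt * ((1.0 - x) / tau_r - U * x * nu) + sig_x_sq * noise[2 * i + 1]
        if nu_new < 0.0:
            nu_new = 0.0
            clips += 1
        if x_new < 0.0:
            x_new = -x_new if reflect else 0.0
            clips += 1
        elif x_new > 1.0:
            x_new = 2.0 - x_new if reflect else 1.0
            clips += 1
        nu, x = nu_new, x_new
        if (i + 1) % record_every == 0:
            nu_out[k] = nu
            x_out[k] = x
            k += 1
    return nu_out[:k], x_out[:k], clips


def simulate(
    params: RateModelParams,
    t_end: float,
    nu0: float | None = None,
    x0: float = 1.0,
    record_every: int | None = None,
    rng: np.random.Generator | None = None,
) -> RateTrajectory:
    """Euler-Maruyama integration of the coupled (nu, x) system.

    Requires ``dt <= 0.01 * min(1, tau_r)`` (in tau_nu units).  ``nu`` is
    kept nonnegative and ``x`` in [0, 1] by clipping (or reflection);
    boundary events are counted in ``n_clips``.  The trajectory is
    recorded every ``record_every`` steps (default: every 0.1 tau_nu).
    """
    p = params
    if p.dt > 0.01 * min(1.0, p.tau_r) + 1e-15:
        raise ValueError(
            f"dt={p.dt} violates dt <= 0.01*min(1, tau_r)={0.01 * min(1.0, p.tau_r)}"
        )
    if rng is None:
        rng = np.random.default_rng(p.seed)
    if nu0 is None:
        nu0 = 0.05 * p.nu_m
    if record_every is None:
        record_every = max(1, int(round(0.1 / p.dt)))
    n_steps = int(round(t_end / p.dt))
    noise = rng.standard_normal(2 * n_steps)
    sqdt = math.sqrt(p.dt)
    nu_arr, x_arr, clips = _em_loop(
        float(nu0), float(x0), n_steps, record_every, p.dt, p.tau_nu, p.tau_r,
        p.U, p.nu_m, p.J / p.rate_unit, p.theta, p.delta,
        p.sigma_nu * sqdt, (p.D / p.tau_r) * sqdt,
        p.boundary == "reflect", noise,
    )
    sample_dt = record_every * p.dt
    t = np.arange(nu_arr.size) * sample_dt
    return RateTrajectory(t=t, nu=nu_arr, x=x_arr, n_clips=int(clips),
                          sample_dt=sample_dt)


def drift(nu: np.ndarray, x: float, params: RateModelParams) -> np.ndarray:
    """Deterministic drift of nu at frozen x: ``(-nu + nu_m S)/tau_nu``."""
    X = params.J * np.asarray(nu) * x / params.rate_unit - params.theta
    return (-np.asarray(nu) + params.nu_m * sigmoid(X, params.delta)) / params.tau_nu


def effective_potential(
    x_fixed: float, params: RateModelParams
) -> Callable[[np.ndarray], np.ndarray]:
    """Effective potential for the rate at frozen synaptic resource.

    ``Phi(nu) = integral_0^nu [v - nu_m S(J v x/nu_scale - theta)] dv``,
    so that ``tau_nu dnu/dt = -Phi'(nu) + noise``.  Returned as a
    closed-form callable.
    """
    if not (0.0 <= x_fixed <= 1.0):
        raise ValueError("x_fixed must be in [0, 1]")
    p = params
    a = p.J * x_fixed / p.rate_unit

    def phi(nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        quad = 0.5 * nu * nu
        if a == 0.0:
            integral = float(sigmoid(-p.theta, p.delta)) * nu
        else:
            w1 = (a * nu - p.theta) / p.delta
            w0 = -p.theta / p.delta
            integral = 0.5 * nu + (p.delta / (2.0 * a)) * (
                np.logaddexp(w1, -w1) - np.logaddexp(w0, -w0)
            )
        return quad - p.nu_m * integral

    return phi


def histogram_modes(
    nu: np.ndarray, bins: int = 60, smooth: int = 5, min_prominence: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Modes of the rate histogram.

    Returns (mode positions, smoothed counts, bin centers).  Counts are
    smoothed with a moving average before peak detection; peaks need a
    prominence of ``min_prominence`` times the maximum count.
    """
    counts, edges = np.histogram(nu, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth) / smooth
    # peak detection on log counts: a minority state (a few % occupancy)
    # is still a clear mode on the log scale
    smoothed = np.convolve(np.log10(counts + 1.0), kernel, mode="same")
    peaks, _ = _signal.find_peaks(smoothed, prominence=min_prominence * smoothed.max(),
                                  plateau_size=(None, None))
    # a mode at the very edge still counts (smoothing flattens an edge
    # spike into a plateau, so compare against the first interior drop)
    interior = smoothed[1:-1]
    if counts[0] > 0 and smoothed[0] >= smoothed[1] and (
            interior.size == 0 or smoothed[0] > interior.min()):
        peaks = np.concatenate([[0], peaks])
    if counts[-1] > 0 and smoothed[-1] >= smoothed[-2] and (
            interior.size == 0 or smoothed[-1] > interior.min()):
        peaks = np.concatenate([peaks, [smoothed.size - 1]])
    peaks = np.unique(peaks.astype(int))
    return centers[peaks], smoothed, centers


def detect_states(
    traj: RateTrajectory,
    hysteresis: float = 0.25,
    min_dwell_samples: int = 5,
) -> PermanenceStats:
    """Segment a trajectory into up/down dwells with hysteresis.

    Two thresholds are placed at the histogram dip between the two modes,
    offset by ``hysteresis`` times the inter-mode distance; the state
    switches only on a full band crossing.  Dwells shorter than
    ``min_dwell_samples`` samples are discarded.  A unimodal histogram
    sets the ``no_transitions`` flag (phase-P candidate).
    """
    nu = np.asarray(traj.nu)
    modes, smoothed, centers = histogram_modes(nu)
    if modes.size < 2:
        return PermanenceStats(np.array([]), np.array([]), no_transitions=True)
    # two most extreme modes
    low_mode, high_mode = float(modes.min()), float(modes.max())
    sel = (centers > low_mode) & (centers < high_mode)
    if sel.any():
        inner = smoothed[sel]
        # the minimum may be a plateau (empty bins between well-separated
        # modes); place the dip at the plateau center
        ties = np.nonzero(inner <= inner.min() + 1e-12)[0]
        dip = float(centers[sel][ties[ties.size // 2]])
    else:
        dip = 0.5 * (low_mode + high_mode)
    band = hysteresis * (high_mode - low_mode)
    lo, hi = dip - band, dip + band

    state = 0  # +1 up, -1 down
    switch_idx: list[int] = []
    states: list[int] = []
    for i, v in enumerate(nu):
        if v >= hi and state != 1:
            switch_idx.append(i)
            states.append(1)
            state = 1
        elif v <= lo and state != -1:
            switch_idx.append(i)
            states.append(-1)
            state = -1
    if len(switch_idx) < 2:
        return PermanenceStats(np.array([]), np.array([]), no_transitions=True,
                               thresholds=(lo, hi))
    dur = np.diff(switch_idx)
    lab = np.array(states[:-1])
    keep = dur >= min_dwell_samples
    dt_s = traj.sample_dt if traj.sample_dt else float(traj.t[1] - traj.t[0])
    up = dur[keep & (lab == 1)] * dt_s
    down = dur[keep & (lab == -1)] * dt_s
    return PermanenceStats(up_durations=up, down_durations=down,
                           no_transitions=False, thresholds=(lo, hi))


# ---------------------------------------------------------------------------
# permanence-time model selection
# ---------------------------------------------------------------------------

def _powerlaw_fit_tail(x: np.ndarray) -> tuple[float, float, float]:
    """Continuous power-law fit with the lower cutoff chosen by KS
    minimization (Clauset-style).  Returns (alpha, x_min, ks)."""
    xs = np.sort(x)
    # candidate cutoffs: quantiles of the sample (<= 50 candidates).  The
    # tail must retain at least a quarter of the sample (and >= 10
    # points) so the scan cannot retreat into an arbitrarily small tail
    # where any model fits.
    n_min = max(10, xs.size // 4)
    qs = np.unique(xs[np.linspace(0, max(xs.size - n_min, 0), 50).astype(int)])
    best = (np.inf, np.nan, np.nan)
    for xmin in qs:
        tail = xs[xs >= xmin]
        n = tail.size
        if n < n_min:
            continue
        alpha = 1.0 + n / np.sum(np.log(tail / xmin))
        cdf_model = 1.0 - (tail / xmin) ** (1.0 - alpha)
        cdf_emp = np.arange(1, n + 1) / n
        ks = float(np.max(np.abs(cdf_model - cdf_emp)))
        if ks < best[0]:
            best = (ks, alpha, xmin)
    ks, alpha, xmin = best
    return alpha, xmin, ks


def fit_permanence(
    durations: Sequence[float] | np.ndarray, min_samples: int = 200
) -> PermanenceFit:
    """Maximum-likelihood comparison of exponential vs power-law dwell
    distributions.

    The power law uses a lower cutoff ``x_min`` selected by
    Kolmogorov-Smirnov minimization; both models are then fit on the tail
    ``x >= x_min`` and compared with a normalized (Vuong) log-likelihood
    ratio test at the 0.05 level.  The power law is selected only when it
    is significantly better.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} durations, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")

    rate_full = 1.0 / float(np.mean(x))
    alpha, xmin, _ = _powerlaw_fit_tail(x)
    tail = x[x >= xmin]
    n = tail.size

    # log-densities on the common tail
    ll_pl = np.log((alpha - 1.0) / xmin) - alpha * np.log(tail / xmin)
    lam = 1.0 / float(np.mean(tail - xmin))
    ll_ex = np.log(lam) - lam * (tail - xmin)

    pointwise = ll_pl - ll_ex
    R = float(np.sum(pointwise))
    sd = float(np.std(pointwise))
    if sd < 1e-12:
        v = 0.0
    else:
        v = R / (sd * math.sqrt(n))
    p_value = float(erfc(abs(v) / math.sqrt(2.0)))
    model = "power_law" if (R > 0 and p_value < 0.05) else "exponential"
    return PermanenceFit(model=model, rate=rate_full, exponent=float(alpha),
                         x_min=float(xmin), loglik_ratio=R, p_value=p_value,
                         n_tail=int(n))


def classify_updown_phase(
    params: RateModelParams,
    t_end: float = 2e4,
    replicas: int = 4,
    seed: int = 0,
    min_samples: int = 50,
    slaving_corr: float = 0.9,
) -> str:
    """Classify a parameter point as P, E, C, or S.

    P: no up-down transitions detected in any replica.
    S: the rate is slaved to the synaptic variable -- smoothed
    correlation(nu, x) above ``slaving_corr`` with transition rate above
    ``1/(10 tau_r)``.
    C: power-law model selected for the up-state permanence times.
    E: exponential permanence times (the remaining case).
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(7,))
    ups: list[np.ndarray] = []
    n_trans = 0
    corrs: list[float] = []
    for child in ss.spawn(replicas):
        rng = np.random.default_rng(child)
        traj = simulate(params, t_end, rng=rng)
        stats = detect_states(traj)
        if not stats.no_transitions:
            ups.append(stats.up_durations)
            n_trans += stats.up_durations.size + stats.down_durations.size
        w = max(3, int(round(params.tau_r / 10.0 / traj.sample_dt)))
        w = min(w, traj.nu.size // 4)
        kern = np.ones(w) / w
        nu_s = np.convolve(traj.nu, kern, mode="valid")
        x_s = np.convolve(traj.x, kern, mode="valid")
        if nu_s.std() > 0 and x_s.std() > 0:
            corrs.append(float(np.corrcoef(nu_s, x_s)[0, 1]))

    if n_trans == 0:
        return "P"
    rate = n_trans / (replicas * t_end)
    if corrs and np.mean(corrs) > slaving_corr and rate > 1.0 / (10.0 * params.tau_r):
        return "S"
    up = np.concatenate(ups) if ups else np.array([])
    if up.size >= min_samples:
        fit = fit_permanence(up, min_samples=min_samples)
        if fit.model == "power_law":
            return "C"
    return "E"
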