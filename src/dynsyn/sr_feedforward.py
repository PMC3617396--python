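"""Feed-forward stochastic multiresonance with dynamic synapses.

A population of ``N`` presynaptic neurons fires independent Poisson trains
at rate ``f_n`` through dynamic synapses onto a leaky integrate-and-fire
neuron whose firing threshold adapts to the mean synaptic drive.  A weak
(subthreshold) signal is detected through the noise generated by the
synaptic bombardment; detection is quantified by the power norm ``C0``,
the time average of signal times output rate.

Because the synaptic current fluctuations depend non-monotonically on
``f_n`` when synapses depress and facilitate -- while the adaptive
threshold keeps the mean drive ineffective -- the resonance curve
``C0(f_n)`` develops two peaks (one for static synapses): the
low-frequency peak position is controlled by ``tau_fac`` and the
high-frequency one by ``tau_rec``.

Units: time in ms, rates in Hz (converted internally), currents in pA,
voltages in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from dynsyn.tm_synapse import TMParams, SpikeTrain, steady_state

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

__all__ = [
    "SignalSpec",
    "NeuronSpec",
    "SRConfig",
    "CurrentStats",
    "ResonanceCurve",
    "generate_poisson_trains",
    "current_stats",
    "synaptic_current_trace",
    "simulated_current_stats",
    "simulate_postsynaptic",
    "power_norm",
    "resonance_curve",
    "detect_peaks",
    "peak_shift_analysis",
]


@dataclass(frozen=True)
class SignalSpec:
    """Weak input signal: zero-mean sine or rate-modulated Poisson pulses."""

    waveform: str = "sine"          # "sine" or "poisson_pulses"
    amplitude: float = 0.25         # mV, must be subthreshold
    f_s: float = 2.0                # Hz
    pulse_width: float = 2.0        # ms, poisson_pulses only
    pulse_rate: float = 20.0        # Hz, mean pulse rate, poisson_pulses only

    def __post_init__(self) -> None:
        if self.waveform not in ("sine", "poisson_pulses"):
            raise ValueError("waveform must be 'sine' or 'poisson_pulses'")
        if self.f_s <= 0:
            raise ValueError("f_s must be positive")


@dataclass(frozen=True)
class NeuronSpec:
    """Leaky integrate-and-fire neuron with adaptive threshold.

    The threshold relaxes with time constant ``tau_theta`` toward
    ``theta0 + k * (low-pass of R*I)``, so the voltage gap between the
    mean subthreshold drive and the threshold stays approximately
    constant as the presynaptic rate varies (for ``k = 1``).
    """

    tau_m: float = 10.0       # ms
    R: float = 0.1            # mV/pA
    v_reset: float = 0.0      # mV
    theta0: float = 0.75      # mV, baseline gap
    k: float = 1.0            # adaptation gain
    tau_theta: float = 1000.0  # ms
    refractory: float = 2.0   # ms


@dataclass
class SRConfig:
    N: int = 120
    f_n: float = 20.0                        # Hz
    synapse: TMParams = field(default_factory=lambda: TMParams(
        U=0.05, tau_rec=400.0, tau_fac=1000.0, tau_in=3.0, A=100.0))
    signal: SignalSpec = field(default_factory=SignalSpec)
    neuron: NeuronSpec = field(default_factory=NeuronSpec)
    duration: float = 8000.0                 # measurement window, ms
    warmup: float = 3000.0                   # ms
    dt: float = 0.1                          # ms
    trials: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.f_n < 0:
            raise ValueError("need N >= 1 and f_n >= 0")
        # the signal alone must never elicit spikes: its largest voltage
        # response (amplitude, reached at zero frequency) must stay below
        # the baseline gap
        if self.signal.amplitude >= self.neuron.theta0:
            raise ValueError(
                "signal amplitude must stay below the threshold gap theta0")
        period = 1000.0 / self.signal.f_s
        n_per = self.duration / period
        if abs(n_per - round(n_per)) > 1e-9:
            raise ValueError("duration must be a whole number of signal periods")


@dataclass
class CurrentStats:
    mean: float      # pA
    variance: float  # pA^2
    I_p: float       # pA


@dataclass
class ResonanceCurve:
    f_n: np.ndarray
    C0: np.ndarray
    sem: np.ndarray
    peak_freqs: np.ndarray
    peak_prominences: np.ndarray
    smoothed: np.ndarray


def generate_poisson_trains(
    N: int,
    f_n: float,
    t_end: float,
    seed: int | np.random.Generator | None = 0,
) -> list[SpikeTrain]:
    """Independent homogeneous Poisson spike trains at ``f_n`` Hz over
    ``t_end`` ms."""
    if f_n < 0:
        raise ValueError("f_n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate_ms = f_n * 1e-3
    trains = []
    for _ in range(N):
        n = rng.poisson(rate_ms * t_end)
        times = np.sort(rng.random(n)) * t_end
        # enforce strict ordering (coincidences at float resolution are
        # astronomically rare but would violate the SpikeTrain invariant)
        times = np.unique(times)
        trains.append(SpikeTrain(times))
    return trains


def current_stats(N: int, f_n: float, params: TMParams) -> CurrentStats:
    """Stationary mean and variance of the summed synaptic current.

    ``I_p = A u_inf x_inf`` is the single-event efficacy;
    ``mean = N f_n tau_in I_p`` and ``variance = mean * I_p / 2``.
    """
    rate_ms = f_n * 1e-3
    u_inf, x_inf = steady_state(params, rate_ms)
    I_p = params.A * u_inf * x_inf
    mean = N * rate_ms * params.tau_in * I_p
    var = 0.5 * N * rate_ms * params.tau_in * I_p * I_p
    return CurrentStats(mean=mean, variance=var, I_p=I_p)


@njit(cache=True)
def _releases(times: np.ndarray, offsets: np.ndarray, U: float,
              tau_rec: float, tau_fac: float, mode: int) -> np.ndarray:
    """Per-spike release amounts u*x for concatenated spike trains.

    mode: 0 full, 1 depression_only, 2 static.  Between spikes x relaxes
    toward 1 (tau_rec) and u toward U (tau_fac), in closed form.
    """
    out = np.empty(times.size)
    for j in range(offsets.size - 1):
        lo, hi = offsets[j], offsets[j + 1]
        x = 1.0
        u = 1.0 if mode == 1 else U
        t_last = -1e18
        for k in range(lo, hi):
            dt = times[k] - t_last
            if mode == 2:
                out[k] = U
                t_last = times[k]
                continue
            if tau_rec > 0:
                x = 1.0 - (1.0 - x) * math.exp(-dt / tau_rec)
            else:
                x = 1.0
            if mode == 0:
                if tau_fac > 0:
                    u = U + (u - U) * math.exp(-dt / tau_fac)
                else:
                    u = U
            rel = u * x
            out[k] = rel
            x -= rel
            if mode == 0:
                u += U * (1.0 - u)
            t_last = times[k]
    return out


@njit(cache=True)
def _scan_active(weights: np.ndarray, decay: float) -> np.ndarray:
    """Cumulative exponentially-decaying sum of per-bin release weights."""
    y = np.empty(weights.size)
    acc = 0.0
    for i in range(weights.size):
        acc = acc * decay + weights[i]
        y[i] = acc
    return y


def synaptic_current_trace(
    trains: Sequence[SpikeTrain],
    params: TMParams,
    t_end: float,
    dt: float,
) -> np.ndarray:
    """Total synaptic current A * sum_j y_j(t) on a dt grid (pA).

    Each release decays with ``tau_in``; releases are computed exactly per
    synapse (event-driven closed forms) and accumulated into bins with
    their within-bin decay factor.
    """
    n_bins = int(round(t_end / dt))
    counts = np.array([len(tr) for tr in trains])
    offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    times = (np.concatenate([tr.times for tr in trains])
             if counts.sum() else np.empty(0))
    mode = {"full": 0, "depression_only": 1, "static": 2}[params.mode]
    rel = _releases(times, offsets, params.U, params.tau_rec, params.tau_fac, mode)

    idx = np.minimum((times / dt).astype(np.int64), n_bins - 1)
    # weight each release by its decay from the spike time to the bin edge
    w = rel * np.exp(-(((idx + 1) * dt) - times) / params.tau_in)
    binned = np.zeros(n_bins)
    np.add.at(binned, idx, w)
    y = _scan_active(binned, math.exp(-dt / params.tau_in))
    return params.A * y


def simulated_current_stats(
    N: int,
    f_n: float,
    params: TMParams,
    t_end: float = 20_000.0,
    warmup: float = 2_000.0,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte Carlo estimate of the stationary current mean and variance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trains = generate_poisson_trains(N, f_n, warmup + t_end, rng)
    I = synaptic_current_trace(trains, params, warmup + t_end, dt)
    tail = I[int(warmup / dt):]
    return float(tail.mean()), float(tail.var())


@njit(cache=True)
def _membrane(I, S, dt, tau_m, R, v_reset, theta0, k_gain, tau_theta, ref_steps):
    """LIF with adaptive threshold; returns spike step indices."""
    n = I.size
    spikes = np.empty(n, dtype=np.int64)
    n_sp = 0
    v = 0.0
    i_lp = I[0] * R
    theta = theta0 + k_gain * i_lp
    a_m = dt / tau_m
    a_th = dt / tau_theta
    ref = 0
    for i in range(n):
        drive = R * I[i] + S[i]
        i_lp += a_th * (R * I[i] - i_lp)
        theta += a_th * (theta0 + k_gain * i_lp - theta)
        if ref > 0:
            ref -= 1
            v = v_reset
            continue
        v += a_m * (-v + drive)
        if v >= theta:
            spikes[n_sp] = i
            n_sp += 1
            v = v_reset
            ref = ref_steps
    return spikes[:n_sp]


def _signal_wave(spec: SignalSpec, t: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.waveform == "sine":
        return spec.amplitude * np.sin(2.0 * np.pi * spec.f_s * 1e-3 * t)
    # rate-modulated Poisson pulses: short rectangular pulses whose rate
    # is modulated by the sinusoid
    lam = spec.pulse_rate * 1e-3 * (
        1.0 + np.sin(2.0 * np.pi * spec.f_s * 1e-3 * t))
    dt = t[1] - t[0]
    pulses = rng.random(t.size) < lam * dt
    wave = np.zeros(t.size)
    width = max(1, int(round(spec.pulse_width / dt)))
    for i in np.nonzero(pulses)[0]:
        wave[i:i + width] = spec.amplitude
    return wave


def simulate_postsynaptic(
    config: SRConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Simulate the postsynaptic neuron for one trial.

    Returns ``(spike_times_ms, nu, bin_centers_ms, diagnostics)`` where
    ``nu`` is the firing rate (Hz) binned at one twentieth of the signal
    period over the measurement window (warmup excluded).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_total = config.warmup + config.duration
    dt = config.dt
    n = int(round(t_total / dt))
    t = np.arange(n) * dt

    trains = generate_poisson_trains(config.N, config.f_n, t_total, rng)
    I = synaptic_current_trace(trains, config.synapse, t_total, dt)
    S = _signal_wave(config.signal, t, rng)

    neu = config.neuron
    ref_steps = int(round(neu.refractory / dt))
    sp_idx = _membrane(I, S, dt, neu.tau_m, neu.R, neu.v_reset,
                       neu.theta0, neu.k, neu.tau_theta, ref_steps)
    sp_t = sp_idx * dt

    keep = sp_t >= config.warmup
    sp_meas = sp_t[keep] - config.warmup
    period = 1000.0 / config.signal.f_s
    bin_w = period / 20.0
    n_bins = int(round(config.duration / bin_w))
    counts, edges = np.histogram(sp_meas, bins=n_bins, range=(0, config.duration))
    nu = counts / (bin_w * 1e-3)  # Hz
    centers = 0.5 * (edges[:-1] + edges[1:])

    i_meas = I[int(config.warmup / dt):]
    diag = {
        "mean_current": float(i_meas.mean()),
        "var_current": float(i_meas.var()),
        "n_spikes": int(sp_meas.size),
        "rate": float(sp_meas.size / (config.duration * 1e-3)),
    }
    return sp_meas, nu, centers, diag


def power_norm(S: np.ndarray, nu: np.ndarray, dt: float) -> float:
    """Power norm ``C0 = <S(t) nu(t)>``: trapezoidal time average of the
    signal-rate product over the (whole-period) window."""
    S = np.asarray(S, float)
    nu = np.asarray(nu, float)
    if S.shape != nu.shape:
        raise ValueError("signal and rate must share the sampling grid")
    total = S.size * dt
    return float(np.trapezoid(S * nu, dx=dt) / total)


def _c0_trial(config: SRConfig, rng: np.random.Generator) -> float:
    _, nu, centers, _ = simulate_postsynaptic(config, rng)
    S = config.signal.amplitude * np.sin(
        2.0 * np.pi * config.signal.f_s * 1e-3 * (config.warmup + centers))
    return power_norm(S, nu, centers[1] - centers[0])


def resonance_curve(
    config: SRConfig,
    f_n_grid: Sequence[float],
    trials: int | None = None,
    prominence_frac: float = 0.15,
) -> ResonanceCurve:
    """Mean power norm (with s.e.m.) over a presynaptic-rate grid, with
    peak detection on the 3-point moving-average smoothed curve."""
    grid = np.asarray(f_n_grid, float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("f_n grid must be strictly increasing")
    n_trials = config.trials if trials is None else trials
    c0 = np.empty((grid.size, n_trials))
    for i, fn in enumerate(grid):
        cfg = replace(config, f_n=float(fn))
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(3, i))
        for j, child in enumerate(ss.spawn(n_trials)):
            c0[i, j] = _c0_trial(cfg, np.random.default_rng(child))
    mean = c0.mean(axis=1)
    sem = c0.std(axis=1, ddof=1) / math.sqrt(n_trials) if n_trials > 1 else 0 * mean
    freqs, proms, smoothed = detect_peaks(grid, mean, prominence_frac)
    return ResonanceCurve(f_n=grid, C0=mean, sem=sem, peak_freqs=freqs,
                          peak_prominences=proms, smoothed=smoothed)


def detect_peaks(
    grid: np.ndarray, c0: np.ndarray, prominence_frac: float = 0.15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima of the 3-point moving-average smoothed curve with
    prominence above ``prominence_frac`` of the curve maximum."""
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(c0, kernel, mode="same")
    smoothed[0] = c0[0]
    smoothed[-1] = c0[-1]
    peaks, props = _signal.find_peaks(
        smoothed, prominence=prominence_frac * smoothed.max())
    return (np.asarray(grid)[peaks], props.get("prominences", np.empty(0)),
            smoothed)


def peak_shift_analysis(
    base_config: SRConfig,
    param_name: str,
    values: Sequence[float],
    f_n_grid: Sequence[float],
    trials: int | None = None,
):
    """Table of two-peak positions as a synaptic time constant is varied.

    ``param_name`` is ``"tau_rec"`` or ``"tau_fac"``.  Curves with fewer
    than two detected peaks are flagged and excluded from shift
    comparisons.  Returns a pandas DataFrame with columns (value,
    low_peak, high_peak, n_peaks, excluded).
    """
    import pandas as pd

    if len(values) < 2:
        raise ValueError("need at least two parameter values")
    if param_name not in ("tau_rec", "tau_fac"):
        raise ValueError("param_name must be 'tau_rec' or 'tau_fac'")
    rows = []
    for val in values:
        syn = replace(base_config.synapse, **{param_name: float(val)})
        cfg = replace(base_config, synapse=syn)
        curve = resonance_curve(cfg, f_n_grid, trials)
        pk = np.sort(curve.peak_freqs)
        rows.append({
            "value": float(val),
            "low_peak": pk[0] if pk.size >= 2 else np.nan,
            "high_peak": pk[-1] if pk.size >= 2 else np.nan,
            "n_peaks": int(pk.size),
            "excluded": pk.size < 2,
        })
    return pd.DataFrame(rows)
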