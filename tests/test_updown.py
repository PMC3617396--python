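import numpy as np
import pytest

from dynsyn.updown import (
    PermanenceStats,
    RateModelParams,
    RateTrajectory,
    classify_updown_phase,
    detect_states,
    effective_potential,
    fit_permanence,
    histogram_modes,
    sigmoid,
    simulate,
)

UPDOWN_REF = RateModelParams(J=1.2, theta=0.44, delta=0.3, nu_m=5e-3, tau_r=1000.0,
                        U=0.6, D=0.0, sigma_nu=4e-4, dt=0.01, seed=0)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0, 0.3) == 0.5

    def test_limits(self):
        assert sigmoid(1e3, 0.3) == pytest.approx(1.0)
        assert sigmoid(-1e3, 0.3) == pytest.approx(0.0)

    def test_monotone(self):
        x = np.linspace(-3, 3, 101)
        assert np.all(np.diff(sigmoid(x, 0.3)) > 0)

    def test_delta_validation(self):
        with pytest.raises(ValueError):
            sigmoid(0.0, 0.0)


class TestSimulate:
    def test_noiseless_relaxes_to_fixed_point(self):
        p = RateModelParams(J=1.2, theta=0.44, tau_r=50.0, U=0.6,
                            D=0.0, sigma_nu=0.0, dt=0.005, seed=0)
        traj = simulate(p, 5_000.0, nu0=0.2 * p.nu_m, x0=0.9)
        nu_star, x_star = traj.nu[-1], traj.x[-1]
        # residuals of both nullclines at the endpoint

        def resid(v):
            nu, x = v
            d_nu = (-nu + p.nu_m * sigmoid(p.J * nu * x / p.nu_m - p.theta,
                                           p.delta)) / p.tau_nu
            d_x = (1.0 - x) / p.tau_r - p.U * x * nu
            return [d_nu, d_x]

        assert np.max(np.abs(resid([nu_star, x_star]))) < 1e-8

    def test_fixed_point_conservation(self):
        # starting exactly at the deterministic fixed point, drift < 1e-6
        p = RateModelParams(J=1.2, theta=0.44, tau_r=50.0, U=0.6,
                            D=0.0, sigma_nu=0.0, dt=0.005, seed=0)
        warm = simulate(p, 5_000.0, nu0=0.2 * p.nu_m, x0=0.9)
        nu0, x0 = warm.nu[-1], warm.x[-1]
        traj = simulate(p, 50.0, nu0=nu0, x0=x0)  # 10^4 steps at dt=0.005
        assert abs(traj.nu[-1] - nu0) < 1e-6
        assert abs(traj.x[-1] - x0) < 1e-6

    def test_ou_limit_at_zero_release(self):
        # U=0, D>0: x is an OU process around 1 (reflected at the bound);
        # autocorrelation time ~ tau_r
        p = RateModelParams(J=1.2, theta=0.44, tau_r=50.0, U=0.0, D=1.0,
                            sigma_nu=0.0, dt=0.005, seed=2, boundary="reflect")
        traj = simulate(p, 40_000.0, x0=1.0, record_every=10)
        x = traj.x[2000:]
        sigma_ou = (p.D / p.tau_r) * np.sqrt(p.tau_r / 2.0)
        assert abs(x.mean() - 1.0) < 2.0 * sigma_ou
        # ACF decay time of the centered series within a factor 2 of tau_r
        xc = x - x.mean()
        acf = [1.0] + [np.corrcoef(xc[:-k], xc[k:])[0, 1]
                       for k in range(1, 3000, 50)][0:40]
        lags = np.arange(0, 2000, 50)[: len(acf)] * traj.sample_dt
        tau_fit = -1.0 / np.polyfit(lags[:20], np.log(np.maximum(acf[:20], 1e-3)), 1)[0]
        # reflection at the x=1 bound folds the process and shortens the
        # apparent correlation time (~tau_r/2 for an OU centered on the
        # boundary); assert the right order of magnitude
        assert p.tau_r / 4.0 < tau_fit < 1.5 * p.tau_r

    def test_bimodal_histogram_reference_parameters(self):
        traj = simulate(UPDOWN_REF, 40_000.0)
        modes, _, _ = histogram_modes(traj.nu)
        assert modes.size >= 2

    def test_noise_scaling_monostable(self):
        # doubling sigma_nu quadruples the stationary rate variance
        base = RateModelParams(J=0.5, theta=0.44, tau_r=50.0, U=0.1,
                               D=0.0, sigma_nu=1e-4, dt=0.005, seed=4)
        v = []
        for mult, seed in ((1.0, 0), (2.0, 1)):
            p = RateModelParams(J=0.5, theta=0.44, tau_r=50.0, U=0.1, D=0.0,
                                sigma_nu=mult * 1e-4, dt=0.005, seed=seed)
            traj = simulate(p, 20_000.0)
            v.append(traj.nu[5000:].var())
        assert v[1] / v[0] == pytest.approx(4.0, rel=0.25)

    def test_dt_precondition(self):
        with pytest.raises(ValueError):
            simulate(RateModelParams(dt=0.02), 100.0)

    def test_reproducible(self):
        a = simulate(UPDOWN_REF, 500.0)
        b = simulate(UPDOWN_REF, 500.0)
        assert np.array_equal(a.nu, b.nu)


class TestEffectivePotential:
    def test_gradient_vanishes_at_fixed_points(self):
        p = RateModelParams(J=1.1, theta=0.44)
        for xf in (0.3, 0.85, 1.0):
            phi = effective_potential(xf, p)
            nu = np.linspace(0.0, 1.2 * p.nu_m, 40_001)
            dphi = np.gradient(phi(nu), nu)
            sign_flips = np.nonzero(np.diff(np.sign(dphi)))[0]
            for i in sign_flips:
                nu_star = nu[i]
                # drift = -Phi' must vanish here
                drift = (-nu_star + p.nu_m * sigmoid(
                    p.J * nu_star * xf / p.nu_m - p.theta, p.delta))
                assert abs(drift) < 1e-4 * p.nu_m

    def test_minimum_position_follows_x(self):
        p = RateModelParams(J=1.1, theta=0.44)

        def global_min(xf):
            phi = effective_potential(xf, p)
            nu = np.linspace(0.0, 1.2 * p.nu_m, 20_001)
            return nu[np.argmin(phi(nu))]

        assert global_min(0.2) < 0.2 * p.nu_m   # depressed: down state
        assert global_min(1.0) > 0.7 * p.nu_m   # recovered: up state

    def test_bistable_at_intermediate_x(self):
        p = RateModelParams(J=1.1, theta=0.44)
        phi = effective_potential(0.85, p)
        nu = np.linspace(0.0, 1.2 * p.nu_m, 40_001)
        v = phi(nu)
        dv = np.diff(v)
        minima = np.nonzero((dv[:-1] < 0) & (dv[1:] > 0))[0]
        assert minima.size == 2

    def test_invalid_x(self):
        with pytest.raises(ValueError):
            effective_potential(1.5, RateModelParams())


def _make_traj(nu, dt=0.1):
    nu = np.asarray(nu, float)
    return RateTrajectory(t=np.arange(nu.size) * dt, nu=nu,
                          x=np.ones_like(nu), sample_dt=dt)


class TestDetectStates:
    def test_square_wave_recovery(self, rng):
        plateau = 400
        wave = np.tile(np.concatenate([np.full(plateau, 1.0),
                                       np.full(plateau, 0.0)]), 12)
        noisy = wave + 0.02 * rng.standard_normal(wave.size)
        traj = _make_traj(noisy)
        stats = detect_states(traj)
        assert not stats.no_transitions
        all_d = np.concatenate([stats.up_durations, stats.down_durations])
        expected = plateau * traj.sample_dt
        assert np.all(np.abs(all_d - expected) <= traj.sample_dt + 1e-9)

    def test_monostable_flag(self, rng):
        traj = _make_traj(0.5 + 0.01 * rng.standard_normal(20_000))
        assert detect_states(traj).no_transitions

    def test_detector_idempotence(self, rng):
        plateau = 300
        wave = np.tile(np.concatenate([np.full(plateau, 1.0),
                                       np.full(plateau, 0.0)]), 10)
        traj = _make_traj(wave + 0.01 * rng.standard_normal(wave.size))
        s1 = detect_states(traj)
        # rebuild a clean square wave from the detected durations
        segs = []
        ups, downs = list(s1.up_durations), list(s1.down_durations)
        level = 1.0
        while ups or downs:
            src = ups if level == 1.0 else downs
            if not src:
                break
            d = src.pop(0)
            segs.append(np.full(int(round(d / traj.sample_dt)), level))
            level = 1.0 - level
        rebuilt = _make_traj(np.concatenate(segs))
        s2 = detect_states(rebuilt)
        d1 = np.concatenate([s1.up_durations, s1.down_durations])
        d2 = np.concatenate([s2.up_durations, s2.down_durations])
        assert d2.size > 0
        assert set(np.round(d2, 6)).issubset(set(np.round(d1, 6)))

    def test_telegraph_mle(self):
        # telegraph process with exponential dwells at rate 1: MLE dwell
        # mean within 5% at ~10^4 events
        rng = np.random.default_rng(3)
        dwells = rng.exponential(1.0, 10_000)
        dt = 0.005
        level, parts = 1.0, []
        for d in dwells:
            parts.append(np.full(max(1, int(round(d / dt))), level))
            level = 1.0 - level
        traj = _make_traj(np.concatenate(parts), dt=dt)
        stats = detect_states(traj, min_dwell_samples=1)
        est = np.concatenate([stats.up_durations, stats.down_durations]).mean()
        assert est == pytest.approx(1.0, rel=0.05)


class TestFitPermanence:
    def test_exponential_selected(self):
        rng = np.random.default_rng(0)
        fit = fit_permanence(rng.exponential(1.0, 10_000))
        assert fit.model == "exponential"
        assert fit.rate == pytest.approx(1.0, rel=0.03)

    def test_power_law_selected(self):
        rng = np.random.default_rng(1)
        sample = rng.pareto(1.5, 10_000) + 1.0  # density exponent 2.5
        fit = fit_permanence(sample)
        assert fit.model == "power_law"
        assert fit.exponent == pytest.approx(2.5, abs=0.1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_permanence(np.ones(50))

    def test_positive_durations_required(self):
        with pytest.raises(ValueError):
            fit_permanence(np.concatenate([np.ones(300), [-1.0]]))


class TestClassifyPhase:
    def test_noiseless_bistable_is_P(self):
        p = RateModelParams(J=1.2, theta=0.5, tau_r=50.0, U=0.0,
                            D=0.0, sigma_nu=0.0, dt=0.005, seed=0)
        assert classify_updown_phase(p, t_end=2_000.0, replicas=2) == "P"

    def test_static_synapses_never_critical(self):
        # tau_r -> 0 (fast x) with D = 0: only P or E can emerge
        p = RateModelParams(J=1.1, theta=0.46, tau_r=2.0, U=0.04, D=0.0,
                            sigma_nu=8e-4, dt=0.01, seed=1)
        label = classify_updown_phase(p, t_end=30_000.0, replicas=2)
        assert label in ("P", "E")

    def test_exponential_at_D0(self):
        p = RateModelParams(J=1.1, theta=0.46, tau_r=1000.0, U=0.04, D=0.0,
                            sigma_nu=8e-4, dt=0.01, seed=1)
        label = classify_updown_phase(p, t_end=30_000.0, replicas=2)
        assert label in ("P", "E")
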