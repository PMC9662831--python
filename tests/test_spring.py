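import math

import numpy as np
import pytest

import parahop as ph
from parahop.simulate import Trajectory
from parahop.spring import FIT_REGION_MASS, KB_PN_UM
from parahop.synth import SyntheticSpec


def _traj(positions, dt_min=1.0):
    x = np.asarray(positions, dtype=float)
    return Trajectory(
        times=np.arange(x.size) * dt_min * 60.0,
        positions=x[:, None],
        tether_counts=np.zeros((x.size, 1), dtype=np.int64),
        sampling_interval=dt_min * 60.0,
        L=10.0,
        seed=0,
    )


class TestStepwiseVelocities:
    def test_three_point_arithmetic(self):
        pairs = ph.stepwise_velocities(_traj([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(pairs, [[-1 / 3, 1.0], [2 / 3, -1.0]])

    def test_constant_track_gives_zero_pairs(self):
        pairs = ph.stepwise_velocities(_traj([0.5] * 10))
        assert np.all(pairs == 0.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            ph.stepwise_velocities(_traj([1.0]))

    def test_ou_regression_slope_matches_closed_form(self, ou_track_long):
        """E[v|x0] = x0 (e^{-dt/tau} - 1)/dt for an over-damped spring."""
        spec, traj = ou_track_long
        pairs = ph.stepwise_velocities(traj)
        slope = np.polyfit(pairs[:, 0], pairs[:, 1], 1)[0]
        expected = math.expm1(-1.0 / (spec.tau / 60.0))  # per min, dt=1 min
        assert slope == pytest.approx(expected, rel=0.03)


class TestVelocityProfile:
    def test_exact_linear_restoring_force(self):
        x = np.linspace(-1, 1, 400)
        pairs = np.column_stack([x, -0.4 * x])
        prof = ph.fit_velocity_profile(pairs)
        assert prof.slope == pytest.approx(-0.4, abs=1e-12)
        assert prof.var_v == pytest.approx(0.0, abs=1e-20)
        # per-bin sd reflects only the deterministic within-bin variation
        # of a linear profile, at most bin_width*|m|/sqrt(12)
        assert np.all(prof.sd_v <= 0.05 * 0.4 / np.sqrt(12.0) + 1e-12)

    def test_fit_region_holds_at_least_68_percent(self, ou_track_long):
        _, traj = ou_track_long
        pairs = ph.stepwise_velocities(traj)
        prof = ph.fit_velocity_profile(pairs)
        assert prof.n_points >= FIT_REGION_MASS * pairs.shape[0]
        lo, hi = prof.fit_region
        assert lo == -hi

    def test_velocity_sd_independent_of_position_for_ou(self, ou_track_long):
        """Spring-like motion: Var[v] does not depend on starting position."""
        _, traj = ou_track_long
        pairs = ph.stepwise_velocities(traj)
        prof = ph.fit_velocity_profile(pairs)
        well = prof.counts >= 200
        sds = prof.sd_v[well]
        assert sds.max() - sds.min() < 0.25 * sds.mean()

    def test_single_bin_is_an_error(self):
        pairs = np.column_stack([np.zeros(10), np.ones(10)])
        with pytest.raises(ValueError):
            ph.fit_velocity_profile(pairs)


class TestOUEstimates:
    def test_two_minute_relaxation_from_slope(self):
        est = ph.ou_estimates(m=math.expm1(-0.5), var_v=1.0, dt_sample=1.0)
        assert est.tau == pytest.approx(2.0, rel=1e-12)

    def test_slope_out_of_range_rejected(self):
        for m in (0.0, 0.1, -1.0, -1.5):
            with pytest.raises(ValueError):
                ph.ou_estimates(m=m, var_v=1.0, dt_sample=1.0)

    def test_weak_spring_limit_is_pure_diffusion(self):
        # m -> 0-: tau -> inf and D -> var_v * dt/2
        est = ph.ou_estimates(m=-1e-8, var_v=2.0, dt_sample=1.0)
        assert est.tau > 1e6
        assert est.D * 60.0 == pytest.approx(2.0 * 1.0 / 2.0, rel=1e-4)

    def test_parameter_recovery_on_exact_ou(self, ou_track_long):
        """Round trip: generate OU at the fitted magnitudes, re-estimate
        (D, tau) from the velocity profile within 10%."""
        spec, traj = ou_track_long
        pairs = ph.stepwise_velocities(traj)
        prof = ph.fit_velocity_profile(pairs)
        est = ph.ou_estimates(prof.slope, prof.var_v, dt_sample=1.0)
        assert est.tau * 60.0 == pytest.approx(spec.tau, rel=0.10)
        assert est.D == pytest.approx(spec.D, rel=0.10)
        assert est.k_over_kBT == pytest.approx(1.0 / (spec.D * spec.tau), rel=0.15)


class TestTransitionDensity:
    @pytest.mark.parametrize("D,tau,dt", [(2e-4, 120.0, 60.0), (1e-3, 30.0, 5.0)])
    def test_normalisation(self, D, tau, dt):
        x = np.linspace(-3, 3, 20001)
        dens = ph.ou_transition_density(x, dt, x0=0.3, D=D, tau=tau)
        assert np.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-6)

    def test_long_lag_forgets_start(self):
        x = np.linspace(-2, 2, 10001)
        dens = ph.ou_transition_density(x, 1e9, x0=1.0, D=2e-4, tau=120.0)
        mean = np.trapezoid(x * dens, x)
        var = np.trapezoid(x**2 * dens, x)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert var == pytest.approx(2e-4 * 120.0, rel=1e-6)

    def test_short_lag_concentrates_at_start(self):
        d_near = ph.ou_transition_density(1.0, 1e-6, x0=1.0, D=2e-4, tau=120.0)
        d_far = ph.ou_transition_density(0.9, 1e-6, x0=1.0, D=2e-4, tau=120.0)
        assert d_near > 1e3 * max(d_far, 1e-300)


class TestAutocorrModels:
    def test_lag_zero_normalisation(self):
        pos, vel = ph.autocorr_models(0.0, dt_sample=1.0, tau=2.0)
        assert (pos, vel) == (1.0, 1.0)

    def test_position_decay_at_one_tau(self):
        pos, _ = ph.autocorr_models(2.0, dt_sample=1.0, tau=2.0)
        assert pos == pytest.approx(math.exp(-1.0))

    @pytest.mark.parametrize("tau,dt", [(2.0, 1.0), (0.5, 1.0), (10.0, 3.0)])
    def test_velocity_anticorrelated_at_the_sampling_lag(self, tau, dt):
        """Negative velocity autocorrelation at lag = sampling time is the
        signature of elastic motion."""
        _, vel = ph.autocorr_models(dt, dt_sample=dt, tau=tau)
        a = math.exp(-dt / tau)
        assert vel == pytest.approx(-((1 - a) ** 2) / (2 - 2 * a), rel=1e-12)
        assert vel < 0


class TestEmpiricalAutocorr:
    def test_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        ac = ph.empirical_autocorr(rng.normal(size=100), 10)
        assert ac[0] == 1.0

    def test_cosine_autocorrelation_is_cosine(self):
        # the biased estimator tapers by (n-k)/n at lag k
        n = 2000
        t = np.arange(n)
        x = np.cos(2 * np.pi * t / 100)
        ac = ph.empirical_autocorr(x, 200)
        k = np.arange(150)
        expected = np.cos(2 * np.pi * k / 100) * (n - k) / n
        np.testing.assert_allclose(ac[:150], expected, atol=0.05)

    def test_ou_autocorrelation_matches_model(self, ou_track_long):
        spec, traj = ou_track_long
        ac = ph.empirical_autocorr(traj.series(0), 10)
        lags_s = np.arange(11) * 60.0
        model, _ = ph.autocorr_models(lags_s, 60.0, spec.tau)
        np.testing.assert_allclose(ac, model, atol=0.03)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ph.empirical_autocorr(np.ones(50), 5)


class TestMSD:
    def test_pure_diffusion_is_linear(self):
        spec = SyntheticSpec(kind="diffusion", D=1e-4, dt_sample=1.0,
                             n_steps=200_000, seed=3, cell_length=50.0)
        traj = ph.gen_diffusion(spec)
        lags, m = ph.msd(traj, lags=[1.0, 2.0, 4.0])
        np.testing.assert_allclose(m, 2 * spec.D * lags, rtol=0.05)

    def test_ou_msd_plateaus_at_twice_stationary_variance(self, ou_track_long):
        spec, traj = ou_track_long
        lags, m = ph.msd(traj, lags=[60.0, 600.0, 3000.0])
        expected = 2 * spec.D * spec.tau * (1 - np.exp(-lags / spec.tau))
        np.testing.assert_allclose(m, expected, rtol=0.08)

    def test_short_lag_recovers_diffusion_coefficient(self):
        spec = SyntheticSpec(kind="diffusion", D=2.01e-4, dt_sample=1.0,
                             n_steps=100_000, seed=9, cell_length=50.0)
        lags, m = ph.msd(ph.gen_diffusion(spec), lags=[1.0])
        assert m[0] / (2 * lags[0]) == pytest.approx(2.01e-4, rel=0.10)

    def test_bad_lags_rejected(self):
        traj = ph.gen_ou(SyntheticSpec(kind="ou", n_steps=50, seed=0))
        with pytest.raises(ValueError):
            ph.msd(traj, lags=[90.0])   # not a multiple of 60 s
        with pytest.raises(ValueError):
            ph.msd(traj, lags=[60.0 * 60])  # beyond the span


class TestCharacteristicForce:
    def test_zero_spring_means_zero_force(self):
        assert ph.characteristic_force(0.0) == 0.0

    def test_fitted_spring_constant_force_scale(self):
        # k/kBT = 36.8 um^-2 at 30 C: F = kBT*sqrt(k/kBT) ~ 0.025 pN
        f = ph.characteristic_force(36.8, T=303.15)
        assert f == pytest.approx(KB_PN_UM * 303.15 * math.sqrt(36.8), rel=1e-12)
        assert f == pytest.approx(0.0254, abs=0.0005)

    def test_sqrt_scaling(self):
        assert ph.characteristic_force(2.0) == pytest.approx(
            math.sqrt(2) * ph.characteristic_force(1.0)
        )
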