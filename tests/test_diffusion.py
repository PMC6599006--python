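"""MSD estimation, displacement pooling, bootstrap errors and the
two-Gaussian sliding-mode mixture fit."""

import numpy as np
import pytest
from scipy.integrate import quad

from idrpep.diffusion import (
    DisplacementSample,
    MsdCurve,
    Trajectory,
    bootstrap_histogram_errors,
    compute_msd,
    displacement_sample,
    fit_diffusion_coefficient,
    fit_two_mode,
    two_mode_density,
)
from idrpep.synthetic_data import SlidingSimSpec, simulate_sliding

DT = 0.033


def make_traj(positions, tid="t0", dt=DT):
    return Trajectory(id=tid, frame_interval=dt, positions=np.asarray(positions, float))


class TestTrajectoryValidation:
    def test_too_short(self):
        with pytest.raises(ValueError, match=">= 2 frames"):
            make_traj([0.0])

    def test_non_finite(self):
        with pytest.raises(ValueError):
            make_traj([0.0, np.nan])


class TestComputeMsd:
    def test_stationary_trajectory_gives_zero(self):
        msd = compute_msd([make_traj(np.zeros(50))], max_lag=0.5)
        assert np.allclose(msd.msd, 0.0)
        assert msd.msd[0] == 0.0 and msd.lag_times[0] == 0.0

    def test_ballistic_closed_form_without_drift_correction(self):
        v = 2.0
        t = np.arange(60) * DT
        msd = compute_msd([make_traj(v * t)], max_lag=0.5, drift_correction=False)
        assert np.allclose(msd.msd, v**2 * msd.lag_times**2, rtol=1e-10)

    def test_drift_correction_removes_ballistic_component(self):
        v = 2.0
        t = np.arange(60) * DT
        msd = compute_msd([make_traj(v * t)], max_lag=0.5, drift_correction=True)
        assert np.allclose(msd.msd, 0.0, atol=1e-20)

    def test_brownian_recovery_within_3_sem(self):
        spec = SlidingSimSpec(
            n_trajectories=200, n_frames=100, d_slow=0.3, d_fast=0.3,
            fraction_fast=0.0, localization_sd=0.02, seed=11,
        )
        trajs, _ = simulate_sliding(spec)
        msd = compute_msd(trajs, max_lag=0.4)
        fit = fit_diffusion_coefficient(msd)
        assert abs(fit.d - 0.3) <= 3 * fit.d_sem
        # localization noise shows up as a positive intercept ~ 2 sigma^2
        assert fit.intercept == pytest.approx(2 * 0.02**2, rel=0.5)

    def test_requested_lag_longer_than_all_trajectories(self):
        with pytest.raises(ValueError):
            compute_msd([make_traj([0.0, 1.0])], max_lag=0.01)

    def test_mixed_frame_intervals_rejected(self):
        with pytest.raises(ValueError, match="mixed frame intervals"):
            compute_msd([make_traj(np.zeros(5)), make_traj(np.zeros(5), dt=0.05)],
                        max_lag=0.1)


class TestFitDiffusionCoefficient:
    def _curve(self, d, b=0.0):
        lags = np.arange(11) * DT
        return MsdCurve(lag_times=lags, msd=2 * d * lags + b,
                        n_pairs=np.full(11, 100), sem=np.zeros(11))

    def test_exact_line(self):
        fit = fit_diffusion_coefficient(self._curve(0.5))
        assert fit.d == pytest.approx(0.5, rel=1e-12)
        assert not fit.negative_slope

    def test_exact_line_with_offset(self):
        fit = fit_diffusion_coefficient(self._curve(0.5, b=0.01))
        assert fit.d == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(0.01, rel=1e-10)

    def test_negative_slope_flagged(self):
        fit = fit_diffusion_coefficient(self._curve(-0.1))
        assert fit.negative_slope and fit.d < 0

    def test_too_few_lags(self):
        curve = self._curve(0.5)
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(curve, fit_lag_range=(0.0, 0.02))


class TestDisplacementSample:
    def test_stationary_gives_all_zero(self):
        s = displacement_sample([make_traj(np.zeros(20))], lag=DT)
        assert np.allclose(s.displacements, 0.0)

    def test_counting_one_frame_lag(self):
        s = displacement_sample([make_traj(np.arange(15.0))], lag=DT)
        assert s.n == 14

    def test_non_commensurate_lag_suggests_nearest(self):
        with pytest.raises(ValueError, match="nearest valid lag"):
            displacement_sample([make_traj(np.zeros(20))], lag=0.05)

    def test_two_mode_pooled_variance_matches_mixture_moment(self):
        spec = SlidingSimSpec(n_trajectories=400, n_frames=100, seed=21)
        trajs, truth = simulate_sliding(spec)
        s = displacement_sample(trajs, lag=5 * DT)
        expected = (
            (1 - truth["fraction_fast"]) * 2 * truth["d_slow"] * s.lag
            + truth["fraction_fast"] * 2 * truth["d_fast"] * s.lag
            + 2 * truth["localization_sd"] ** 2
        )
        assert s.displacements.var() == pytest.approx(expected, rel=0.1)


class TestBootstrapErrors:
    def _sample(self, values):
        return DisplacementSample(lag=DT, displacements=np.asarray(values, float),
                                  source_ids=("t0",))

    def test_identical_values_give_zero_sem(self):
        s = self._sample(np.full(200, 0.3))
        bins = np.linspace(-1, 1, 11)
        assert np.allclose(bootstrap_histogram_errors(s, bins, n_boot=50), 0.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        s = self._sample(rng.normal(size=500))
        bins = np.linspace(-4, 4, 21)
        a = bootstrap_histogram_errors(s, bins, n_boot=100, seed=7)
        b = bootstrap_histogram_errors(s, bins, n_boot=100, seed=7)
        assert np.array_equal(a, b)

    def test_sem_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=400)
        bins = np.linspace(-4, 4, 17)
        s1 = bootstrap_histogram_errors(self._sample(base), bins, n_boot=400, seed=2)
        s4 = bootstrap_histogram_errors(self._sample(np.tile(base, 4)), bins,
                                        n_boot=400, seed=3)
        mask = s1 > 0
        ratio = np.median(s4[mask] / s1[mask])
        assert ratio == pytest.approx(0.5, abs=0.12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_histogram_errors(self._sample([]), np.linspace(-1, 1, 5))


class TestTwoModeDensity:
    def test_single_mode_reduces_to_gaussian(self):
        dx = np.linspace(-2, 2, 201)
        d, v, dt = 0.3, 1.5, 0.165
        mix = two_mode_density(dx, dt, [1.0, 0.0], [v, 0.0], [d, 1.0])
        var = 2 * d * dt
        gauss = np.exp(-((dx + v * dt) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        assert np.allclose(mix, gauss, rtol=1e-12)


class TestFitTwoMode:
    def _mixture_sample(self, n=5000, d=(0.05, 0.5), w=0.5, v=(0.0, 0.0),
                        lag=0.165, seed=0):
        rng = np.random.default_rng(seed)
        fast = rng.random(n) < w
        d_arr = np.where(fast, d[1], d[0])
        v_arr = np.where(fast, v[1], v[0])
        dx = rng.normal(-v_arr * lag, np.sqrt(2 * d_arr * lag))
        return DisplacementSample(lag=lag, displacements=dx, source_ids=("sim",))

    def test_two_mode_recovery(self):
        s = self._mixture_sample(seed=4)
        fit = fit_two_mode(s, n_boot=200, seed=1)
        d1, d2 = fit.diffusion_coefficients
        assert d1 == pytest.approx(0.05, rel=0.15)
        assert d2 == pytest.approx(0.5, rel=0.15)
        assert abs(fit.fraction_fast - 0.5) < 0.1
        assert fit.converged and not fit.degenerate
        assert fit.rss < fit.single_mode_rss

    def test_modes_labeled_slow_first(self):
        fit = fit_two_mode(self._mixture_sample(seed=5), n_boot=100, seed=2)
        assert fit.diffusion_coefficients[0] <= fit.diffusion_coefficients[1]

    def test_single_mode_sample_is_degenerate_or_one_amplitude_vanishes(self):
        s = self._mixture_sample(d=(0.2, 0.2), seed=6)
        fit = fit_two_mode(s, n_boot=100, seed=3)
        a = fit.amplitudes
        small_amp = min(a) / (a[0] + a[1]) < 0.05
        close_d = fit.degenerate or np.isclose(*fit.diffusion_coefficients, rtol=0.2)
        assert small_amp or close_d
        # combined density still matches the generating Gaussian
        dx = np.linspace(-1.5, 1.5, 101)
        var = 2 * 0.2 * s.lag
        gauss = np.exp(-(dx**2) / (2 * var)) / np.sqrt(2 * np.pi * var)
        assert np.allclose(fit.density(dx), gauss, atol=0.08 * gauss.max())

    def test_fitted_density_integrates_to_total_amplitude(self):
        fit = fit_two_mode(self._mixture_sample(seed=7), n_boot=100, seed=4)
        integral, _ = quad(lambda x: float(fit.density(x)), -10, 10, limit=200)
        assert integral == pytest.approx(fit.amplitudes.sum(), rel=1e-6)

    def test_mixture_second_moment_consistency(self):
        s = self._mixture_sample(v=(0.5, 2.0), seed=8)
        fit = fit_two_mode(s, n_boot=100, seed=5)
        a = fit.amplitudes / fit.amplitudes.sum()
        v, d, dt = fit.drifts, fit.diffusion_coefficients, s.lag
        model_var = float(
            np.sum(a * (2 * d * dt + (v * dt) ** 2)) - np.sum(a * v * dt) ** 2
        )
        assert model_var == pytest.approx(s.displacements.var(), rel=0.1)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="displacements"):
            fit_two_mode(self._mixture_sample(n=50, seed=9))


def test_msd_estimator_unbiased_on_pure_diffusion():
    spec = SlidingSimSpec(n_trajectories=150, n_frames=80, d_slow=0.2, d_fast=0.2,
                          fraction_fast=0.0, localization_sd=0.0, seed=31)
    trajs, _ = simulate_sliding(spec)
    msd = compute_msd(trajs, max_lag=0.3)
    for m in range(1, len(msd.lag_times)):
        assert abs(msd.msd[m] - 2 * 0.2 * msd.lag_times[m]) <= 3 * msd.sem[m]
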