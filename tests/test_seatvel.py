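import numpy as np
import pytest

from careshift import (
    MotionProfile,
    TransductionParams,
    average_channels,
    default_layout,
    find_fit_window,
    fit_exponential,
    simulate_counts,
    velocity_coefficient,
)
from careshift.errors import FitError, ParameterError, WindowError
from conftest import make_counts


class TestAverageChannels:
    def test_single_channel_unchanged(self, noiseless_counts):
        s = average_channels(noiseless_counts, (3,))
        assert np.array_equal(s, noiseless_counts.counts[:, 2])

    def test_two_constant_channels(self):
        m = np.zeros((4, 20))
        m[:, 0] = 100.0
        m[:, 1] = 200.0
        s = average_channels(make_counts(m), (1, 2))
        assert np.allclose(s, 150.0)

    def test_default_pair_rises_then_plateaus(self, noiseless_counts):
        """Shape check on a noiseless simulated trial."""
        s = average_channels(noiseless_counts)
        p = MotionProfile()
        t = noiseless_counts.t
        assert s[t < p.approach_start].std() < 1.0
        rise = s[np.searchsorted(t, p.contact_time + 2.0)] - s[0]
        assert rise > 100.0
        late = s[t > p.contact_time + 3.0]
        assert np.ptp(late) <= 1.0

    def test_invalid_channel_rejected(self, noiseless_counts):
        with pytest.raises(ParameterError):
            average_channels(noiseless_counts, (0,))
        with pytest.raises(ParameterError):
            average_channels(noiseless_counts, (21,))


class TestFindFitWindow:
    def test_window_is_62_samples_at_62_hz(self):
        rng = np.random.default_rng(0)
        series = np.concatenate([np.zeros(200), np.linspace(0, 500, 100), np.full(100, 500.0)])
        series = series + rng.normal(0, 0.1, series.size)
        start, end = find_fit_window(series, fs=62.0)
        assert end - start + 1 == 62

    def test_step_locates_end_at_step_sample(self):
        series = np.zeros(300)
        series[150:] = 100.0  # step lands at sample 150
        start, end = find_fit_window(series, fs=62.0, mode="raw")
        assert end == 150
        assert start == 150 - 62 + 1

    def test_early_maximum_is_flagged(self):
        series = np.zeros(200)
        series[10:] = 100.0
        with pytest.raises(WindowError):
            find_fit_window(series, fs=62.0, mode="raw")

    def test_window_ends_during_descent_on_simulated_trial(self, noiseless_counts):
        """Cross-check against ground truth: the steepest count rise happens
        before the clothing compression settles."""
        s = average_channels(noiseless_counts)
        start, end = find_fit_window(s, noiseless_counts.fs)
        t_end = noiseless_counts.t[end]
        p = MotionProfile()
        assert p.approach_start < t_end <= p.contact_time + 0.2

    def test_non_62_rate_generalises_by_duration(self):
        series = np.concatenate([np.zeros(250), np.linspace(0, 500, 50), np.full(50, 500.0)])
        start, end = find_fit_window(series, fs=100.0, mode="raw")
        assert end - start + 1 == 100


def _model(t, alpha, beta, gamma):
    return np.exp(alpha * (t - beta)) + gamma


class TestFitExponential:
    def test_noiseless_recovery(self):
        """Exact model data recover (alpha, beta, gamma) to 1e-6 relative."""
        t = np.arange(62) / 62.0
        fit = fit_exponential(_model(t, 0.5, 1.0, 100.0), t)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.5, rel=1e-6)
        assert fit.beta == pytest.approx(1.0, rel=1e-6)
        assert fit.gamma == pytest.approx(100.0, rel=1e-6)

    def test_noisy_recovery_median_within_5_percent(self):
        """Monte-Carlo calibration: noise sd 1 count over 50 seeds, window
        placed on the visible rise of the exponential."""
        t = 12.0 + np.arange(62) / 62.0
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            c = _model(t, 0.5, 1.0, 100.0) + rng.normal(0.0, 1.0, t.size)
            fit = fit_exponential(c, t, seed=seed)
            errs.append(abs(fit.alpha - 0.5) / 0.5)
        assert float(np.median(errs)) < 0.05

    def test_constant_window_degenerate(self):
        t = np.arange(62) / 62.0
        fit = fit_exponential(np.full(62, 10.0), t)
        assert not fit.converged and fit.alpha is None

    def test_additive_constant_shifts_gamma_only(self):
        t = np.arange(62) / 62.0
        c = _model(t, 0.8, 0.3, 50.0)
        f0 = fit_exponential(c, t)
        f1 = fit_exponential(c + 25.0, t)
        assert f1.alpha == pytest.approx(f0.alpha, rel=1e-8)
        assert f1.gamma == pytest.approx(f0.gamma + 25.0, rel=1e-8)

    def test_time_shift_moves_beta_only(self):
        t = np.arange(62) / 62.0
        c = _model(t, 0.8, 0.3, 50.0)
        f0 = fit_exponential(c, t)
        f1 = fit_exponential(c, t + 7.5)
        assert f1.alpha == pytest.approx(f0.alpha, rel=1e-8)
        assert f1.beta == pytest.approx(f0.beta + 7.5, rel=1e-8)
        assert f1.gamma == pytest.approx(f0.gamma, rel=1e-8)

    def test_objective_matches_grid_search_oracle(self):
        """On a small window the solver's minimum matches an independent
        dense 3-D grid search over (alpha, amplitude, gamma)."""
        t = np.arange(20) / 20.0
        rng = np.random.default_rng(3)
        c = _model(t, 1.2, -0.8, 30.0) + rng.normal(0.0, 0.5, t.size)
        fit = fit_exponential(c, t, seed=0)
        solver_obj = fit.residual_ss

        u = t - t[0]
        alphas = np.linspace(0.2, 3.0, 57)
        best = np.inf
        for a in alphas:
            basis = np.exp(a * u)
            # profile out (amplitude, gamma) by linear least squares on the grid
            X = np.column_stack([basis, np.ones_like(u)])
            coef, *_ = np.linalg.lstsq(X, c, rcond=None)
            if coef[0] <= 0:
                continue
            r = X @ coef - c
            best = min(best, float(r @ r))
        # solver must be at least as good as the alpha-grid oracle, and the
        # oracle must come within its own grid resolution of the solver
        assert solver_obj <= best + 1e-9
        assert best - solver_obj < 0.05 * max(solver_obj, 1e-6)


class TestVelocityCoefficient:
    def test_deterministic_on_identical_trials(self, noiseless_counts):
        f1 = velocity_coefficient(noiseless_counts)
        f2 = velocity_coefficient(noiseless_counts)
        assert f1.alpha == f2.alpha

    def test_monotone_in_descent_velocity(self, layout, noiseless_tp):
        alphas = []
        for v in (10.0, 30.0, 50.0, 70.0, 90.0):
            c = simulate_counts(
                MotionProfile(descent_velocity=v), layout, trans_params=noiseless_tp
            )
            alphas.append(velocity_coefficient(c).alpha)
        assert np.all(np.diff(alphas) > 0)

    def test_flagged_window_raises_structured_error(self):
        m = np.full((400, 20), 100.0)
        m[5:, 0] = 500.0  # step right at the start: window cannot be placed
        with pytest.raises(WindowError):
            velocity_coefficient(make_counts(m), channels=(1,), mode="raw")

    def test_degenerate_trial_raises_fit_error(self):
        rng = np.random.default_rng(1)
        m = np.full((400, 20), 100.0) + rng.normal(0, 0.01, (400, 20))
        with pytest.raises(FitError) as excinfo:
            velocity_coefficient(make_counts(m))
        assert excinfo.value.fit is not None
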