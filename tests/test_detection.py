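"""Detection statistics on synthetic trace ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from nanostim import detection as det
from nanostim.oracles import discrete_detection_oracle
from nanostim.params import ParameterError


def _gaussian_traces(n_trials, n_samples, rng, mean=0.0, sd=1.0, rho=0.0):
    """Trace ensemble with optional AR(1) temporal correlation."""
    eps = rng.normal(size=(n_trials, n_samples))
    if rho > 0:
        for j in range(1, n_samples):
            eps[:, j] = rho * eps[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j]
    return mean + sd * eps


T_GRID = np.arange(-50.0, 650.0, 1.0)
WINDOW = (0.0, 600.0)


class TestDetect:
    def test_constant_trace_below_a_lower_boundary_triggers(self):
        tr = np.full(T_GRID.size, -5.0)
        assert det.detect(tr, T_GRID, threshold=-1.0, boundary=det.LOWER,
                          window=WINDOW)

    def test_infinite_thresholds_are_certain_or_impossible(self):
        rng = np.random.default_rng(0)
        tr = rng.normal(size=T_GRID.size)
        assert det.detect(tr, T_GRID, np.inf, det.LOWER, WINDOW)
        assert not det.detect(tr, T_GRID, np.inf, det.UPPER, WINDOW)

    def test_fixture_straddles_the_threshold(self):
        # catch trace stays above the boundary, stimulus trace dips below
        catch = np.zeros(T_GRID.size)
        stim = np.zeros(T_GRID.size)
        stim[300] = -2.0
        theta = -1.0
        assert det.detect(stim, T_GRID, theta, det.LOWER, WINDOW)
        assert not det.detect(catch, T_GRID, theta, det.LOWER, WINDOW)

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            det.detect(np.zeros(T_GRID.size), T_GRID, 0.0, det.LOWER,
                       window=(700.0, 800.0))


class TestCalibration:
    def test_extreme_targets(self):
        rng = np.random.default_rng(1)
        tr = _gaussian_traces(200, T_GRID.size, rng)
        ext = det.trial_extrema(tr, T_GRID, det.UPPER, WINDOW)
        theta_all = det.calibrate_threshold(tr, T_GRID, det.UPPER,
                                            target_fp=1.0, window=WINDOW)
        assert theta_all <= ext.min()

    def test_gaussian_order_statistics_oracle(self):
        """For i.i.d. Gaussian samples the calibrated boundary matches the
        analytic quantile of the per-trial extremum distribution."""
        rng = np.random.default_rng(2)
        n_samples = int(WINDOW[1] - WINDOW[0] - 1)
        tr = _gaussian_traces(6000, T_GRID.size, rng)
        theta = det.calibrate_threshold(tr, T_GRID, det.UPPER,
                                        target_fp=0.25, window=WINDOW)
        # P(max > theta) = 1 - Phi(theta)^m = 0.25
        expected = norm.ppf(0.75 ** (1.0 / n_samples))
        assert theta == pytest.approx(expected, abs=0.05)

    def test_held_out_false_positive_rate_hits_the_target(self):
        """FP(theta) = 0.25 +- 0.01 on held-out catch trials."""
        rng = np.random.default_rng(3)
        tr = _gaussian_traces(40_000, 300, rng, rho=0.9)
        grid = np.arange(-50.0, 250.0)
        calib, hold = tr[:20_000], tr[20_000:]
        theta = det.calibrate_threshold(calib, grid, det.UPPER, 0.25,
                                        window=(0.0, 249.0))
        fp = det.crossing_fraction(hold, grid, theta, det.UPPER,
                                   window=(0.0, 249.0))
        assert fp == pytest.approx(0.25, abs=0.01)

    def test_invalid_target_rejected(self):
        rng = np.random.default_rng(4)
        tr = _gaussian_traces(50, T_GRID.size, rng)
        with pytest.raises(ParameterError):
            det.calibrate_threshold(tr, T_GRID, det.UPPER, 1.7)


class TestEffectSize:
    def test_null_case_is_zero_within_ci(self):
        rng = np.random.default_rng(5)
        catch = _gaussian_traces(400, T_GRID.size, rng, rho=0.8)
        stim = _gaussian_traces(400, T_GRID.size, rng, rho=0.8)
        res = det.effect_size(stim, catch, T_GRID, det.UPPER, "dr")
        assert abs(res.effect_size) <= 3.0 * res.ci_halfwidth + 0.02

    def test_large_shift_saturates_at_one_minus_fp(self):
        rng = np.random.default_rng(6)
        catch = _gaussian_traces(400, T_GRID.size, rng)
        stim = _gaussian_traces(400, T_GRID.size, rng, mean=+15.0)
        res = det.effect_size(stim, catch, T_GRID, det.UPPER, "dr")
        assert res.cd == 1.0
        assert res.effect_size == pytest.approx(0.75, abs=0.08)

    def test_boundary_direction_matters(self):
        rng = np.random.default_rng(7)
        catch = _gaussian_traces(400, T_GRID.size, rng)
        stim = _gaussian_traces(400, T_GRID.size, rng, mean=-15.0)
        res = det.effect_size(stim, catch, T_GRID, det.LOWER, "ir")
        assert res.effect_size == pytest.approx(0.75, abs=0.08)


class TestMonotonicity:
    def test_crossing_rates_are_monotone_in_the_threshold(self):
        rng = np.random.default_rng(8)
        tr = _gaussian_traces(300, T_GRID.size, rng, rho=0.5)
        thetas = np.linspace(-3, 5, 25)
        fp_up = [det.crossing_fraction(tr, T_GRID, th, det.UPPER, WINDOW)
                 for th in thetas]
        fp_lo = [det.crossing_fraction(tr, T_GRID, th, det.LOWER, WINDOW)
                 for th in thetas]
        assert np.all(np.diff(fp_up) <= 1e-12)
        assert np.all(np.diff(fp_lo) >= -1e-12)


class TestStandardizedStats:
    def test_catch_versus_catch_is_flat_zero(self):
        rng = np.random.default_rng(9)
        a = _gaussian_traces(3000, T_GRID.size, rng)
        b = _gaussian_traces(3000, T_GRID.size, rng)
        st_ = det.standardized_stats(a, b, T_GRID)
        assert np.abs(st_.mu_hat).max() < 0.12
        assert np.abs(st_.sigma_hat).max() < 0.12

    def test_known_mean_shift_reads_one(self):
        rng = np.random.default_rng(10)
        catch = _gaussian_traces(4000, T_GRID.size, rng, sd=2.0)
        stim = _gaussian_traces(4000, T_GRID.size, rng, sd=2.0)
        m = (T_GRID >= 100) & (T_GRID < 300)
        stim[:, m] += 2.0  # +1 catch-SD
        st_ = det.standardized_stats(stim, catch, T_GRID)
        assert st_.mu_hat[m].mean() == pytest.approx(1.0, abs=0.08)
        assert np.abs(st_.mu_hat[~m & (T_GRID > 0)]).max() < 0.15

    def test_known_sd_inflation_reads_half(self):
        rng = np.random.default_rng(11)
        catch = _gaussian_traces(4000, T_GRID.size, rng)
        stim = _gaussian_traces(4000, T_GRID.size, rng)
        m = (T_GRID >= 100) & (T_GRID < 300)
        stim[:, m] *= 1.5
        st_ = det.standardized_stats(stim, catch, T_GRID)
        assert st_.sigma_hat[m].mean() == pytest.approx(0.5, abs=0.08)


class TestSimplifiedModel:
    def test_no_perturbation_gives_zero_effect(self):
        exact, approx = det.simplified_effect_size(0.9, [0.0, 0.0], 4)
        assert exact == 0.0
        assert approx == 0.0

    def test_single_feature_worked_example(self):
        p0 = 0.75 ** 0.25
        exact, _ = det.simplified_effect_size(p0, [-0.1 * p0], 4)
        assert exact == pytest.approx(0.075, abs=1e-12)

    def test_false_positive_rate_inversion(self):
        p0 = 0.75 ** 0.25
        assert det.false_positive_rate_simplified(p0, 4) == \
            pytest.approx(0.25, abs=1e-12)

    def test_two_feature_additivity_error_term(self):
        p0, d1, d2, n = 0.92, -0.05, +0.03, 4
        exact, additive = det.simplified_effect_size(p0, [d1, d2], n)
        assert abs(exact - additive) == pytest.approx(
            p0 ** (n - 2) * abs(d1 * d2), abs=1e-12)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ParameterError):
            det.simplified_effect_size(1.2, [0.0], 4)
        with pytest.raises(ParameterError):
            det.simplified_effect_size(0.5, [0.6], 4)

    @pytest.mark.parametrize("n,dp", [(2, -0.05), (4, -0.1), (8, 0.03)])
    def test_matches_bernoulli_monte_carlo(self, n, dp):
        p0 = 0.75 ** (1.0 / n)
        exact, _ = det.simplified_effect_size(p0, [dp], n)
        n_mc = 200_000
        fp, cd, y = discrete_detection_oracle(p0, [dp], n, n_mc,
                                              seed=n * 13 + 1)
        se = np.sqrt(2 * 0.25 * 0.75 / n_mc)
        assert abs(fp - (1 - p0**n)) < 3 * se
        assert abs(y - exact) < 3 * se


@settings(max_examples=60, deadline=None)
@given(p0=st.floats(0.5, 0.999), n=st.integers(2, 10),
       f1=st.floats(-0.4, 0.4), f2=st.floats(-0.4, 0.4))
def test_additivity_bound_holds_identically(p0, n, f1, f2):
    """|Y12 - Y1 - Y2| equals p0^(n-2) |dp1 dp2| for admissible perturbations."""
    d1 = f1 * min(p0, 1 - p0)
    d2 = f2 * min(p0, 1 - p0)
    exact, additive = det.simplified_effect_size(p0, [d1, d2], n)
    assert abs(exact - additive) <= p0 ** (n - 2) * abs(d1 * d2) + 1e-12
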