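"""Response-curve family: shapes, likelihood, fitting, outer border."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime

from uelshift import hof


def _random_params(model_type, rng):
    names = hof.PARAM_NAMES[model_type]
    out = []
    for n in names:
        lo, hi = hof.BOUNDS[n]
        if n in ("b", "d"):
            hi = 50.0  # keep exponentials informative for gradient checks
        out.append(rng.uniform(lo if n not in ("a", "c") else -10.0,
                               hi if n not in ("a", "c") else 10.0))
    return np.array(out)


class TestResponseShapes:
    def test_flat_model_is_half_at_a_zero(self):
        fit = hof.HOFFit(1, np.array([0.0]), (0.0, 1.0), 0, 1, 0, 0.5)
        x = np.linspace(0, 1, 7)
        assert np.allclose(hof.response(fit, x), 0.5)

    def test_monotone_decreasing_sigmoid(self):
        fit = hof.HOFFit(2, np.array([-3.0, 8.0]), (0.0, 1.0), 0, 2, 0, 1.0)
        y = hof.response(fit, np.linspace(0, 1, 50))
        assert np.all(np.diff(y) < 0)

    def test_symmetric_hump_peaks_at_analytic_optimum(self):
        # model IV: dy/du = 0 at u* = (c - a) / (2b)
        a, b, c = -4.0, 10.0, 2.0
        fit = hof.HOFFit(4, np.array([a, b, c]), (0.0, 1.0), 0, 3, 0, 1.0)
        u = np.linspace(0, 1, 20001)
        y = hof.response(fit, u)
        assert u[np.argmax(y)] == pytest.approx((c - a) / (2 * b), abs=1e-3)

    def test_equal_shape_params_peak_at_zero(self):
        a = c = 1.5
        u = np.linspace(-0.5, 0.5, 20001)
        y, _ = hof._response_raw(4, np.array([a, 6.0, c]), u)
        assert u[np.argmax(y)] == pytest.approx(0.0, abs=1e-3)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 7), st.integers(0, 2**31 - 1))
    def test_response_bounded_in_unit_interval(self, model_type, seed):
        rng = np.random.default_rng(seed)
        params = _random_params(model_type, rng)
        y, _ = hof._response_raw(model_type, params, np.linspace(0, 1, 101))
        assert np.all(y >= 0.0) and np.all(y <= 1.0)

    @pytest.mark.parametrize("model_type", [2, 3, 4, 5, 6, 7])
    def test_analytic_gradient_matches_numerical(self, model_type):
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 1, 40)
        y_obs = rng.integers(0, 2, 40).astype(float)
        for _ in range(5):
            params = _random_params(model_type, rng)
            _, grad = hof._nll_and_grad(params, model_type, u, y_obs)
            num = approx_fprime(params,
                               lambda p: hof._nll_and_grad(p, model_type, u, y_obs)[0],
                               1e-7)
            assert np.allclose(grad, num, rtol=1e-3, atol=1e-3)


class TestLikelihood:
    def test_flat_half_equals_n_log_two(self):
        n = 37
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, n).astype(float)
        nll = hof.negloglik(1, [0.0], np.linspace(0, 1, n), y)
        assert nll == pytest.approx(n * np.log(2.0))

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(0, 1, 60)
        y_obs = rng.integers(0, 2, 60).astype(float)
        for model_type in range(1, 8):
            for _ in range(20):
                params = _random_params(model_type, rng)
                p, _ = hof._response_raw(model_type, params, u)
                p = np.clip(p, 1e-9, 1 - 1e-9)
                brute = -sum(yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                             for yi, pi in zip(y_obs, p))
                assert hof.negloglik(model_type, params, u, y_obs) == pytest.approx(
                    brute, abs=1e-10)

    def test_perfect_separation_drives_probs_to_bounds(self):
        # separable data: the fitted sigmoid saturates within the steepness
        # bound and the likelihood approaches its supremum of 1
        elev = np.linspace(0, 1, 100)
        y = (elev < 0.5).astype(int)
        fit = hof.fit_model(2, elev, y, seed=0)
        assert hof.response(fit, 0.0) > 0.999
        assert hof.response(fit, 1.0) < 0.001
        assert -fit.logL < 1.5


class TestFitting:
    def test_recovers_decreasing_sigmoid_inflection(self):
        # data simulated from model II (a=-6, b=12): inflection at u = 0.5
        rng = np.random.default_rng(1)
        elev = np.sort(rng.uniform(2000, 3000, 400))
        u = (elev - 2000) / 1000
        p = 1 / (1 + np.exp(-6 + 12 * u))
        y = (rng.uniform(size=400) < p).astype(int)
        fit = hof.fit_model(2, elev, y, seed=2)
        a, b = fit.params
        inflection = 2000 + (-a / b) * 1000
        assert abs(inflection - 2500) < 0.05 * 1000

    def test_all_presences_flat_plateau_flagged(self):
        elev = np.linspace(1000, 2000, 50)
        fit = hof.fit_model(1, elev, np.ones(50), seed=0)
        assert "all_presences" in fit.flags
        assert hof.response(fit, 1500.0) > 0.999

    def test_refit_same_seed_identical(self, step_series):
        elev, y = step_series
        f1 = hof.fit_model(5, elev, y, seed=9)
        f2 = hof.fit_model(5, elev, y, seed=9)
        assert np.array_equal(f1.params, f2.params)
        assert f1.aic == f2.aic

    def test_too_few_presences_unfittable(self):
        elev = np.linspace(0, 1, 20)
        y = np.zeros(20, dtype=int)
        y[:3] = 1
        with pytest.raises(hof.UnfittableSeries):
            hof.fit_model(2, elev, y, seed=0)

    def test_aic_identity(self, step_series):
        elev, y = step_series
        for t in range(1, 8):
            fit = hof.fit_model(t, elev, y, seed=1)
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.logL)
            assert fit.k == hof.N_PARAMS[t]


class TestSelection:
    def test_step_data_selects_decreasing_family(self, step_series):
        elev, y = step_series
        fit = hof.select_model(elev, y, seed=3)
        assert fit.aic == min(
            hof.fit_model(t, elev, y, seed=3 + t).aic for t in range(1, 8))

    def test_pure_noise_mostly_selects_flat(self):
        # under i.i.d. coin-flip data the AIC penalty keeps the flat model:
        # each richer type beats it only via a chance chi-square excess
        # (P(chi2_1 > 2) = 0.16 for type II, less for the others), so the
        # correlated family-wise false-selection rate is ~25%
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            rng = np.random.default_rng(1000 + seed)
            elev = np.linspace(1900, 3600, 80)
            y = rng.integers(0, 2, 80)
            if y.sum() < 5 or y.sum() > 75:
                hits += 1  # degenerate draw; flat is the only honest answer
                continue
            fit = hof.select_model(elev, y, seed=seed)
            hits += int(fit.model_type == 1)
        assert hits / n_trials >= 0.70


class TestOuterBorder:
    def test_relative_level_is_exp_minus_two(self, step_series):
        elev, y = step_series
        for t in (2, 4, 5):
            fit = hof.fit_model(t, elev, y, seed=5)
            ob, censored = hof.outer_border(fit)
            if censored:
                continue
            ratio = hof.response(fit, ob) / fit.y_max
            assert ratio == pytest.approx(np.exp(-2.0), abs=1e-3)

    def test_model_ii_matches_closed_form_inversion(self):
        # y = 1/(1+e^(a+bu)) falls to exp(-2)*y_max at a known u
        a, b = -6.0, 12.0
        fit = hof.HOFFit(2, np.array([a, b]), (2000.0, 3000.0), 0, 2, 0,
                         y_max=1 / (1 + np.exp(a)))
        thr = np.exp(-2.0) * fit.y_max
        u_star = (np.log(1.0 / thr - 1.0) - a) / b
        ob, censored = hof.outer_border(fit)
        assert not censored
        assert ob == pytest.approx(2000 + 1000 * u_star, abs=0.2)

    def test_flat_model_censored_at_top(self):
        fit = hof.HOFFit(1, np.array([0.0]), (1900.0, 3600.0), 0, 1, 0, 0.5)
        ob, censored = hof.outer_border(fit)
        assert censored and ob == 3600.0

    def test_degenerate_fit_rejected(self):
        fit = hof.HOFFit(1, np.array([25.0]), (0.0, 1.0), 0, 1, 0, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            hof.outer_border(fit)

    def test_removing_low_absences_never_lowers_border(self, step_series):
        elev, y = step_series
        fit_full = hof.select_model(elev, y, seed=6)
        ob_full, _ = hof.outer_border(fit_full)
        keep = ~((y == 0) & (elev < elev[y == 1].min()))
        fit_thin = hof.select_model(elev[keep], y[keep], seed=6)
        ob_thin, _ = hof.outer_border(fit_thin)
        assert ob_thin >= ob_full - 1.0
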