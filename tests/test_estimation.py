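"""Objective construction, DE fitting, and the closed-form VAR(1) check."""

import math

import numpy as np
import pytest

from esmdyn import (
    DeConfig,
    EsmSeries,
    NoiseParams,
    OuParams,
    StationaryParams,
    build_transition_plan,
    fit_mle,
    gaussian_nll,
    GaussianPrediction,
    ou_conditional,
    ou_to_var,
    param_count,
    series_nll,
    var_closed_form,
)
from esmdyn.estimation import _fast_ou_nll, _fast_ou_nll_pop, _prepare
from conftest import make_series, random_stable_ou


def _sim_equal_spaced(ou, n, rng, dt=1.0):
    """Exact OU draw on an equally spaced single-day grid."""
    from esmdyn import ou_stationary

    stat = ou_stationary(ou)
    chol = np.linalg.cholesky(stat.cov)
    x = np.empty((n, ou.d))
    x[0] = stat.mu + chol @ rng.standard_normal(ou.d)
    for i in range(1, n):
        pred = ou_conditional(ou, x[i - 1], dt)
        ew, ev = np.linalg.eigh(pred.cov)
        x[i] = pred.mean + (ev * np.sqrt(np.maximum(ew, 0))) @ rng.standard_normal(ou.d)
    return make_series(np.arange(n) * dt, [0] * n, x)


class TestSeriesNll:
    def test_stationary_family_is_iid_sum(self, rng):
        x = rng.normal(size=(6, 2))
        s = make_series(10 + np.arange(6.0), [0] * 6, x)
        plan = build_transition_plan(s)
        p = StationaryParams([0.0, 0.0], np.eye(2))
        expected = sum(
            gaussian_nll(xi, GaussianPrediction(p.mu, p.cov)) for xi in x
        )
        assert series_nll("stationary", p, s, plan) == pytest.approx(expected, abs=1e-10)

    def test_single_day_term_by_term_oracle(self, rng):
        from esmdyn import ou_stationary

        ou = random_stable_ou(rng)
        t = np.array([10.0, 11.4, 13.0])
        x = rng.normal(size=(3, 2)) + ou.mu
        s = make_series(t, [0, 0, 0], x)
        plan = build_transition_plan(s)
        stat = ou_stationary(ou)
        expected = gaussian_nll(x[0], GaussianPrediction(stat.mu, stat.cov))
        expected += gaussian_nll(x[1], ou_conditional(ou, x[0], 1.4))
        expected += gaussian_nll(x[2], ou_conditional(ou, x[1], 1.6))
        assert series_nll("ou", ou, s, plan) == pytest.approx(expected, abs=1e-10)

    def test_additive_over_independent_series(self, rng):
        ou = random_stable_ou(rng)
        s1 = _sim_equal_spaced(ou, 10, rng)
        s2 = _sim_equal_spaced(ou, 12, rng)
        p1, p2 = build_transition_plan(s1), build_transition_plan(s2)
        total = series_nll("ou", ou, [s1, s2], [p1, p2])
        assert total == pytest.approx(
            series_nll("ou", ou, s1, p1) + series_nll("ou", ou, s2, p2), abs=1e-10
        )

    def test_unstable_params_give_infinite_objective(self, rng):
        s = _sim_equal_spaced(random_stable_ou(rng), 10, rng)
        plan = build_transition_plan(s)
        bad = OuParams([0.0, 0.0], [[-1.0, 0.0], [0.0, 1.0]], np.eye(2))
        assert series_nll("ou", bad, s, plan) == math.inf

    def test_ou_equals_mapped_var_on_unit_spacing(self, rng):
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 25, rng)
        plan = build_transition_plan(s)
        var = ou_to_var(ou, 1.0)
        assert series_nll("var", var, s, plan) == pytest.approx(
            series_nll("ou", ou, s, plan), abs=1e-8
        )


class TestFastObjective:
    def test_matches_reference_path(self, rng):
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 30, rng, dt=0.9)
        plan = build_transition_plan(s)
        prep = _prepare(s, plan, "continuous")
        for _ in range(10):
            cand = random_stable_ou(rng)
            ref = series_nll("ou", cand, s, plan)
            fast = _fast_ou_nll(cand.mu, cand.theta, cand.sigma, prep)
            assert fast == pytest.approx(ref, rel=1e-10, abs=1e-8)

    def test_population_batch_matches_single(self, rng):
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 20, rng)
        plan = build_transition_plan(s)
        prep = _prepare(s, plan, "continuous")
        from esmdyn.estimation import _encode_bounds

        lo, hi = _encode_bounds(prep, False)
        pop = rng.uniform(lo, hi, size=(30, lo.size))
        batch = _fast_ou_nll_pop(pop, prep)
        for row, val in zip(pop, batch):
            mu = row[:2]
            theta = row[2:6].reshape(2, 2)
            sigma = np.array([[row[6], 0.0], [row[7], row[8]]])
            single = _fast_ou_nll(mu, theta, sigma, prep)
            if math.isinf(single):
                assert math.isinf(val)
            else:
                assert val == pytest.approx(single, rel=1e-9)


class TestFitMle:
    def test_reproducible_under_fixed_seed(self, rng):
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 40, rng)
        plan = build_transition_plan(s)
        de = DeConfig.reduced(seed=5, iterations=15, polish=0)
        f1 = fit_mle("ou", s, plan, de=de)
        f2 = fit_mle("ou", s, plan, de=de)
        np.testing.assert_array_equal(f1.raw_x, f2.raw_x)
        assert f1.train_nll == f2.train_nll

    def test_univariate_parameter_recovery(self):
        rng = np.random.default_rng(42)
        ou = OuParams([50.0], [[1.0]], [[5.0]])
        s = _sim_equal_spaced(ou, 1000, rng)
        plan = build_transition_plan(s)
        fit = fit_mle("ou", s, plan, de=DeConfig.reduced(seed=2, iterations=60))
        assert fit.params.theta[0, 0] == pytest.approx(1.0, rel=0.2)
        assert fit.params.mu[0] == pytest.approx(50.0, abs=0.5)

    def test_fit_no_worse_than_truth(self, rng):
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 60, rng, dt=0.8)
        plan = build_transition_plan(s)
        # a global-search budget: the optimizer must reach at least the
        # likelihood of the generating parameters
        de = DeConfig(n_pop=50, iterations=500, seed=1, polish=600)
        fit = fit_mle("ou", s, plan, de=de)
        truth_nll = series_nll("ou", ou, s, plan)
        assert fit.train_nll <= truth_nll + 1e-6

    def test_var_fit_matches_closed_form_on_transition_objective(self):
        rng = np.random.default_rng(3)
        ou = random_stable_ou(rng)
        s = _sim_equal_spaced(ou, 150, rng)
        plan = build_transition_plan(s)
        plan.stationary_items[0].retained = False  # pure regression objective
        closed = var_closed_form(s, plan)
        fit = fit_mle(
            "var", s, plan, de=DeConfig.reduced(seed=9, n_pop=20, iterations=400, polish=1500)
        )
        nll_closed = series_nll("var", closed, s, plan)
        nll_fit = series_nll("var", fit.params, s, plan)
        assert abs(nll_fit - nll_closed) < 1e-3

    def test_stationary_fit_is_sample_moments(self, rng):
        x = rng.normal(size=(30, 2)) * 3.0 + 10.0
        s = make_series(10 + np.arange(30.0), [0] * 30, x)
        plan = build_transition_plan(s)
        fit = fit_mle("stationary", s, plan)
        np.testing.assert_allclose(fit.params.mu, x.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            fit.params.cov, (x - x.mean(0)).T @ (x - x.mean(0)) / 30, atol=1e-12
        )

    def test_underdetermined_series_rejected(self, rng):
        s = make_series([10.0, 11.0], [0, 0], rng.normal(size=(2, 2)))
        plan = build_transition_plan(s)
        with pytest.raises(ValueError, match="under-determined|too few"):
            fit_mle("ou", s, plan, de=DeConfig.reduced(seed=0, iterations=5))

    def test_noise_fit_runs_and_estimates_error_variance(self):
        rng = np.random.default_rng(8)
        ou = OuParams([0.0], [[1.0]], [[2.0]])
        s = _sim_equal_spaced(ou, 120, rng)
        noisy = s.ratings + rng.standard_normal(s.ratings.shape) * 1.0
        s2 = make_series(s.timestamps, s.day_index, noisy)
        plan = build_transition_plan(s2)
        fit = fit_mle(
            "ou", s2, plan, de=DeConfig.reduced(seed=4, iterations=60), noise=True
        )
        assert fit.noise is not None
        assert fit.noise.error_var[0] > 0.05  # some noise detected
        assert np.isfinite(fit.train_nll)


class TestVarClosedForm:
    def test_noiseless_linear_map_recovered_exactly(self, rng):
        a = np.array([[0.5, 0.1], [-0.2, 0.6]])
        c = np.array([1.0, -0.5])
        x = np.empty((30, 2))
        x[0] = rng.normal(size=2)
        for i in range(1, 30):
            x[i] = c + a @ x[i - 1]
        s = make_series(np.arange(30.0), [0] * 30, x)
        plan = build_transition_plan(s)
        est = var_closed_form(s, plan)
        np.testing.assert_allclose(est.transition, a, atol=1e-9)
        np.testing.assert_allclose(est.intercept, c, atol=1e-9)
        np.testing.assert_allclose(est.innovation_cov, 0.0, atol=1e-12)

    def test_three_point_hand_ols(self):
        s = make_series(
            np.arange(4.0), [0] * 4, np.array([[0.0], [1.0], [1.5], [1.75]])
        )
        plan = build_transition_plan(s)
        est = var_closed_form(s, plan)
        assert est.transition[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert est.intercept[0] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_gives_near_zero_transition(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10_000, 1))
        s = make_series(np.arange(10_000.0), [0] * 10_000, x)
        plan = build_transition_plan(s)
        est = var_closed_form(s, plan)
        assert abs(est.transition[0, 0]) < 0.05

    def test_too_few_transitions_rejected(self, rng):
        s = make_series([0.0, 1.0, 2.0], [0] * 3, rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            var_closed_form(s, build_transition_plan(s))


def test_param_count_bookkeeping():
    assert param_count("ou", 2) == 9
    assert param_count("var", 2) == 9
    assert param_count("stationary", 2) == 5
    assert param_count("ou", 2, noise=True) == 11
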