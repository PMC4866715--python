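import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from otbiomon import (
    FittedDistribution,
    RiskInputs,
    ValidationError,
    fit_loglogistic,
    fit_pareto,
    monte_carlo_rq,
    monte_carlo_rq_from_fits,
    risk_report,
    select_distribution,
    ssd_cdf,
    ssd_curve_table,
)

from conftest import exceedance_probability_quadrature


def draw_loglogistic(alpha, beta, n, seed):
    u = np.random.default_rng(seed).random(n)
    return alpha * (u / (1 - u)) ** (1 / beta)


def draw_pareto(xm, a, n, seed):
    u = np.random.default_rng(seed).random(n)
    return xm * (1 - u) ** (-1 / a)


class TestParetoFit:
    def test_closed_form_example(self):
        fit = fit_pareto([1, 2, 4])
        assert fit.params["x_m"] == 1.0
        assert fit.params["a"] == pytest.approx(3 / math.log(8))

    def test_constant_sample_degenerate(self):
        fit = fit_pareto([3.0, 3.0, 3.0])
        assert fit.degenerate
        assert fit.params["x_m"] == 3.0
        assert math.isinf(fit.params["a"])

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            fit_pareto([-1.0, 2.0])

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            fit_pareto([2.0])

    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    @settings(derandomize=True, max_examples=40)
    def test_matches_closed_form_on_random_samples(self, seed, n):
        x = np.exp(np.random.default_rng(seed).normal(2.0, 0.7, n))
        fit = fit_pareto(x)
        xm = x.min()
        assert fit.params["x_m"] == xm
        assert fit.params["a"] == pytest.approx(n / np.log(x / xm).sum())

    def test_agrees_with_scipy_numeric_mle(self):
        x = draw_pareto(5.0, 2.5, 400, seed=7)
        fit = fit_pareto(x)
        b, loc, scale = stats.pareto.fit(x, floc=0.0, fscale=x.min())
        assert fit.params["a"] == pytest.approx(b, rel=0.02)


class TestLogLogisticFit:
    def test_parameter_recovery(self):
        x = draw_loglogistic(100.0, 2.0, 2000, seed=3)
        fit = fit_loglogistic(x)
        assert fit.params["alpha"] == pytest.approx(100.0, rel=0.05)
        assert fit.params["beta"] == pytest.approx(2.0, rel=0.10)

    def test_symmetric_log_data_alpha_is_geometric_median(self):
        x = np.exp(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        fit = fit_loglogistic(x)
        assert fit.params["alpha"] == pytest.approx(1.0, abs=1e-6)

    def test_too_few_rejected(self):
        with pytest.raises(ValidationError):
            fit_loglogistic([1.0, 2.0])

    def test_agrees_with_scipy_fisk_mle(self):
        x = draw_loglogistic(50.0, 3.0, 500, seed=11)
        fit = fit_loglogistic(x)
        c, loc, scale = stats.fisk.fit(x, floc=0.0)
        assert fit.params["alpha"] == pytest.approx(scale, rel=0.01)
        assert fit.params["beta"] == pytest.approx(c, rel=0.01)

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_recovery_error_shrinks_with_n(self, n):
        errors = []
        for seed in range(8):
            x = draw_loglogistic(100.0, 2.0, n, seed=100 + seed)
            fit = fit_loglogistic(x)
            errors.append(abs(fit.params["alpha"] / 100.0 - 1.0))
        # asymptotic SE of the location on the log scale is sqrt(3)/(beta sqrt(n))
        assert np.mean(errors) < 4.0 * math.sqrt(3.0) / (2.0 * math.sqrt(n))


class TestSelection:
    def test_clean_loglogistic_sample_selected(self):
        x = draw_loglogistic(100.0, 2.0, 500, seed=5)
        assert select_distribution(x).family == "log_logistic"

    def test_clean_pareto_sample_selected(self):
        x = draw_pareto(10.0, 1.5, 500, seed=5)
        assert select_distribution(x).family == "pareto"

    def test_minimal_set_smoke(self):
        fit = select_distribution([1.0, 3.0, 9.0])
        assert fit.family in ("log_logistic", "pareto")
        assert set(fit.candidates) == {"log_logistic", "pareto"}

    def test_candidates_retained_with_gof(self):
        fit = select_distribution(draw_loglogistic(10, 2, 100, seed=1))
        for cand in fit.candidates.values():
            assert cand.ks_distance >= 0
        assert fit.ks_distance == min(c.ks_distance for c in fit.candidates.values())


class TestCdf:
    def test_loglogistic_median_at_scale(self):
        fit = FittedDistribution("log_logistic", {"alpha": 7.0, "beta": 2.0},
                                 n_obs=0, ks_distance=0.0, log_likelihood=0.0)
        assert fit.cdf(7.0) == pytest.approx(0.5)

    def test_pareto_support_bound_and_formula(self):
        fit = FittedDistribution("pareto", {"x_m": 1.0, "a": 1.0},
                                 n_obs=0, ks_distance=0.0, log_likelihood=0.0)
        assert ssd_cdf(fit, 1.0) == 0.0
        assert ssd_cdf(fit, 2.0) == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        fit = FittedDistribution("pareto", {"x_m": 1.0, "a": 1.0},
                                 n_obs=0, ks_distance=0.0, log_likelihood=0.0)
        with pytest.raises(ValidationError):
            fit.cdf(0.0)

    def test_monotone(self):
        fit = FittedDistribution("log_logistic", {"alpha": 3.0, "beta": 1.5},
                                 n_obs=0, ks_distance=0.0, log_likelihood=0.0)
        grid = np.geomspace(0.01, 100, 50)
        assert np.all(np.diff(fit.cdf(grid)) >= 0)


def _point_mass(value):
    return FittedDistribution("pareto", {"x_m": value, "a": math.inf},
                              n_obs=3, ks_distance=1.0, log_likelihood=math.inf,
                              degenerate=True)


class TestMonteCarlo:
    def test_degenerate_ratio_below_one(self):
        res = monte_carlo_rq_from_fits(_point_mass(10.0), _point_mass(20.0),
                                       iterations=1000, repeats=3, seed=0)
        assert res.p_at_risk == 0.0
        assert res.rq_quantiles["q50"] == pytest.approx(0.5)

    def test_identical_distributions_give_half(self):
        fit = FittedDistribution("log_logistic", {"alpha": 100.0, "beta": 2.0},
                                 n_obs=6, ks_distance=0.1, log_likelihood=0.0)
        res = monte_carlo_rq_from_fits(fit, fit, iterations=10_000, repeats=10, seed=1)
        se = math.sqrt(0.25 / (10_000 * 10))
        assert res.p_at_risk == pytest.approx(0.5, abs=3 * se)

    def test_matches_quadrature_oracle(self):
        mtc = FittedDistribution("log_logistic", {"alpha": 50.0, "beta": 3.0},
                                 n_obs=10, ks_distance=0.1, log_likelihood=0.0)
        pnetc = FittedDistribution("log_logistic", {"alpha": 200.0, "beta": 2.0},
                                   n_obs=6, ks_distance=0.1, log_likelihood=0.0)
        truth = exceedance_probability_quadrature(
            "log_logistic", mtc.params, "log_logistic", pnetc.params)
        res = monte_carlo_rq_from_fits(mtc, pnetc, iterations=10_000, repeats=10, seed=2)
        se = math.sqrt(truth * (1 - truth) / (10_000 * 10))
        assert res.p_at_risk == pytest.approx(truth, abs=3 * se)

    def test_estimate_tightens_with_iterations(self):
        mtc = FittedDistribution("log_logistic", {"alpha": 80.0, "beta": 2.0},
                                 n_obs=10, ks_distance=0.1, log_likelihood=0.0)
        pnetc = FittedDistribution("pareto", {"x_m": 60.0, "a": 1.5},
                                   n_obs=6, ks_distance=0.1, log_likelihood=0.0)
        truth = exceedance_probability_quadrature(
            "log_logistic", mtc.params, "pareto", pnetc.params)
        for iters in (1000, 100_000):
            res = monte_carlo_rq_from_fits(mtc, pnetc, iterations=iters,
                                           repeats=3, seed=4)
            se = math.sqrt(truth * (1 - truth) / (iters * 3))
            assert res.p_at_risk == pytest.approx(truth, abs=4 * se)

    def test_repeat_sd_scales_inverse_sqrt_iterations(self):
        fit_a = FittedDistribution("log_logistic", {"alpha": 100.0, "beta": 2.0},
                                   n_obs=10, ks_distance=0.1, log_likelihood=0.0)
        fit_b = FittedDistribution("log_logistic", {"alpha": 150.0, "beta": 2.0},
                                   n_obs=6, ks_distance=0.1, log_likelihood=0.0)
        sd_small = monte_carlo_rq_from_fits(fit_a, fit_b, iterations=1000,
                                            repeats=30, seed=5).sd_over_repeats
        sd_large = monte_carlo_rq_from_fits(fit_a, fit_b, iterations=16_000,
                                            repeats=30, seed=6).sd_over_repeats
        ratio = sd_small / sd_large  # expected sqrt(16) = 4
        assert 2.0 < ratio < 8.0

    def test_seed_determinism(self):
        x = draw_loglogistic(100, 2, 12, seed=9)
        inputs = RiskInputs(mtc_values=x, pnetc_values=draw_loglogistic(300, 2, 6, seed=10))
        a = monte_carlo_rq(inputs, iterations=2000, repeats=5, seed=42)
        b = monte_carlo_rq(inputs, iterations=2000, repeats=5, seed=42)
        assert a.p_at_risk == b.p_at_risk
        assert a.repeat_values == b.repeat_values
        assert a.rq_quantiles == b.rq_quantiles

    def test_unit_rescaling_invariance(self):
        mtc = draw_loglogistic(100, 2, 15, seed=13)
        pnetc = draw_loglogistic(250, 1.5, 6, seed=14)
        base = monte_carlo_rq(RiskInputs(mtc, pnetc), iterations=5000,
                              repeats=5, seed=7)
        scaled = monte_carlo_rq(RiskInputs(mtc * 1000, pnetc * 1000),
                                iterations=5000, repeats=5, seed=7)
        assert scaled.p_at_risk == pytest.approx(base.p_at_risk, abs=1e-9)

    def test_bad_iterations(self):
        with pytest.raises(ValidationError):
            monte_carlo_rq_from_fits(_point_mass(1), _point_mass(2), iterations=0)


class TestRiskReport:
    def test_severe_site_counts(self):
        pnetc = [100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0]
        low_mtc = [10.0, 20.0, 30.0, 40.0, 50.0]
        report = risk_report(bt_inputs=RiskInputs(low_mtc, pnetc),
                             iterations=1000, repeats=3, seed=0)
        assert report["groups"]["BT"]["severely_impacted_sites"] == 0

    def test_all_sites_above_endpoints_high_risk(self):
        pnetc = draw_loglogistic(100, 3, 6, seed=20)
        mtc = draw_loglogistic(100, 3, 12, seed=21) * (pnetc.max() / 10)
        report = risk_report(pt_inputs=RiskInputs(mtc * 100, pnetc),
                             iterations=5000, repeats=5, seed=1)
        pt = report["groups"]["PT"]
        assert pt["severely_impacted_sites"] == 12
        assert pt["p_at_risk"] > 0.5

    def test_report_determinism(self):
        inputs = RiskInputs(draw_loglogistic(500, 2, 10, seed=30),
                            draw_loglogistic(300, 2, 6, seed=31))
        a = risk_report(bt_inputs=inputs, iterations=2000, repeats=4, seed=9)
        b = risk_report(bt_inputs=inputs, iterations=2000, repeats=4, seed=9)
        assert a == b

    def test_requires_some_inputs(self):
        with pytest.raises(ValidationError):
            risk_report()


def test_ssd_curve_table_brackets_sample():
    x = draw_loglogistic(100, 2, 50, seed=40)
    fit = select_distribution(x)
    table = ssd_curve_table(x, fit, n_grid=50)
    assert table["empirical_cdf"].iloc[0] == 0.0
    assert table["empirical_cdf"].iloc[-1] == 1.0
    assert ((table["fitted_cdf"] >= 0) & (table["fitted_cdf"] <= 1)).all()
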