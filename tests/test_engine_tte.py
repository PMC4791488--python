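"""Weibull time-to-event family: simulation, likelihood, fits, statistics."""

import numpy as np
import pytest
from scipy import stats

import ncpower as ncp
from ncpower import nlmem
from ncpower.families import tte


class TestSimulation:
    def test_censoring_fraction_matches_survivor_function(self, tte_preset):
        """Among untreated subjects the censoring probability is
        S(T) = exp(-(theta1 T)^gamma) = exp(-4)."""
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design.with_n_subjects(100_000), 123)
        z0 = data.z == 0
        frac_cens = np.mean(~data.event[z0])
        expected = np.exp(-4.0)
        se = np.sqrt(expected * (1 - expected) / z0.sum())
        assert abs(frac_cens - expected) < 3 * se

    def test_event_times_respect_censor_time(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design, 5)
        assert np.all(data.y <= design.censor_time)
        assert np.all((data.y == design.censor_time) == ~data.event)

    def test_covariate_split_is_exactly_half(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design, 5)
        assert data.z.sum() == design.n_subjects // 2

    def test_reproducible_from_seed(self, tte_preset):
        model, design = tte_preset
        a = ncp.simulate_dataset(model, design, 17)
        b = ncp.simulate_dataset(model, design, 17)
        assert np.array_equal(a.y, b.y)


class TestLoglik:
    def test_hand_computed_single_subject(self):
        # event at y=1, z=0, theta1=0.2, gamma=2:
        # log(lam*g*(lam*y)^(g-1)) - (lam*y)^2 = log(0.08) - 0.04
        val = tte.loglik((0.2, 2.0, 0.0), np.array([0.0]), np.array([1.0]), np.array([True]))
        assert val == pytest.approx(np.log(0.08) - 0.04, abs=1e-12)
        assert val == pytest.approx(-2.5657, abs=1e-4)

    def test_restricted_never_beats_full(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design, 9)
        full = ncp.fit_model(model, data, restricted=False)
        red = ncp.fit_model(model, data, restricted=True)
        assert red.loglik <= full.loglik + 1e-8

    def test_fit_maximum_beats_nearby_points(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design, 21)
        fit = ncp.fit_model(model, data, restricted=False)
        ll_hat = ncp.loglik(model, fit.theta_hat, data)
        assert ll_hat == pytest.approx(fit.loglik, abs=1e-8)
        for shift in ([0.01, 0, 0], [0, 0.05, 0], [0, 0, 0.05]):
            assert ncp.loglik(model, fit.theta_hat + shift, data) <= ll_hat + 1e-10


def _numeric_se(model, data, fit):
    """SEs from the numerically differentiated observed information."""
    theta = fit.theta_hat
    n = theta.size
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    H = np.empty((n, n))
    f = lambda p: ncp.loglik(model, p, data)
    f0 = f(theta)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        for j in range(i, n):
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return np.sqrt(np.diag(np.linalg.inv(-H)))


class TestParameterRecovery:
    def test_recovery_at_n2000(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design.with_n_subjects(2000), 31)
        fit = ncp.fit_model(model, data, restricted=False)
        assert fit.converged
        se = _numeric_se(model, data, fit)
        truth = np.array([0.2, 2.0, 0.4])
        assert np.all(np.abs(fit.theta_hat - truth) < 3 * se)


class TestStatistics:
    def test_llr_arithmetic(self):
        full = nlmem.FitResult(np.zeros(3), -100.0, False, True, 5, "x")
        red = nlmem.FitResult(np.zeros(3), -103.0, True, True, 5, "x")
        assert nlmem.llr_statistic(full, red) == pytest.approx(6.0)
        red_same = nlmem.FitResult(np.zeros(3), -100.0, True, True, 5, "x")
        assert nlmem.llr_statistic(full, red_same) == 0.0

    def test_llr_clamps_only_tiny_negatives(self):
        full = nlmem.FitResult(np.zeros(3), -100.0, False, True, 5, "x")
        barely = nlmem.FitResult(np.zeros(3), -100.0 + 2e-7, True, True, 5, "x")
        assert nlmem.llr_statistic(full, barely) == 0.0
        worse = nlmem.FitResult(np.zeros(3), -99.0, True, True, 5, "x")
        assert nlmem.llr_statistic(full, worse) < -1e-6

    def test_llr_rejects_mismatched_data(self):
        full = nlmem.FitResult(np.zeros(3), -100.0, False, True, 5, "a")
        red = nlmem.FitResult(np.zeros(3), -103.0, True, True, 5, "b")
        with pytest.raises(ValueError, match="different datasets"):
            nlmem.llr_statistic(full, red)

    def test_wald_agrees_with_llr_asymptotically(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design.with_n_subjects(2000), 11)
        full = ncp.fit_model(model, data, restricted=False)
        red = ncp.fit_model(model, data, restricted=True)
        llr = nlmem.llr_statistic(full, red)
        wald = ncp.wald_statistic(full, model, data, ncp.HypothesisSpec(df=1))
        assert abs(wald - llr) / llr < 0.15

    def test_wald_zero_at_null_estimate(self, tte_preset):
        model, design = tte_preset
        data = ncp.simulate_dataset(model, design, 2)
        full = ncp.fit_model(model, data, restricted=False)
        full.theta_hat[2] = 0.0  # force the tested effect to its null value
        assert ncp.wald_statistic(full, model, data, ncp.HypothesisSpec(df=1)) == 0.0


class TestBatchedEngine:
    def test_statistics_nonnegative_after_clamp(self, tte_preset):
        model, design = tte_preset
        eng = ncp.SimulationEngine(model, design)
        res = eng.statistics(200, 2000, seed=(77,))
        assert np.mean(res.values >= 0) >= 0.99
        assert res.n_failed == 0

    def test_alternative_fits_noncentral_better_than_central(self, tte_preset):
        """Under the alternative effect, the statistics prefer a noncentral
        chi-square over a central one (in log-likelihood)."""
        model, design = tte_preset
        eng = ncp.SimulationEngine(model, design)
        res = eng.statistics(200, 400, seed=(13,))
        sample = ncp.preprocess_statistics(res.values, 1)
        fit = ncp.fit_noncentrality(sample)
        ll_central = stats.chi2.logpdf(np.maximum(sample.values, 1e-300), 1).sum()
        assert fit.lambda_hat > 0
        assert fit.loglik > ll_central

    def test_wald_type_one_error_calibrated(self, tte_preset):
        model, design = tte_preset
        eng = ncp.SimulationEngine(model.with_effect(0.0), design, statistic="wald")
        res = eng.statistics(200, 10_000, seed=(19,))
        q = ncp.critical_value(ncp.HypothesisSpec(df=1))
        rate = np.mean(res.values > q)
        se = np.sqrt(0.05 * 0.95 / res.values.size)
        assert abs(rate - 0.05) < 3 * se

    def test_batch_matches_single_dataset_fits(self, tte_preset):
        """The replicate-batched fitter and the per-dataset path agree."""
        model, design = tte_preset
        eng = ncp.SimulationEngine(model, design)
        res = eng.statistics(200, 3, seed=(55,))
        for r in range(3):
            data = ncp.simulate_dataset(model, design, (55, r))
            full = ncp.fit_model(model, data, restricted=False)
            red = ncp.fit_model(model, data, restricted=True)
            assert nlmem.llr_statistic(full, red) == pytest.approx(
                res.values[r], abs=1e-6
            )
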