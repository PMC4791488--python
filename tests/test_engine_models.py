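"""Count and Gaussian-linear families, presets, and dataset round trips."""

import numpy as np
import pytest

import ncpower as ncp
from ncpower.nlmem import Dataset, ModelSpec, StudyDesign


class TestPresets:
    def test_registry_names(self):
        for name in ("binary", "tte", "count", "alzheimer12", "alzheimer18", "alzheimer24"):
            model, design = ncp.get_preset(name)
            assert design.n_subjects > 0

    @pytest.mark.parametrize("name", ["pk", "pkpd"])
    def test_ode_families_direct_to_file_input(self, name):
        with pytest.raises(NotImplementedError, match="statistics file"):
            ncp.get_preset(name)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            ncp.get_preset("nope")

    def test_alzheimer_visit_truncation(self):
        _, d12 = ncp.get_preset("alzheimer12")
        _, d24 = ncp.get_preset("alzheimer24")
        assert d12.observation_times == (0.0, 0.5, 1.0)
        assert d24.observation_times == (0.0, 0.5, 1.0, 1.5, 2.0)

    def test_model_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            ModelSpec("binary", (1.0, 1.0), ((1.0, 0.5), (0.0, 1.0)), None, 0.1,
                      "dichotomous", 2)
        with pytest.raises(ValueError, match="positive semi-definite"):
            ModelSpec("binary", (1.0, 1.0), ((1.0, 2.0), (2.0, 1.0)), None, 0.1,
                      "dichotomous", 2)
        with pytest.raises(ValueError):
            StudyDesign(n_subjects=10, observation_times=(1.0, 0.5))


class TestCountFamily:
    def test_baseline_mean_matches_lognormal_moment(self):
        """At t=0 the Poisson mean is b = theta1 exp(eta1), so the observed
        mean tracks theta1 * exp(omega^2 / 2)."""
        model, design = ncp.get_preset("count")
        data = ncp.simulate_dataset(model, design.with_n_subjects(20_000), 99)
        expected = 1.0 * np.exp(0.09 / 2)
        observed = data.y[:, 0].mean()
        se = np.sqrt(data.y[:, 0].var() / data.n_subjects)
        assert abs(observed - expected) < 3 * se

    def test_laplace_loglik_prefers_truth_over_distorted(self):
        model, design = ncp.get_preset("count")
        data = ncp.simulate_dataset(model, design.with_n_subjects(200), 4)
        truth = (1.0, 4.0, 2.0, 0.3, 0.09, 0.09, 0.09)
        ll_true = ncp.loglik(model, truth, data)
        ll_off = ncp.loglik(model, (2.0, 2.0, 1.0, -0.3, 0.09, 0.09, 0.09), data)
        assert np.isfinite(ll_true) and ll_true > ll_off

    def test_restricted_never_beats_full_small_data(self):
        model, design = ncp.get_preset("count")
        small = StudyDesign(n_subjects=30,
                            observation_times=tuple(np.linspace(0, 1, 5)),
                            covariate_kind="standard_normal")
        data = ncp.simulate_dataset(model, small, 12)
        full = ncp.fit_model(model, data, restricted=False)
        red = ncp.fit_model(model, data, restricted=True)
        assert red.loglik <= full.loglik + 1e-6


class TestGaussianFamily:
    def test_baseline_mean_is_theta1(self):
        """pbo(0) = A(e^0 - e^0) = 0, so the mean response at t=0 is 56.4."""
        model, design = ncp.get_preset("alzheimer24")
        data = ncp.simulate_dataset(model, design.with_n_subjects(100_000), 2)
        observed = data.y[:, 0].mean()
        se = np.sqrt((14.3 + 7.9) / data.n_subjects)
        assert abs(observed - 56.4) < 3 * se

    def test_collapses_to_iid_normal_without_random_effects(self, rng):
        model = ModelSpec(
            "gaussian_linear", (56.4, 4.83, -20.0, 2.77, 1.73),
            ((1e-10, 0.0), (0.0, 1e-10)), 1.0, 0.3, "dichotomous", 5,
        )
        design = StudyDesign(n_subjects=40, observation_times=(0.0, 0.5, 1.0))
        data = ncp.simulate_dataset(model, design, 6)
        params = (56.4, 4.83, -20.0, 2.77, 1.73, 0.3, 1e-10, 0.0, 1e-10, 1.0)
        ll = ncp.loglik(model, params, data)
        t = data.times
        mean = (
            56.4 + 4.83 * (1 - 0.3 * data.z)[:, None] * t[None, :]
            - 20.0 * (np.exp(-2.77 * t) - np.exp(-1.73 * t))[None, :]
        )
        resid = data.y - mean
        iid = -0.5 * resid.size * np.log(2 * np.pi) - 0.5 * np.sum(resid**2)
        assert ll == pytest.approx(iid, abs=1e-5)

    def test_marginal_matches_monte_carlo_integration(self, rng):
        """The exact multivariate-normal marginal equals brute-force Monte
        Carlo integration of the conditional likelihood over eta."""
        model, design = ncp.get_preset("alzheimer24")
        params = (56.4, 4.83, -20.0, 2.77, 1.73, 0.3, 14.3, -1.2, 6.1, 7.9)
        om = np.array([[14.3, -1.2], [-1.2, 6.1]])
        L = np.linalg.cholesky(om)
        t = np.asarray(design.observation_times)
        n_draws = 100_000
        for seed in range(5):
            data = ncp.simulate_dataset(model, design.with_n_subjects(4), seed)
            exact = ncp.loglik(model, params, data)
            mc_rng = np.random.default_rng(1000 + seed)
            eta = mc_rng.standard_normal((n_draws, 2)) @ L.T
            total, total_var = 0.0, 0.0
            for i in range(data.n_subjects):
                c = 1 - 0.3 * data.z[i]
                mean = (
                    (56.4 + eta[:, 0])[:, None]
                    + ((4.83 + eta[:, 1]) * c)[:, None] * t[None, :]
                    - 20.0 * (np.exp(-2.77 * t) - np.exp(-1.73 * t))[None, :]
                )
                resid = data.y[i][None, :] - mean
                cond = -0.5 * t.size * np.log(2 * np.pi * 7.9) - 0.5 * np.sum(
                    resid**2, axis=1
                ) / 7.9
                m = cond.max()
                w = np.exp(cond - m)
                total += m + np.log(w.mean())
                total_var += (w.std(ddof=1) / (w.mean() * np.sqrt(n_draws))) ** 2
            assert abs(exact - total) < 3 * np.sqrt(total_var) + 1e-6

    def test_recovery_at_n500(self):
        model, design = ncp.get_preset("alzheimer24")
        data = ncp.simulate_dataset(model, design.with_n_subjects(500), 41)
        fit = ncp.fit_model(model, data, restricted=False)
        assert fit.converged
        # SEs for the linear fixed effects from the marginal covariance:
        # Var(theta1_hat) ~ (om1 + s2/J) / N is a conservative scale
        assert abs(fit.theta_hat[0] - 56.4) < 3 * np.sqrt((14.3 + 7.9) / 500)
        assert abs(fit.theta_hat[1] - 4.83) < 3 * np.sqrt((6.1 + 7.9) / 500) * 2


class TestDatasetRoundTrip:
    @pytest.mark.parametrize("preset", ["tte", "binary", "alzheimer24"])
    def test_csv_frame_round_trip_preserves_loglik(self, preset):
        model, design = ncp.get_preset(preset)
        design = design.with_n_subjects(20)
        data = ncp.simulate_dataset(model, design, 3)
        frame = data.to_frame()
        assert set(frame.columns) == {"id", "time", "covariate", "dv", "cens"}
        back = Dataset.from_frame(frame, model.family, censor_time=design.censor_time)
        if model.family == "tte":
            params = (0.2, 2.0, 0.4)
        elif model.family == "binary":
            params = (-1.0, 4.0, 0.3, 0.4, 4.0)
        else:
            params = (56.4, 4.83, -20.0, 2.77, 1.73, 0.3, 14.3, -1.2, 6.1, 7.9)
        assert ncp.loglik(model, params, back) == pytest.approx(
            ncp.loglik(model, params, data), rel=1e-10
        )
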