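"""Parametric bootstrap confidence intervals and the CDF-band diagnostic."""

import numpy as np
import pytest

import ncpower as ncp


def _fit_from_draws(rng, lam, s_p, df=1):
    draws = rng.noncentral_chisquare(df, lam, size=s_p) if lam > 0 else rng.chisquare(df, s_p)
    sample = ncp.preprocess_statistics(draws, df)
    return ncp.fit_noncentrality(sample), sample


class TestBootstrapPowerCi:
    def test_interval_contains_true_power(self, rng):
        fit, _ = _fit_from_draws(rng, 7.85, 400)
        boot = ncp.bootstrap_power_ci(
            fit, 400, 1000, ncp.HypothesisSpec(df=1), [200], 200, rng_seed=5
        )
        lo, hi = boot.power_ci_by_size[200]
        assert lo < 0.800 < hi
        assert boot.lambda_ci[0] < fit.lambda_hat < boot.lambda_ci[1]

    def test_nested_coverage_mini_calibration(self, rng):
        """Over independent outer repetitions, ~95 % of bootstrap CIs cover
        the true power (loose binomial check at 100 repetitions)."""
        hyp = ncp.HypothesisSpec(df=1)
        true_power = ncp.power_from_lambda(7.85, 1, 0.05)
        covered = 0
        for rep in range(100):
            fit, _ = _fit_from_draws(rng, 7.85, 200)
            boot = ncp.bootstrap_power_ci(fit, 200, 300, hyp, [200], 200, rng_seed=rep)
            lo, hi = boot.power_ci_by_size[200]
            covered += lo <= true_power <= hi
        assert 85 <= covered <= 100

    def test_width_shrinks_with_sample_size(self, rng):
        hyp = ncp.HypothesisSpec(df=1)
        widths = {}
        for s_p in (100, 400):
            fit = ncp.NoncentralityFit(
                lambda_hat=7.85, df=1, sample_size=s_p, loglik=0.0,
                at_boundary=False, converged=True,
            )
            boot = ncp.bootstrap_power_ci(fit, s_p, 500, hyp, [200], 200, rng_seed=9)
            lo, hi = boot.power_ci_by_size[200]
            widths[s_p] = hi - lo
        assert widths[100] > widths[400]

    def test_boundary_fit_degenerates_to_alpha(self, rng):
        fit, _ = _fit_from_draws(rng, 0.0, 400)
        assert fit.lambda_hat == 0.0
        boot = ncp.bootstrap_power_ci(
            fit, 400, 500, ncp.HypothesisSpec(df=1), [200], 200, rng_seed=1
        )
        lo, hi = boot.power_ci_by_size[200]
        assert lo >= 0.05 - 1e-9
        assert hi < 0.15  # narrow band just above alpha

    def test_reproducible_from_seed(self, rng):
        fit, _ = _fit_from_draws(rng, 5.0, 100)
        a = ncp.bootstrap_power_ci(fit, 100, 200, ncp.HypothesisSpec(df=1), [100], 100, 3)
        b = ncp.bootstrap_power_ci(fit, 100, 200, ncp.HypothesisSpec(df=1), [100], 100, 3)
        assert np.array_equal(a.lambda_draws, b.lambda_draws)
        assert a.power_ci_by_size == b.power_ci_by_size

    def test_requires_converged_fit_and_enough_sets(self, rng):
        fit, _ = _fit_from_draws(rng, 5.0, 100)
        bad = ncp.NoncentralityFit(5.0, 1, 100, 0.0, False, converged=False)
        with pytest.raises(ValueError):
            ncp.bootstrap_power_ci(bad, 100, 500, ncp.HypothesisSpec(df=1), [100], 100, 0)
        with pytest.raises(ValueError):
            ncp.bootstrap_power_ci(fit, 100, 50, ncp.HypothesisSpec(df=1), [100], 100, 0)


class TestDiagnosticBand:
    def test_band_is_ordered_and_monotone(self, rng):
        fit, sample = _fit_from_draws(rng, 7.85, 200)
        band = ncp.diagnostic_band(fit, sample, b=300, rng_seed=2)
        assert np.all(band.band_low <= band.band_high + 1e-12)
        assert np.all(np.diff(band.band_low) >= -1e-12)
        assert np.all(np.diff(band.band_high) >= -1e-12)
        assert np.all((band.band_low >= 0) & (band.band_high <= 1))

    def test_well_specified_sample_stays_mostly_inside(self, rng):
        fracs = []
        for rep in range(15):
            fit, sample = _fit_from_draws(rng, 7.85, 100)
            band = ncp.diagnostic_band(fit, sample, b=300, rng_seed=rep)
            fracs.append(band.outside_fraction)
        assert np.median(fracs) < 0.15

    def test_boundary_mixture_is_flagged(self, rng):
        """A point mass at zero — the boundary-null signature — pushes the
        ECDF far outside the non-central chi-square band."""
        fracs = []
        for rep in range(10):
            draws = rng.noncentral_chisquare(1, 7.85, size=100)
            draws[: 50] = 0.0  # half delta_0, half ncx2
            sample = ncp.preprocess_statistics(draws, 1)
            fit = ncp.fit_noncentrality(sample)
            band = ncp.diagnostic_band(fit, sample, b=300, rng_seed=rep)
            fracs.append(band.outside_fraction)
        assert np.median(fracs) > 0.25
        assert np.median(fracs) > 0.15  # clearly above the well-specified level

    def test_single_retained_draw_gives_degenerate_band(self, rng):
        fit, sample = _fit_from_draws(rng, 7.85, 50)
        band = ncp.diagnostic_band(fit, sample, b=1, rng_seed=0, retain="all")
        assert np.allclose(band.band_low, band.band_high)

    def test_percentile_strategy_is_narrower_than_envelope(self, rng):
        fit, sample = _fit_from_draws(rng, 7.85, 100)
        env = ncp.diagnostic_band(fit, sample, b=400, rng_seed=4, strategy="envelope")
        pct = ncp.diagnostic_band(fit, sample, b=400, rng_seed=4, strategy="percentile")
        assert np.all(pct.band_high - pct.band_low <= env.band_high - env.band_low + 1e-12)

    def test_csv_frame_columns(self, rng):
        fit, sample = _fit_from_draws(rng, 7.85, 60)
        band = ncp.diagnostic_band(fit, sample, b=200, rng_seed=0)
        frame = band.to_frame()
        assert list(frame.columns) == ["t", "band_low", "band_high", "ecdf"]
        assert len(frame) == band.t_grid.size
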