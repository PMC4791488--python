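# Methods

## Model of the test statistic

For a two-sided test of one fixed effect (`H0: theta_H = 0`) in a
mixed-effects model, the likelihood-ratio statistic `t = 2 (l_full -
l_reduced)` is asymptotically central chi-square with `k` degrees of freedom
under the null and non-central chi-square `ncx2(k, lambda)` under a fixed
alternative.  The package treats these two facts as its working model:

* **MCPE** uses only the null distribution: power is the fraction of
  simulated statistics exceeding `chi2_{1-alpha,k}`.  Rejection uses strict
  inequality; ties (probability zero for continuous statistics) do not
  reject.
* **PPE** additionally uses the alternative distribution: `lambda` is
  estimated by maximum likelihood from the simulated statistics, power is
  `1 - F_ncx2(chi2_{1-alpha,k}; k, lambda_hat)`, and the curve across study
  sizes follows from `lambda_k = lambda_ref N_k / N_ref`.

The linear scaling is exact when the reference design (including its group
structure) is replicated to change study size, because the expected
information is then proportional to `N`.  Extrapolation far below the
asymptotic regime (very small `N`) is the known weak spot.

Degrees of freedom enter only through `k`; multivariate linear hypotheses
are supported by setting `df = k > 1`.  The package never computes `lambda`
from the expected Fisher information — simulation-estimation is the input.

## Estimating the non-centrality parameter

`fit_noncentrality` maximizes `sum_s log f_ncx2(t_s; k, lambda)` over
`lambda >= 0`.  Implementation details that matter:

* **Score equation instead of direct search.**  Using
  `d f_k / d lambda = (f_{k+2} - f_k) / 2`, the score is
  `sum_s (r_s - 1)/2` with the density ratio
  `r = f_{k+2}/f_k = sqrt(t/lambda) * I_{k/2}(x)/I_{k/2-1}(x)`,
  `x = sqrt(lambda t)`.  Its derivative is `sum r (r' - r)/4` with
  `r' = f_{k+4}/f_{k+2}`.  The root is found by bracketed Newton iteration
  (bisection fallback, bracket `[0, max(t) + 10k]`), converged at
  `|Delta lambda| < 1e-8`.  For `k = 1` and `k = 3` the Bessel ratios reduce
  to `tanh(x)` and `coth(x) - 1/x`; this, plus full vectorization across
  samples (`fit_noncentrality_batch`), is what makes nested bootstrap
  studies with ~10^6 refits feasible.
* **Boundary rule.**  The score at `lambda = 0` is `sum(t - k) / (2k)`, so
  the estimate is exactly zero whenever the sample mean is at most `k`;
  this is tested before any iteration, making the boundary case exact
  rather than tolerance-dependent.
* **Zero statistics.**  Clamped-to-zero statistics have no finite density
  for `k < 2`.  They contribute the limiting lambda-dependence
  `c * exp(-lambda/2)` with the constant floored at 1e-300 (for `k = 2` the
  exact limit `c = 1/2` is used), which corresponds to score contribution
  `-1/2` — consistent between the reported log-likelihood and the score
  used for fitting.
* **Negative statistics** (possible when both optimizations are stochastic
  or one fails) are handled by `preprocess_statistics`: default policy
  `clamp` to zero with a logged warning (conservative — treats the
  replicate as carrying no evidence); `drop` and `error` are available.
  Non-finite values are always dropped and counted.

`power_from_lambda` returns exactly `alpha` at `lambda = 0` (central
branch) and uses `scipy.stats.ncx2.sf` otherwise.

## Parametric bootstrap and diagnostic

`B` sets of `S_P` draws from `ncx2(k, lambda_hat)` are re-fitted; the
2.5th/97.5th percentiles of the bootstrap `lambda_hat_b` are scaled to each
study size and mapped to power, giving 95 % intervals.  Default `B = 1000`.
Non-convergent refits are dropped; more than 10 % dropped raises an error.

The diagnostic keeps the `lambda_hat_b` inside their own 2.5–97.5 percentile
range and draws the pointwise **min/max envelope** of the corresponding
`ncx2` CDFs on a 512-point grid over `[0, 1.2 max(t)]`.  The envelope is the
plainest reading of "the estimates in the 95 % confidence interval are used
to plot the CDF"; a pointwise-percentile band and a keep-all-draws variant
are available behind `strategy=`/`retain=` switches because the construction
is genuinely ambiguous.  A statistic counts as outside when its entire ECDF
step interval `((i-1)/n, i/n]` misses the band; an outside fraction above
5 % logs a warning rather than raising — the band covers only the
uncertainty in `lambda_hat`, not the sampling noise of the ECDF itself, so
small excursions occur even under a correct model and the diagnostic is
deliberately a flag, not a test.  No formal goodness-of-fit p-value is
computed.

## The simulate-and-estimate engine

All four families simulate subject-level data from the declared model and
fit full (tested effect free) and reduced (effect fixed at 0) models by
maximum likelihood, starting at the simulating parameters — the standard
choice in simulation studies, where the interest is the statistic's
distribution, not optimizer robustness.  Dichotomous covariates alternate
0/1 deterministically (exact half/half split); continuous covariates are
standard normal.  Per-replicate random streams derive from
`SeedSequence((seed..., replicate_index))`, so every run is bit-reproducible
and grids parallelize without reseeding artifacts.

* **Time-to-event** (Weibull, one event per subject, administrative
  censoring at `T = 10`; defaults `theta1 = 0.2`, `gamma = 2`, `N* = 200`).
  The covariate acts proportionally on the hazard (`theta_H` is a log
  hazard ratio, default 0.4), which places the reference design near 80 %
  power.  The likelihood is exact and the fitter is a replicate-batched
  Newton iteration with analytic gradient and Hessian on
  `(log theta1, log gamma, theta_H)` — ~10,000 full/reduced fit pairs per
  second on one core.  LLR values in `[-1e-6, 0)` (matched-optimum noise)
  are clamped to zero; anything more negative is passed through to the
  preprocessing policy.
* **Binary** (logistic with random intercept and slope, 20 visits on
  `[0, 1]`; `theta = (-1, 4)`, `Omega = diag(0.4, 4)`, effect 0.3 damping
  the slope, `N* = 110`).  Marginal likelihood by mode-centered adaptive
  Gauss-Hermite quadrature, default 7 nodes/dimension (7 vs 15 nodes agree
  to < 1e-4 per subject); the Laplace approximation (the 1-node case) is
  available where throughput matters, e.g. the diagnostic study below.
* **Count** (Poisson with saturating rate, lognormal `b, A, k`, continuous
  covariate on `k`; `theta = (1, 4, 2)`, `Omega = 0.09 I_3`, effect 0.3,
  `N* = 160`).  Laplace approximation over the 3-D random effect —
  dense quadrature in three dimensions buys little at these variances.
  Inner Newton steps are trust-region capped with per-subject step halving;
  if the observed inner Hessian is numerically indefinite at the stopping
  point, the Fisher-scoring information substitutes in the determinant.
* **Gaussian linear** (disease progression `S0 + alpha t` plus placebo
  response `A(e^{-koff t} - e^{-kon t})`, treatment damping the progression
  rate; `theta = (56.4, 4.83, -20, 2.77, 1.73)`, `omega1^2 = 14.3`,
  `omega2^2 = 6.1`, `omega12 = -1.2`, `sigma^2 = 7.9`; visits every 6
  months, times in years).  Random effects enter linearly, so the marginal
  is exactly multivariate normal with covariance `Z Omega Z' + sigma^2 I`;
  `Omega` is estimated through its Cholesky factor (the covariance term
  included).  The 12/18/24-month variants truncate the visit schedule.

Wald statistics come from the inverse of the observed information,
numerically differentiated at the estimate (central differences); a
singular information matrix raises an identifiability error.  ODE-based PK
and PKPD families are registered by name but deliberately have no internal
estimator — their statistics enter via a statistics file.  No general
model-description language, ODE solver, FOCE/SAEM estimation, or
between-occasion variability is provided.

## Evaluation harness

`run_method_comparison` repeats both estimators `L` times per Monte Carlo
sample size `S in {100, 200, 400}` at the reference study size, against a
10,000-replicate MCPE reference, and reports relative bias
`100 (mean - pi_ref)/pi_ref`, SD (divisor `L - 1`) and range, all in
percent.  MCPE and PPE share the statistic pool within a run (paired
design; reduces comparison noise without changing either marginal summary).
Pools are independent across `(L, S)` cells.  Study-size grids built from
fractional multipliers round up to the next even integer; user-supplied
grids are used verbatim.  `run_coverage_study` reports the fraction of
bootstrap 95 % intervals containing the reference power.

## What the synthetic conditions do and do not show

The engine simulates from the same model family it fits, with known true
parameters as starting values.  Passing tests therefore demonstrate the
statistical machinery — estimator correctness, calibration of the null
distribution, the precision advantage of PPE, nominal bootstrap coverage,
the linear-lambda extrapolation — under conditions where the asymptotic
theory should hold.  They do not probe model misspecification, local
minima from poor starting values, estimation-algorithm bias (e.g.
linearization methods), or ODE-scale models; with real data all of these
can distort the statistic's distribution, which is exactly what the CDF
diagnostic is for.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations for a single
CPU: null calibration uses 10,000 time-to-event replicates; the
table-reproduction check L = 250 runs at S = 100 against a 10,000-replicate
reference; precision ordering L = 1000 (distributional stub) and L = 150
(time-to-event engine); bootstrap coverage 1000 outer repetitions with
S_P = 100 and B = 500; power-curve agreement 200 PPE runs of S_P = 400
against 10,000-replicate MCPE at five sizes; the diagnostic study 5 seeds
times 100 binary replicates per scenario with Laplace fits.  Model and
design parameters themselves are always the preset values above.

## Known limitations

* The `lambda` estimate is mildly biased upward at small `S_P` (boundary
  truncation plus MLE curvature), which propagates to a small positive
  power bias of well under 2 % in the evaluated scenarios — negligible
  next to design and parameter uncertainty in practice.
* Bootstrap intervals inherit that bias; their coverage can sit a few
  points below nominal for families where the `ncx2` approximation is
  imperfect.  Treat them as approximate.
* The CDF-band diagnostic is over-sensitive by construction (see above);
  use it to compare scenarios and catch gross violations, not as a formal
  test.
* Power extrapolated to study sizes far below the reference can deviate
  where the asymptotic chi-square approximation breaks down.
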