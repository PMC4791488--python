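# ncpower

Parametric power estimation (PPE) for hypothesis tests in (non-linear)
mixed-effects models.

## The problem

Power calculations for mixed-effects analyses — pharmacometric dose-response
models, longitudinal trial models, parametric survival models — rarely have a
closed form.  The classical recourse is Monte Carlo power estimation (MCPE):
simulate `S` datasets under the alternative, refit full and reduced models,
and report the fraction of likelihood-ratio (LLR) statistics exceeding the
chi-square critical value.  Each replicate contributes one bit of
information, so stable estimates need many replicates, and a power *curve*
multiplies that cost by the number of study sizes.

PPE replaces the rejection count with a parametric fit.  Under the
alternative `H1: theta_H = theta_H*`, the LLR (and Wald) statistic is
asymptotically non-central chi-square with `k` degrees of freedom and
non-centrality `lambda`.  From a sample `T = (t_1, ..., t_S)` of simulated
statistics, PPE estimates

    lambda_hat = argmax_lambda  sum_s log f_chi2(t_s; k, lambda)

and converts it to power analytically,

    pi_hat = 1 - F_chi2( chi2_{1-alpha,k}; k, lambda_hat ).

Because the expected Fisher information of a design replicated across `N`
subjects is `N` times the single-subject information, `lambda` scales
linearly in study size:

    lambda_k = lambda_ref * N_k / N_ref.

One batch of simulations at a single study size therefore yields the entire
power-versus-N curve — with noticeably better precision per replicate than
MCPE (roughly half as many simulations for the same SD).

The package also ships:

* a **parametric bootstrap** for the Monte Carlo uncertainty of `lambda_hat`
  and the resulting power (95 % percentile intervals);
* a **CDF-band diagnostic**: the ECDF of the observed statistics overlaid on
  the envelope of non-central chi-square CDFs from the bootstrap — excursions
  indicate the distributional assumption is violated (e.g. a null hypothesis
  on the boundary of the parameter space);
* a compact **simulate-and-estimate engine** with maximum-likelihood fitting
  for four model families (Weibull time-to-event; binary longitudinal with
  bivariate random effects via adaptive Gauss-Hermite quadrature; Poisson
  count with trivariate random effects via Laplace; Gaussian linear disease
  progression with exact marginal likelihood), plus presets for the
  published evaluation designs and an Alzheimer's trial application example;
* an **evaluation harness** comparing PPE with MCPE over repeated runs
  (relative bias, SD, range, bootstrap coverage).

Statistics from external estimation software can be supplied as a CSV with a
`statistic` column, or as `ofv_full`/`ofv_reduced` columns of objective
function values in the `-2 log L` convention (the statistic is then
`ofv_reduced - ofv_full`).

## Worked example

Estimate the power curve of a Weibull time-to-event trial (baseline scale
0.2, shape 2, log hazard ratio 0.4 between two equal arms, events censored
at t = 10) from 200 simulate-and-refit replicates at the reference size
N = 200:

```bash
ncpower sse --preset tte --samples 200 --seed 42 --b 1000 --out demo
cat demo/power_curve.csv
```

```
n,lambda,power,ci_low,ci_high
50,1.8479349673980752,0.274512258279495,0.2509107138703494,0.2974307632110908
100,3.6958699347961503,0.48509510354741053,0.44418088940579536,0.5232863503710161
150,5.543804902194226,0.6534258805424774,0.6057881453239159,0.6956492046356385
200,7.391739869592301,0.7760187659203716,0.7300774731311748,0.8144241289773351
250,9.239674836990375,0.8598667022103621,0.8203612805822825,0.8908793209046457
```

The engine simulated 200 trials, fitted the full and reduced Weibull models
to each, and estimated `lambda_hat = 7.39` from the 200 LLR statistics.
Each row scales that estimate to a study size (`lambda = 7.39 * N / 200`)
and converts it to power: about 78 % at the reference size N = 200 (the
large-sample Monte Carlo value is 0.80), dropping to 27 % at N = 50 and
rising to 86 % at N = 250.  `ci_low`/`ci_high` are 95 % parametric-bootstrap
intervals reflecting the Monte Carlo noise of using only 200 replicates;
`demo/diagnostic.csv` holds the CDF-band diagnostic, and `demo/sse_run.json`
records the fully resolved configuration including the seed.

The same curve from an existing statistics file, with figures:

```bash
ncpower fit my_stats.csv --df 1 --n-ref 200 --grid 50:400:50 \
        --bootstrap --plot --out results
```

Library use mirrors the CLI:

```python
import ncpower as ncp

sample = ncp.preprocess_statistics(values, df=1)          # clamp negatives
curve = ncp.ppe_power_curve(sample, ncp.HypothesisSpec(df=1),
                            n_ref=200, size_grid=[50, 100, 200, 400])
```

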