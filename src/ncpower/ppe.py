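"""Parametric power estimation (PPE) core.

The likelihood-ratio (and Wald) statistic of a test with ``df`` degrees of
freedom follows, asymptotically, a central chi-square distribution under the
null hypothesis and a non-central chi-square distribution with non-centrality
parameter ``lambda`` under the alternative.  PPE estimates ``lambda`` by
maximum likelihood from a modest sample of simulated test statistics, converts
it to power analytically, and — because ``lambda`` is proportional to the
number of design-replicated subjects — scales it linearly with study size to
obtain the full power-versus-sample-size curve from simulations at a single
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "HypothesisSpec",
    "StatisticSample",
    "NoncentralityFit",
    "PowerEstimate",
    "PowerCurve",
    "preprocess_statistics",
    "fit_noncentrality",
    "fit_noncentrality_batch",
    "power_from_lambda",
    "scale_lambda",
    "ppe_power_curve",
    "ncx2_logpdf",
]

logger = logging.getLogger(__name__)

#: lower floor on the non-central chi-square density used when evaluating the
#: log-likelihood at statistics exactly equal to zero (df <= 2 has an
#: unbounded / vanishing density at the origin).
DENSITY_FLOOR = 1e-300

#: absolute tolerance on the non-centrality estimate.
LAMBDA_TOL = 1e-8


@dataclass(frozen=True)
class HypothesisSpec:
    """A (possibly multivariate, linear) hypothesis on fixed effects.

    Parameters
    ----------
    df : int
        Degrees of freedom ``k`` of the test (number of restrictions).
    null_value : float
        Value of the tested parameter under the null hypothesis.
    alpha : float
        Two-sided significance level, in (0, 1).
    """

    df: int
    null_value: float = 0.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if int(self.df) != self.df or self.df < 1:
            raise ValueError(f"df must be a positive integer, got {self.df}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class StatisticSample:
    """A cleaned collection of nonnegative test statistics.

    ``n_raw`` counts statistics supplied before preprocessing, ``n_dropped``
    those removed (non-finite entries, or negatives under the ``drop``
    policy), and ``n_clamped`` negatives set to zero under the ``clamp``
    policy.
    """

    values: np.ndarray
    df: int
    n_raw: int
    n_dropped: int = 0
    n_clamped: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("statistic values must be nonnegative")
        if self.n_raw != self.values.size + self.n_dropped:
            raise ValueError("n_raw must equal len(values) + n_dropped")

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass
class NoncentralityFit:
    """Maximum-likelihood estimate of the non-centrality parameter."""

    lambda_hat: float
    df: int
    sample_size: int
    loglik: float
    at_boundary: bool
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class PowerEstimate:
    """A single power estimate with optional confidence bounds."""

    power: float
    method: Literal["MCPE", "PPE"]
    study_size: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low must not exceed ci_high")


@dataclass
class PowerCurve:
    """Power versus study size obtained by linear non-centrality scaling."""

    reference_size: int
    lambda_ref: float
    sizes: np.ndarray
    lambdas: np.ndarray
    power: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    fit: NoncentralityFit | None = None

    def to_frame(self):
        import pandas as pd

        nan = np.full(self.sizes.shape, np.nan)
        return pd.DataFrame(
            {
                "n": self.sizes.astype(int),
                "lambda": self.lambdas,
                "power": self.power,
                "ci_low": self.ci_low if self.ci_low is not None else nan,
                "ci_high": self.ci_high if self.ci_high is not None else nan,
            }
        )


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_statistics(
    raw: Iterable[float],
    df: int,
    negative_policy: Literal["clamp", "drop", "error"] = "clamp",
) -> StatisticSample:
    """Clean a raw collection of test statistics.

    Non-finite entries are always dropped.  Negative statistics — which can
    arise from stochastic noise in the estimation step of a
    simulate-and-refit study — are handled according to ``negative_policy``:
    ``clamp`` sets them to zero (conservative: treats the replicate as
    carrying no evidence against the null), ``drop`` removes them, ``error``
    raises.
    """
    arr = np.asarray(list(raw) if not isinstance(raw, np.ndarray) else raw, dtype=float)
    arr = arr.ravel()
    n_raw = arr.size
    if n_raw == 0:
        raise ValueError("no usable statistics: input is empty")
    if int(df) != df or df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")

    finite = np.isfinite(arr)
    n_dropped = int(np.sum(~finite))
    arr = arr[finite]

    negative = arr < 0
    n_neg = int(np.sum(negative))
    n_clamped = 0
    if n_neg:
        if negative_policy == "clamp":
            arr = np.where(negative, 0.0, arr)
            n_clamped = n_neg
            logger.warning("clamped %d negative test statistics to 0", n_neg)
        elif negative_policy == "drop":
            arr = arr[~negative]
            n_dropped += n_neg
        elif negative_policy == "error":
            raise ValueError(f"{n_neg} negative test statistics with negative_policy='error'")
        else:
            raise ValueError(f"unknown negative_policy {negative_policy!r}")

    if arr.size == 0:
        raise ValueError("no usable statistics: all entries removed by preprocessing")
    return StatisticSample(
        values=arr, df=int(df), n_raw=n_raw, n_dropped=n_dropped, n_clamped=n_clamped
    )


# ---------------------------------------------------------------------------
# stable non-central chi-square pieces


def ncx2_logpdf(t, df: int, lam: float):
    """Numerically stable log-density of the non-central chi-square.

    Uses the exponentially scaled Bessel function so that large ``lam``
    (up to ~1e4) and small ``t`` neither overflow nor underflow.  Statistics
    exactly zero get the density's limiting lambda-dependence
    ``c * exp(-lam/2)`` with the constant ``c`` floored at ``DENSITY_FLOOR``
    (df = 2 has the exact finite limit c = 1/2).
    """
    t = np.asarray(t, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    # the floor only replaces the divergent/vanishing constant at t = 0; it
    # must not clamp genuinely small densities elsewhere
    if lam == 0.0:
        out = stats.chi2.logpdf(t, df)
        zero = t == 0.0
        if np.any(zero):
            c = 0.5 if df == 2 else DENSITY_FLOOR
            out = np.where(zero, np.log(c), out)
        return out

    nu = df / 2.0 - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.sqrt(lam * t)
        main = (
            -np.log(2.0)
            - (t + lam) / 2.0
            + (df / 4.0 - 0.5) * (np.log(t) - np.log(lam))
            + x
            + np.log(special.ive(nu, x))
        )
    zero = t == 0.0
    if np.any(zero):
        c = 0.5 if df == 2 else DENSITY_FLOOR
        main = np.where(zero, np.log(c) - lam / 2.0, main)
    return main


def _density_ratio(t: np.ndarray, df: int, lam: np.ndarray) -> np.ndarray:
    """Elementwise ratio f(t; df+2, lam) / f(t; df, lam).

    This ratio drives the score of the non-centrality log-likelihood:
    d/dlam log f(t; df, lam) = (ratio - 1) / 2.  For df = 1 and df = 3 the
    half-integer Bessel functions reduce to hyperbolic forms, which is much
    faster than the generic scaled-Bessel path.
    """
    t = np.asarray(t, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = np.empty(np.broadcast(t, lam).shape, dtype=float)
    tb, lb = np.broadcast_arrays(t, lam)

    central = lb == 0.0
    if np.any(central):
        out[central] = tb[central] / df

    m = ~central
    if np.any(m):
        tt, ll = tb[m], lb[m]
        x = np.sqrt(ll * tt)
        with np.errstate(divide="ignore", invalid="ignore"):
            if df == 1:
                ratio = np.tanh(x)
            elif df == 3:
                ratio = 1.0 / np.tanh(x) - 1.0 / x
            else:
                ratio = special.ive(df / 2.0, x) / special.ive(df / 2.0 - 1.0, x)
            val = np.sqrt(tt / ll) * ratio
        # t == 0 contributes the limiting score -1/2, i.e. ratio 0
        val = np.where(tt == 0.0, 0.0, val)
        # x -> 0 limit of the ratio is t/df
        small = (x < 1e-12) & (tt > 0.0)
        if np.any(small):
            val = np.where(small, tt / df, val)
        out[m] = val
    return out


def _score_and_deriv(T: np.ndarray, df: int, lam: np.ndarray, deriv: bool = True):
    """Score of the non-centrality log-likelihood and (optionally) its
    derivative, summed over the last axis of ``T``.

    Uses d f_k/d lam = (f_{k+2} - f_k)/2, hence per-observation score
    (r - 1)/2 with r = f_{k+2}/f_k and derivative r (r' - r)/4 with
    r' = f_{k+4}/f_{k+2}.
    """
    lam = np.asarray(lam, dtype=float)
    r = _density_ratio(T, df, lam[..., None] if lam.ndim else lam)
    score = 0.5 * (r - 1.0).sum(axis=-1)
    if not deriv:
        return score, None
    r2 = _density_ratio(T, df + 2, lam[..., None] if lam.ndim else lam)
    dscore = 0.25 * (r * (r2 - r)).sum(axis=-1)
    return score, dscore


def fit_noncentrality_batch(
    T: np.ndarray, df: int, tol: float = LAMBDA_TOL, max_iter: int = 100
) -> np.ndarray:
    """Row-wise non-centrality MLEs for a matrix of statistic samples.

    Safeguarded Newton on the score equation, fully vectorized across rows.
    Rows whose sample mean is <= df sit on the boundary (score at 0 is
    nonpositive) and get exactly 0.
    """
    T = np.atleast_2d(np.asarray(T, dtype=float))
    n_rows = T.shape[0]
    mean = T.mean(axis=1)
    lam = np.maximum(mean - df, 0.0)
    boundary = mean <= df
    lam[boundary] = 0.0

    active = ~boundary
    if not np.any(active):
        return lam

    lo = np.zeros(n_rows)
    hi = T.max(axis=1) + 10.0 * df
    # ensure the upper bracket has negative score
    for _ in range(60):
        sc_hi, _ = _score_and_deriv(T[active], df, hi[active], deriv=False)
        bad = sc_hi >= 0
        if not np.any(bad):
            break
        idx = np.flatnonzero(active)[bad]
        hi[idx] *= 2.0

    work = active.copy()
    for _ in range(max_iter):
        if not np.any(work):
            break
        idx = np.flatnonzero(work)
        l_cur = lam[idx]
        score, dscore = _score_and_deriv(T[idx], df, l_cur)
        # stop before moving: the current iterate is the accepted root
        done = (np.abs(score) < 1e-9) | (hi[idx] - lo[idx] < tol)
        if done.any():
            work[idx[done]] = False
            keep = ~done
            if not keep.any():
                continue
            idx = idx[keep]
            l_cur, score, dscore = l_cur[keep], score[keep], dscore[keep]
        # update brackets from the score sign (score decreases through root)
        pos = score > 0
        lo[idx] = np.where(pos, l_cur, lo[idx])
        hi[idx] = np.where(pos, hi[idx], l_cur)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = l_cur - score / dscore
        inside = np.isfinite(newton) & (newton > lo[idx]) & (newton < hi[idx])
        new = np.where(inside, newton, 0.5 * (lo[idx] + hi[idx]))
        small_step = inside & (np.abs(new - l_cur) < tol)
        lam[idx] = new
        work[idx[small_step]] = False
    return lam


def fit_noncentrality(sample: StatisticSample, tol: float = LAMBDA_TOL) -> NoncentralityFit:
    """Maximum-likelihood estimate of the non-centrality parameter.

    Maximizes ``sum(log f(t_s; df, lam))`` over ``lam >= 0`` where ``f`` is
    the non-central chi-square density.  The score at zero equals
    ``sum(t - df) / (2 df)``, so the estimate is exactly zero whenever the
    sample mean does not exceed the degrees of freedom.
    """
    t = sample.values
    df = sample.df
    if t.mean() <= df:
        lam_hat = 0.0
        at_boundary = True
        converged = True
        message = "score at lambda=0 nonpositive (sample mean <= df)"
    else:
        lam_hat = float(fit_noncentrality_batch(t[None, :], df, tol=tol)[0])
        at_boundary = lam_hat == 0.0
        score, _ = _score_and_deriv(t[None, :], df, np.array([lam_hat]), deriv=False)
        converged = bool(abs(score[0]) < 1e-4 * max(1.0, t.size))
        message = "" if converged else f"score {score[0]:.3g} at best iterate"
        if not converged:
            logger.warning("fit_noncentrality did not fully converge: %s", message)
    loglik = float(np.sum(ncx2_logpdf(t, df, lam_hat)))
    return NoncentralityFit(
        lambda_hat=lam_hat,
        df=df,
        sample_size=t.size,
        loglik=loglik,
        at_boundary=at_boundary,
        converged=converged,
        message=message,
    )


# ---------------------------------------------------------------------------
# power and scaling


def power_from_lambda(lam, df: int, alpha: float = 0.05):
    """Power of a chi-square test with non-centrality ``lam``.

    Returns ``1 - F(q; df, lam)`` where ``q`` is the (1 - alpha) central
    chi-square quantile and ``F`` the non-central chi-square CDF.  At
    ``lam = 0`` this is the type-I error rate ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lam must be nonnegative")
    q = stats.chi2.ppf(1.0 - alpha, df)
    out = np.where(
        lam_arr == 0.0,
        stats.chi2.sf(q, df),
        stats.ncx2.sf(q, df, np.where(lam_arr == 0.0, 1.0, lam_arr)),
    )
    if np.isscalar(lam) or np.ndim(lam) == 0:
        return float(out)
    return out


def scale_lambda(lambda_ref: float, n_ref: int, n_k: int) -> float:
    """Scale a non-centrality parameter from ``n_ref`` to ``n_k`` subjects.

    Valid when the reference design is replicated to change study size, so
    the expected information — and with it lambda — grows linearly in N.
    """
    if n_ref < 1 or n_k < 1:
        raise ValueError("study sizes must be positive integers")
    if lambda_ref < 0:
        raise ValueError("lambda_ref must be nonnegative")
    return lambda_ref * n_k / n_ref


def round_to_next_even(x: float) -> int:
    """Round a (possibly fractional) study size up to the next even integer."""
    m = int(np.ceil(x))
    return m if m % 2 == 0 else m + 1


def sizes_from_multipliers(n_ref: int, multipliers: Sequence[float]) -> np.ndarray:
    """Study-size grid from fractional multipliers of a reference size."""
    return np.array(sorted({round_to_next_even(m * n_ref) for m in multipliers}), dtype=int)


def ppe_power_curve(
    sample: StatisticSample,
    hyp: HypothesisSpec,
    n_ref: int,
    size_grid: Sequence[int],
) -> PowerCurve:
    """PPE power-versus-study-size curve.

    Fits the non-centrality parameter once from statistics simulated at the
    reference size ``n_ref``, then scales it linearly to each grid size and
    converts to power analytically.
    """
    grid = np.asarray(size_grid, dtype=int)
    if grid.size == 0:
        raise ValueError("size_grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("size_grid must be strictly increasing")
    if np.any(grid < 1):
        raise ValueError("study sizes must be positive")
    if sample.df != hyp.df:
        raise ValueError("sample.df and hyp.df disagree")

    fit = fit_noncentrality(sample)
    lambdas = np.array([scale_lambda(fit.lambda_hat, n_ref, int(n)) for n in grid])
    power = np.asarray(power_from_lambda(lambdas, hyp.df, hyp.alpha), dtype=float)
    return PowerCurve(
        reference_size=int(n_ref),
        lambda_ref=fit.lambda_hat,
        sizes=grid,
        lambdas=lambdas,
        power=np.atleast_1d(power),
        fit=fit,
    )
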