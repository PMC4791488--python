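"""Mixed-effects simulate-and-estimate engine.

Declarative model/design descriptions, dataset simulation, marginal
maximum-likelihood fits of full (tested effect free) and reduced (tested
effect fixed at its null value) models, and the LLR / Wald statistics built
from them.  Family-specific numerics live in :mod:`ncpower.families`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .families import FAMILIES
from .ppe import HypothesisSpec

__all__ = [
    "ModelSpec",
    "StudyDesign",
    "Dataset",
    "FitResult",
    "simulate_dataset",
    "loglik",
    "fit_model",
    "llr_statistic",
    "wald_statistic",
    "batch_statistics",
]

#: LLR values in [-1e-6, 0) are numerical noise from matched optima and are
#: clamped to zero; anything more negative is returned as-is for
#: preprocess_statistics to handle.
LLR_CLAMP_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-effects model description.

    ``theta`` holds the structural fixed effects (excluding the tested
    covariate effect), ``effect_size`` the tested effect used for
    simulation, and ``tested_index`` the position of the tested effect in
    the family's full natural-scale parameter vector.
    """

    family: str
    theta: tuple[float, ...]
    omega: tuple[tuple[float, ...], ...] | None
    sigma: float | None
    effect_size: float
    covariate_kind: str  # "dichotomous" | "standard_normal"
    tested_index: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            if self.family in ("pk", "pkpd"):
                raise NotImplementedError(
                    f"{self.family!r} estimation is not implemented — supply its "
                    "test statistics via a statistics file instead"
                )
            raise ValueError(f"unknown family {self.family!r}")
        if self.omega is not None:
            om = np.asarray(self.omega, dtype=float)
            if not np.allclose(om, om.T):
                raise ValueError("omega must be symmetric")
            eig = np.linalg.eigvalsh(om)
            if np.any(eig < -1e-12):
                raise ValueError("omega must be positive semi-definite")
        if self.covariate_kind not in ("dichotomous", "standard_normal"):
            raise ValueError(f"unknown covariate_kind {self.covariate_kind!r}")

    def with_effect(self, effect_size: float) -> "ModelSpec":
        return replace(self, effect_size=effect_size)


@dataclass(frozen=True)
class StudyDesign:
    """A replicable reference design: per-subject schedule and allocation."""

    n_subjects: int
    observation_times: tuple[float, ...] = ()
    censor_time: float | None = None
    dose: float | None = None
    covariate_kind: str = "dichotomous"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        t = np.asarray(self.observation_times, dtype=float)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("observation times must be nonnegative, strictly increasing")
        if self.censor_time is not None and self.censor_time <= 0:
            raise ValueError("censor_time must be positive")

    def with_n_subjects(self, n: int) -> "StudyDesign":
        return replace(self, n_subjects=int(n))

    def covariate(self, n: int, rng: np.random.Generator | None) -> np.ndarray:
        """Per-subject covariate values.

        Dichotomous covariates alternate 0/1 deterministically, giving an
        exact half/half split at any even study size; continuous covariates
        are drawn standard normal.
        """
        if self.covariate_kind == "dichotomous":
            return (np.arange(n) % 2).astype(float)
        if rng is None:
            raise ValueError("continuous covariate needs a random generator")
        return rng.standard_normal(n)


@dataclass
class Dataset:
    """Long-format simulated data; one covariate value per subject."""

    family: str
    z: np.ndarray  # per-subject covariate
    times: np.ndarray  # shared observation times (empty for tte)
    y: np.ndarray  # (n_subjects, n_times) or (n_subjects,) for tte
    event: np.ndarray | None = None  # tte only: True where the event was observed
    censor_time: float | None = None

    @property
    def n_subjects(self) -> int:
        return int(self.z.size)

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.y, dtype=float).tobytes())
        h.update(np.ascontiguousarray(self.z, dtype=float).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        if self.family == "tte":
            return pd.DataFrame(
                {
                    "id": np.arange(self.n_subjects),
                    "time": self.y,
                    "covariate": self.z,
                    "dv": self.y,
                    "cens": (~self.event).astype(int),
                }
            )
        n, j = self.y.shape
        return pd.DataFrame(
            {
                "id": np.repeat(np.arange(n), j),
                "time": np.tile(self.times, n),
                "covariate": np.repeat(self.z, j),
                "dv": self.y.ravel(),
                "cens": 0,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, family: str,
                   censor_time: float | None = None) -> "Dataset":
        frame = frame.sort_values(["id", "time"], kind="stable")
        ids = frame["id"].to_numpy()
        uniq, first = np.unique(ids, return_index=True)
        z = frame["covariate"].to_numpy()[first]
        if family == "tte":
            y = frame["dv"].to_numpy(dtype=float)
            event = frame["cens"].to_numpy(dtype=int) == 0
            return cls(family=family, z=z.astype(float), times=np.array([]),
                       y=y, event=event, censor_time=censor_time)
        times = np.unique(frame["time"].to_numpy(dtype=float))
        y = frame["dv"].to_numpy(dtype=float).reshape(uniq.size, times.size)
        return cls(family=family, z=z.astype(float), times=times, y=y)


@dataclass
class FitResult:
    """A maximum-likelihood fit of a full or reduced model."""

    theta_hat: np.ndarray
    loglik: float
    restricted: bool
    converged: bool
    n_iter: int
    data_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.theta_hat = np.asarray(self.theta_hat, dtype=float)


def _family(model: ModelSpec):
    return FAMILIES[model.family]


def simulate_dataset(model: ModelSpec, design: StudyDesign, rng_seed) -> Dataset:
    """Simulate one dataset; reproducible from the seed."""
    seed = rng_seed if isinstance(rng_seed, tuple) else (int(rng_seed),)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fam = _family(model)
    if model.family == "tte":
        z, y, event = fam.simulate(model, design, rng)
        return Dataset(family="tte", z=z, times=np.array([]), y=y, event=event,
                       censor_time=design.censor_time)
    z, t, y = fam.simulate(model, design, rng)
    return Dataset(family=model.family, z=z, times=t, y=y)


def loglik(model: ModelSpec, params: Sequence[float], data: Dataset, **kwargs) -> float:
    """Marginal log-likelihood of ``params`` (natural scale) for ``data``.

    tte and gaussian_linear are exact; binary uses adaptive Gauss-Hermite
    quadrature (default 7 nodes/dimension); count uses the Laplace
    approximation.
    """
    fam = _family(model)
    if model.family == "tte":
        return fam.loglik(params, data.z, data.y, data.event)
    return fam.loglik(params, data.z, data.times, data.y, **kwargs)


def fit_model(
    model: ModelSpec,
    data: Dataset,
    restricted: bool,
    start: Sequence[float] | None = None,
    **kwargs,
) -> FitResult:
    """Maximize the marginal likelihood over the family's free parameters.

    ``restricted=True`` fixes the tested effect at its null value (0 for
    all shipped presets).  Starting values default to the simulating
    parameters, the standard choice in simulation studies.
    """
    fam = _family(model)
    if model.family == "tte":
        theta_hat, ll, conv, n_iter = fam.fit(model, data.z, data.y, data.event,
                                              restricted, start=start, **kwargs)
    else:
        theta_hat, ll, conv, n_iter = fam.fit(model, data.z, data.times, data.y,
                                              restricted, start=start, **kwargs)
    return FitResult(
        theta_hat=theta_hat,
        loglik=ll,
        restricted=restricted,
        converged=conv,
        n_iter=n_iter,
        data_fingerprint=data.fingerprint(),
    )


def llr_statistic(full: FitResult, reduced: FitResult) -> float:
    """Likelihood-ratio statistic 2 (ll_full - ll_reduced).

    Values in [-1e-6, 0) — numerical noise from two matched optimizations —
    are clamped to zero; larger negative values (a genuinely better reduced
    fit, e.g. from a full-model convergence failure) are returned as-is so
    downstream preprocessing can apply its negative-statistic policy.
    """
    if full.data_fingerprint and reduced.data_fingerprint:
        if full.data_fingerprint != reduced.data_fingerprint:
            raise ValueError("full and reduced fits come from different datasets")
    if full.restricted or not reduced.restricted:
        raise ValueError("expected an unrestricted full fit and a restricted reduced fit")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if -LLR_CLAMP_TOL <= stat < 0.0:
        return 0.0
    return float(stat)


def wald_statistic(
    full: FitResult,
    model: ModelSpec,
    data: Dataset,
    hyp: HypothesisSpec,
    rel_step: float = 1e-4,
) -> float:
    """Wald statistic (theta_H_hat - null)^2 / Var(theta_H_hat).

    The variance comes from the inverse of the observed information matrix,
    computed by central-difference differentiation of the marginal
    log-likelihood at the estimate.
    """
    if not full.converged:
        raise ValueError("Wald statistic requires a converged full fit")
    theta = np.asarray(full.theta_hat, dtype=float)
    n = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)

    def f(p):
        return loglik(model, p, data)

    H = np.empty((n, n))
    f0 = f(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                val = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ValueError("observed information matrix is singular — "
                         "tested parameter not identifiable")
    var = cov[model.tested_index, model.tested_index]
    if not np.isfinite(var) or var <= 0:
        raise ValueError("observed information matrix is singular — "
                         "tested parameter not identifiable")
    return float((theta[model.tested_index] - hyp.null_value) ** 2 / var)


def batch_statistics(
    model: ModelSpec,
    design: StudyDesign,
    n_replicates: int,
    seed: tuple[int, ...],
    statistic: str = "llr",
    method: str | None = None,
    effect_lower: float | None = None,
) -> tuple[np.ndarray, int]:
    """Simulate/fit-full/fit-reduced statistics for many replicates.

    The tte family runs through a replicate-batched vectorized fitter;
    other families loop replicate by replicate.  Failed replicates are
    dropped and counted.  ``effect_lower`` (binary family) bounds the tested
    effect from below in the full fit, putting the null on the boundary of
    the parameter space.
    """
    if model.family == "tte":
        from .families import tte as _tte

        return _tte.batch_statistics(model, design, n_replicates, seed,
                                     statistic=statistic or "llr")
    stats_out = []
    n_failed = 0
    fit_kwargs = {}
    if method is not None and model.family == "binary":
        fit_kwargs["method"] = method
    full_kwargs = dict(fit_kwargs)
    if effect_lower is not None:
        if model.family != "binary":
            raise ValueError("effect_lower is supported for the binary family only")
        full_kwargs["effect_lower"] = effect_lower
    for r in range(n_replicates):
        data = simulate_dataset(model, design, (*seed, r))
        try:
            full = fit_model(model, data, restricted=False, **full_kwargs)
            reduced = fit_model(model, data, restricted=True, **fit_kwargs)
        except (FloatingPointError, ValueError):
            n_failed += 1
            continue
        if not (full.converged and reduced.converged):
            n_failed += 1
            continue
        if statistic == "llr":
            stats_out.append(llr_statistic(full, reduced))
        elif statistic == "wald":
            hyp = HypothesisSpec(df=1)
            stats_out.append(wald_statistic(full, model, data, hyp))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return np.asarray(stats_out, dtype=float), n_failed
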