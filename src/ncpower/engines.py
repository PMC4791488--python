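"""Statistic-generating engines.

An *engine* produces one test statistic per simulation replicate at a given
study size.  The package ships two kinds:

* distributional stubs that draw directly from (non-central) chi-square
  distributions — used to study the PPE machinery under exactly-met
  assumptions;
* :class:`SimulationEngine`, which wraps a mixed-effects model preset and
  runs the full simulate / fit-full / fit-reduced loop per replicate.

All engines derive per-replicate random streams from
``SeedSequence((seed..., replicate_index))`` so grids and runs are
reproducible and parallelizable without reseeding artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "EngineResult",
    "StatisticEngine",
    "NoncentralStubEngine",
    "ConstantEngine",
    "SimulationEngine",
]


@dataclass(frozen=True)
class EngineResult:
    """Statistics from one engine call plus the count of failed replicates."""

    values: np.ndarray
    n_failed: int = 0


def _seed_tuple(seed) -> tuple[int, ...]:
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


class StatisticEngine(Protocol):
    """Protocol for simulate-and-fit callables used by MCPE/PPE drivers."""

    df: int

    def statistics(self, n_subjects: int, n_replicates: int, seed) -> EngineResult:
        """Return ``n_replicates`` test statistics at study size ``n_subjects``."""
        ...


class NoncentralStubEngine:
    """Draws statistics directly from ncx2(df, lambda_ref * N / n_ref).

    With ``lambda_ref = 0`` this is the central chi-square null stub.  The
    idealized engine used to validate the PPE machinery when its
    distributional assumption holds exactly.
    """

    def __init__(self, df: int, lambda_ref: float, n_ref: int):
        if lambda_ref < 0:
            raise ValueError("lambda_ref must be nonnegative")
        self.df = int(df)
        self.lambda_ref = float(lambda_ref)
        self.n_ref = int(n_ref)

    def statistics(self, n_subjects: int, n_replicates: int, seed) -> EngineResult:
        lam = self.lambda_ref * n_subjects / self.n_ref
        rng = np.random.default_rng(np.random.SeedSequence(_seed_tuple(seed)))
        if lam == 0.0:
            vals = rng.chisquare(self.df, size=n_replicates)
        else:
            vals = rng.noncentral_chisquare(self.df, lam, size=n_replicates)
        return EngineResult(values=vals)


class ConstantEngine:
    """Returns a constant statistic; degenerate engine for plumbing tests."""

    def __init__(self, value: float, df: int = 1):
        self.value = float(value)
        self.df = int(df)

    def statistics(self, n_subjects: int, n_replicates: int, seed) -> EngineResult:
        return EngineResult(values=np.full(n_replicates, self.value))


class SimulationEngine:
    """Simulate datasets from a model preset and compute LLR (or Wald)
    statistics by maximum-likelihood estimation of full and reduced models.

    The time-to-event family uses a replicate-batched vectorized fitter;
    other families fit replicate by replicate.
    """

    def __init__(self, model, design, statistic: str = "llr",
                 method: str | None = None, effect_lower: float | None = None):
        from . import nlmem  # local import to avoid cycle

        self.model = model
        self.design = design
        self.statistic = statistic
        self.method = method
        self.effect_lower = effect_lower
        self.df = 1  # all shipped presets test a single fixed effect
        self._nlmem = nlmem

    def statistics(self, n_subjects: int, n_replicates: int, seed) -> EngineResult:
        design = self.design.with_n_subjects(n_subjects)
        values, n_failed = self._nlmem.batch_statistics(
            self.model,
            design,
            n_replicates,
            seed=_seed_tuple(seed),
            statistic=self.statistic,
            method=self.method,
            effect_lower=self.effect_lower,
        )
        return EngineResult(values=np.asarray(values, dtype=float), n_failed=n_failed)
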