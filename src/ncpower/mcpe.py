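"""Monte Carlo power estimation (MCPE).

The classical reference method: simulate datasets under the alternative,
refit full and reduced models, and estimate power as the fraction of
replicates whose test statistic exceeds the central chi-square critical
value.  Each replicate contributes only dichotomous information, which is
why MCPE needs substantially more replicates than PPE for the same
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ppe import HypothesisSpec, StatisticSample

__all__ = ["McpeResult", "critical_value", "mcpe_power", "mcpe_power_curve"]

logger = logging.getLogger(__name__)

#: fraction of failed replicates at a single study size above which the
#: result is flagged as unreliable.
FAILURE_FLAG_FRACTION = 0.2


@dataclass(frozen=True)
class McpeResult:
    """Rejection-rate power estimate at one study size."""

    power: float
    n_rejected: int
    n_total: int
    critical_value: float
    n_failed: int = 0
    flagged: bool = False


def critical_value(hyp: HypothesisSpec) -> float:
    """(1 - alpha) quantile of the central chi-square with ``df`` degrees
    of freedom — the rejection threshold of both LLR and Wald tests."""
    return float(stats.chi2.ppf(1.0 - hyp.alpha, hyp.df))


def mcpe_power(sample: StatisticSample, hyp: HypothesisSpec) -> McpeResult:
    """Power as the exact fraction of statistics exceeding the critical value.

    Rejection uses strict inequality; a statistic exactly equal to the
    threshold (probability zero for continuous statistics) does not reject.
    """
    if sample.df != hyp.df:
        raise ValueError("sample.df and hyp.df disagree")
    q = critical_value(hyp)
    n_total = sample.size
    n_rejected = int(np.sum(sample.values > q))
    return McpeResult(
        power=n_rejected / n_total,
        n_rejected=n_rejected,
        n_total=n_total,
        critical_value=q,
    )


def mcpe_power_curve(
    engine,
    hyp: HypothesisSpec,
    size_grid: Sequence[int],
    s_m: int,
    rng_seed: int,
) -> Mapping[int, McpeResult]:
    """MCPE power at each study size of a grid.

    ``engine`` is a simulate-and-fit callable following the
    :class:`~ncpower.engines.StatisticEngine` protocol: it produces one test
    statistic per replicate for a given study size, with per-replicate
    random streams derived from ``(rng_seed, size_index, replicate_index)``
    so results are reproducible and independent across sizes.

    Replicates whose estimation step fails are excluded from the
    denominator (power among successful fits); if more than 20 % fail at a
    size the corresponding result is flagged.
    """
    grid = np.asarray(size_grid, dtype=int)
    if grid.size == 0:
        raise ValueError("size_grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("size_grid must be strictly increasing")
    q = critical_value(hyp)
    out: dict[int, McpeResult] = {}
    for k, n_k in enumerate(grid):
        res = engine.statistics(int(n_k), s_m, seed=(rng_seed, k))
        values = np.asarray(res.values, dtype=float)
        n_failed = int(res.n_failed)
        if values.size == 0:
            raise RuntimeError(f"engine produced no usable statistics at N={n_k}")
        flagged = n_failed > FAILURE_FLAG_FRACTION * s_m
        if flagged:
            logger.warning(
                "MCPE at N=%d: %d/%d replicates failed", n_k, n_failed, s_m
            )
        n_rejected = int(np.sum(values > q))
        out[int(n_k)] = McpeResult(
            power=n_rejected / values.size,
            n_rejected=n_rejected,
            n_total=int(values.size),
            critical_value=q,
            n_failed=n_failed,
            flagged=flagged,
        )
    return out


def curve_to_frame(results: Mapping[int, McpeResult]):
    """MCPE curve as a table with columns n, power, n_rejected, n_total."""
    import pandas as pd

    sizes = sorted(results)
    return pd.DataFrame(
        {
            "n": sizes,
            "power": [results[n].power for n in sizes],
            "n_rejected": [results[n].n_rejected for n in sizes],
            "n_total": [results[n].n_total for n in sizes],
        }
    )
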