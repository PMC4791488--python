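"""Built-in model and design presets.

The registry covers the three desk-scale evaluation models (binary,
time-to-event, count) with their published parameter values and reference
designs, and the Alzheimer's disease-progression application example at
three study lengths.  ODE-based PK and PKPD models are registered by name
but have no internal estimator — their statistics must be supplied from an
external simulation-estimation run via a statistics file.
"""

from __future__ import annotations

from .nlmem import ModelSpec, StudyDesign

__all__ = ["PRESET_NAMES", "get_preset"]


def _linspace(a: float, b: float, n: int) -> tuple[float, ...]:
    step = (b - a) / (n - 1)
    return tuple(a + i * step for i in range(n))


def _build() -> dict:
    registry = {}

    # Binary: random intercept/slope logistic, dichotomous covariate on the
    # slope; N* = 110, 20 observations equally spaced on [0, 1].
    registry["binary"] = (
        ModelSpec(
            family="binary",
            theta=(-1.0, 4.0),
            omega=((0.4, 0.0), (0.0, 4.0)),
            sigma=None,
            effect_size=0.3,
            covariate_kind="dichotomous",
            tested_index=2,
            name="binary",
        ),
        StudyDesign(
            n_subjects=110,
            observation_times=_linspace(0.0, 1.0, 20),
            covariate_kind="dichotomous",
        ),
    )

    # Time-to-event: Weibull hazard, dichotomous covariate on the scale;
    # N* = 200, one event per subject censored at T = 10.
    registry["tte"] = (
        ModelSpec(
            family="tte",
            theta=(0.2, 2.0),
            omega=None,
            sigma=None,
            effect_size=0.4,
            covariate_kind="dichotomous",
            tested_index=2,
            name="tte",
        ),
        StudyDesign(
            n_subjects=200,
            observation_times=(),
            censor_time=10.0,
            covariate_kind="dichotomous",
        ),
    )

    # Count: saturating Poisson rate, continuous covariate on the rate
    # constant; N* = 160, 10 observations equally spaced on [0, 1].
    registry["count"] = (
        ModelSpec(
            family="count",
            theta=(1.0, 4.0, 2.0),
            omega=((0.09, 0.0, 0.0), (0.0, 0.09, 0.0), (0.0, 0.0, 0.09)),
            sigma=None,
            effect_size=0.3,
            covariate_kind="standard_normal",
            tested_index=3,
            name="count",
        ),
        StudyDesign(
            n_subjects=160,
            observation_times=_linspace(0.0, 1.0, 10),
            covariate_kind="standard_normal",
        ),
    )

    # Alzheimer's disease-progression trial: linear progression plus placebo
    # response, treatment effect on the progression rate; balanced two-arm
    # design, visits every 6 months, study length 12 / 18 / 24 months
    # (times in years).  100 subjects in the illustrative dataset.
    alz_model = ModelSpec(
        family="gaussian_linear",
        theta=(56.4, 4.83, -20.0, 2.77, 1.73),
        omega=((14.3, -1.2), (-1.2, 6.1)),
        sigma=7.9,
        effect_size=0.3,
        covariate_kind="dichotomous",
        tested_index=5,
        name="alzheimer",
    )
    full_visits = (0.0, 0.5, 1.0, 1.5, 2.0)
    for months in (12, 18, 24):
        visits = tuple(t for t in full_visits if t <= months / 12.0 + 1e-9)
        registry[f"alzheimer{months}"] = (
            alz_model,
            StudyDesign(
                n_subjects=100,
                observation_times=visits,
                covariate_kind="dichotomous",
            ),
        )
    return registry


_REGISTRY = _build()
PRESET_NAMES = tuple(sorted(_REGISTRY)) + ("pk", "pkpd")


def get_preset(name: str) -> tuple[ModelSpec, StudyDesign]:
    """Look up a (model, design) preset by name."""
    if name in ("pk", "pkpd"):
        raise NotImplementedError(
            f"{name!r} estimation is not implemented — supply its test "
            "statistics via a statistics file instead"
        )
    try:
        model, design = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    return model, design
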