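"""Synthetic life tables emulating the epidemiological transition.

The Siler hazard

    m(x) = a1·exp(−b1·x) + a2 + a3·exp(b3·x)

superimposes a declining infant/child component, a constant background, and
a rising (Gompertz) senescent component.  Two presets bracket the
transition: a high-mortality regime with heavy infant mortality and life
expectancy in the 30s, and a low-mortality rectangularized regime with life
expectancy in the 80s.  A panel generator interpolates the parameters
log-linearly across years — so every rate declines monotonically and e0
rises — optionally adding Poisson sampling noise at a finite exposure, and
pairs the tables with a slowly rising synthetic record-lifespan series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .lifetable import (
    AgeAtDeathDistribution,
    LifeTable,
    LifeTableError,
    build_lifetable_from_mx,
    from_counts,
)
from .panel import RecordLifespanSeries

__all__ = [
    "SilerParams",
    "SILER_HIGH_MORTALITY",
    "SILER_LOW_MORTALITY",
    "siler_mx",
    "siler_lifetable",
    "generate_transition_panel",
    "fixtures",
]


@dataclass(frozen=True)
class SilerParams:
    """Five-parameter Siler hazard; all parameters strictly positive.

    a1, b1 — infant level (per year) and decline rate; a2 — age-independent
    background rate; a3, b3 — senescent level and slope.
    """

    a1: float
    b1: float
    a2: float
    a3: float
    b3: float

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "a3", "b3"):
            if getattr(self, name) <= 0:
                raise LifeTableError(f"Siler parameter {name} must be positive")


#: pre-transition regime: q0 ≈ 0.22, e0 in the low 30s
SILER_HIGH_MORTALITY = SilerParams(a1=0.25, b1=1.1, a2=0.010, a3=3.2e-4, b3=0.085)
#: post-transition regime: q0 ≈ 0.004, e0 in the low 80s
SILER_LOW_MORTALITY = SilerParams(a1=0.004, b1=1.6, a2=5.0e-4, a3=3.5e-5, b3=0.085)


def siler_mx(params: SilerParams, ages) -> np.ndarray:
    """Siler death rates on an age grid (overflow-guarded at high ages)."""
    ages = np.asarray(ages, dtype=float)
    senescent = params.a3 * np.exp(np.minimum(params.b3 * ages, 700.0))
    return params.a1 * np.exp(-params.b1 * ages) + params.a2 + senescent


def siler_lifetable(
    params: SilerParams,
    *,
    a_top: int = 110,
    year: int = 0,
    radix: float = 100_000.0,
) -> LifeTable:
    """Noise-free life table implied by a Siler schedule on ages 0..a_top."""
    ages = np.arange(a_top + 1)
    mx = siler_mx(params, ages)
    ax = np.full(ages.size, 0.5)
    ax[0] = 0.2  # infant deaths cluster early in the first year of life
    return build_lifetable_from_mx(mx, ax, radix=radix, year=year)


def _interp_params(start: SilerParams, end: SilerParams, t: float) -> SilerParams:
    def geo(a: float, b: float) -> float:
        return float(np.exp((1 - t) * np.log(a) + t * np.log(b)))

    return SilerParams(
        a1=geo(start.a1, end.a1),
        b1=geo(start.b1, end.b1),
        a2=geo(start.a2, end.a2),
        a3=geo(start.a3, end.a3),
        b3=geo(start.b3, end.b3),
    )


def generate_transition_panel(
    start_params: SilerParams = SILER_HIGH_MORTALITY,
    end_params: SilerParams = SILER_LOW_MORTALITY,
    *,
    years: int = 50,
    populations: int = 4,
    seed: int = 0,
    stochastic: bool = False,
    exposure: float = 1e6,
    first_year: int = 1900,
    a_top: int = 110,
) -> Tuple[List[Tuple[str, str, LifeTable]], RecordLifespanSeries]:
    """Panel of life tables walking the epidemiological transition.

    Each of ``populations`` populations interpolates the Siler parameters
    log-linearly from ``start_params`` to ``end_params`` over ``years``
    calendar years, with a fixed multiplicative level jitter per population
    (drawn once from the seeded stream) so populations differ but keep the
    common trend.  With ``stochastic=True`` the observed rates are death
    counts drawn as Poisson(m(x)·exposure) divided by the exposure.  Returns
    the (population, sex, LifeTable) records plus a synthetic record-lifespan
    series rising slowly over the same years.  Deterministic given ``seed``.
    """
    if years < 2:
        raise LifeTableError("need at least two years")
    if populations < 1:
        raise LifeTableError("need at least one population")
    rng = np.random.default_rng(seed)
    # population-level frailty: common multiplicative shift of all rates
    level = np.exp(rng.normal(0.0, 0.08, size=populations))
    records: List[Tuple[str, str, LifeTable]] = []
    ages = np.arange(a_top + 1)
    ax = np.full(ages.size, 0.5)
    ax[0] = 0.2
    for p in range(populations):
        name = f"POP{p:02d}"
        for k in range(years):
            t = k / (years - 1)
            params = _interp_params(start_params, end_params, t)
            mx = siler_mx(params, ages) * level[p]
            if stochastic:
                deaths = rng.poisson(mx * exposure)
                mx = np.maximum(deaths, np.where(ages == a_top, 1, 0)) / exposure
                mx = np.where((mx == 0) & (ages == a_top), 1.0 / exposure, mx)
            lt = build_lifetable_from_mx(mx, ax.copy(), year=first_year + k)
            records.append((name, "female", lt))
    # stays above every table's top mean age at death (110 + a(110+) ~ 113)
    omega_series = {
        first_year + k: round(113.0 + 9.0 * k / (years - 1), 2) for k in range(years)
    }
    return records, RecordLifespanSeries(omega_series)


def fixtures() -> Dict[str, object]:
    """Named analytic distributions used across examples and tests.

    ``two_point(e0, omega)`` and ``degenerate(a)`` use the point-mass
    convention; ``uniform(n)`` puts equal point masses on ages 0..n−1;
    ``worked_toy`` is a three-interval table-style distribution with
    d = (0.1, 0.1, 0.8) and interval mean ages (0.3, 1.5, 7.0).
    """

    def two_point(e0: float, omega: float) -> AgeAtDeathDistribution:
        s1 = 1.0 - e0 / omega
        return from_counts([0.0, omega], [s1, 1.0 - s1], point_mass=True)

    def degenerate(a: float) -> AgeAtDeathDistribution:
        return from_counts([a], [1.0], point_mass=True)

    def uniform(n: int) -> AgeAtDeathDistribution:
        return from_counts(np.arange(n), np.ones(n), point_mass=True)

    worked_toy = from_counts(
        [0, 1, 2], [10_000, 10_000, 80_000], xbar=[0.3, 1.5, 7.0]
    )
    return {
        "two_point": two_point,
        "degenerate": degenerate,
        "uniform": uniform,
        "worked_toy": worked_toy,
    }
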