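"""Maximal-inequality benchmark and normalized lifespan-inequality indices.

Among all age-at-death distributions with a given mean ``e0`` and support in
``[0, ω]`` (ω the maximal lifespan), inequality is maximized by the two-point
distribution M(e0, ω) that puts a share ``s1 = 1 − e0/ω`` at age 0 and the
remaining share at age ω.  Normalizing any index by its value on this
benchmark,

    I*(A, ω) = I(A) / I(M(e0(A), ω)),

yields a dimensionless measure in [0, 1] of how close a population sits to
the most unequal mortality regime compatible with its own longevity.  The
normalized absolute and relative Gini indices coincide: AID* ≡ G*, and
G*(A, ω) → G(A) as ω → ∞.

Closed-form benchmark values (derived from the two-point distribution and
verified against direct evaluation in the test suite):

    AID_max = e0 (ω − e0) / ω        G_max  = (ω − e0) / ω
    σ_max   = sqrt(e0 (ω − e0))      CV_max = sqrt((ω − e0) / e0)
    e†_max  = e0 (ω − e0) / ω        H_max  = (ω − e0) / ω
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .indices import INDEX_NAMES, compute_index
from .lifetable import AgeAtDeathDistribution, LifeTable, LifeTableError, deaths_distribution

__all__ = [
    "DEFAULT_OMEGA",
    "MaxInequalityBenchmark",
    "max_inequality_distribution",
    "max_aid",
    "max_index_value",
    "normalized_index",
    "normalized_gini",
    "normalized_aid",
]

#: default maximal lifespan: the oldest reliably recorded age at death
#: (Jeanne Calment, 122.45 years, rounded down to whole years)
DEFAULT_OMEGA = 122.0


@dataclass(frozen=True)
class MaxInequalityBenchmark:
    """The inequality-maximizing two-point distribution M(e0, ω).

    A share ``s1 = 1 − e0/ω`` dies at exact age 0 and the rest at exact age
    ω (point-mass convention, so the closed forms hold exactly).
    """

    e0: float
    omega: float
    s1: float
    dist: AgeAtDeathDistribution


def _check_domain(e0: float, omega: float) -> None:
    if not (omega > 0 and math.isfinite(omega)):
        raise LifeTableError("omega must be a positive finite age")
    if e0 <= 0:
        raise LifeTableError("benchmark requires e0 > 0")
    if e0 >= omega:
        raise LifeTableError(
            f"benchmark requires e0 < omega (got e0={e0:g}, omega={omega:g}): "
            "no room for variability"
        )


def max_inequality_distribution(e0: float, omega: float = DEFAULT_OMEGA) -> MaxInequalityBenchmark:
    """Construct M(e0, ω), the most unequal distribution with mean ``e0``."""
    _check_domain(e0, omega)
    s1 = 1.0 - e0 / omega
    dist = AgeAtDeathDistribution(
        ages=[0.0, omega], d=[s1, 1.0 - s1], xbar=[0.0, omega]
    )
    return MaxInequalityBenchmark(e0=e0, omega=omega, s1=s1, dist=dist)


def max_aid(e0: float, omega: float = DEFAULT_OMEGA) -> float:
    """Maximal AID attainable at mean ``e0``: ``e0 (ω − e0) / ω`` years."""
    _check_domain(e0, omega)
    return e0 * (omega - e0) / omega


def max_index_value(name: str, e0: float, omega: float = DEFAULT_OMEGA) -> float:
    """Closed-form value of index ``name`` on the benchmark M(e0, ω)."""
    _check_domain(e0, omega)
    if name == "AID":
        return e0 * (omega - e0) / omega
    if name in ("G", "H"):
        return (omega - e0) / omega
    if name == "sigma":
        return math.sqrt(e0 * (omega - e0))
    if name == "CV":
        return math.sqrt((omega - e0) / e0)
    if name == "edagger":
        return e0 * (omega - e0) / omega
    raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")


def _dist_of(obj) -> AgeAtDeathDistribution:
    return deaths_distribution(obj) if isinstance(obj, LifeTable) else obj


def normalized_index(name: str, obj, omega: float = DEFAULT_OMEGA) -> float:
    """Normalized index I*(A, ω) = I(A) / I(M(e0(A), ω)), in [0, 1].

    ``obj`` is an age-at-death distribution, or a life table for the indices
    that need one (e†, H).  Death mass above ω is a domain error: the
    normalization assumes no one outlives the maximal lifespan.
    """
    dist = _dist_of(obj)
    if dist.max_xbar > omega + 1e-9:
        raise LifeTableError(
            f"death mass at age {dist.max_xbar:g} exceeds omega={omega:g}"
        )
    denom = max_index_value(name, dist.e0, omega)
    return compute_index(name, obj) / denom


def normalized_gini(obj, omega: float = DEFAULT_OMEGA) -> float:
    """Normalized Gini G*(A, ω) = G(A) / ((ω − e0)/ω); identical to AID*."""
    return normalized_index("G", obj, omega)


def normalized_aid(obj, omega: float = DEFAULT_OMEGA) -> float:
    """Normalized AID; equals :func:`normalized_gini` by construction."""
    return normalized_index("AID", obj, omega)
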