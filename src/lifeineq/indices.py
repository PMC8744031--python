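"""Classical lifespan-inequality indices on an age-at-death distribution.

All indices operate on the death-share vector ``d`` and the within-interval
mean ages ``x̄`` carried by :class:`~lifeineq.lifetable.AgeAtDeathDistribution`;
``e†`` and the life-table entropy additionally need the remaining life
expectancies of a full :class:`~lifeineq.lifetable.LifeTable`.

The absolute Gini (average inter-individual difference)

    AID(A) = ½ Σ_x Σ_y d_x d_y |x̄ − ȳ|

is half the expected absolute difference between the ages at death of two
randomly drawn individuals, in years.  The relative Gini G = AID / e0 is
dimensionless and lies in [0, 1].
"""

from __future__ import annotations

import numpy as np

from .lifetable import AgeAtDeathDistribution, LifeTable, LifeTableError, deaths_distribution

__all__ = [
    "aid",
    "gini",
    "std_dev",
    "cv",
    "e_dagger",
    "entropy",
    "INDEX_NAMES",
    "compute_index",
]

#: identifiers accepted by :func:`compute_index` and the decomposition/CLI layers
INDEX_NAMES = ("AID", "G", "sigma", "CV", "edagger", "H")


def aid(dist: AgeAtDeathDistribution, *, method: str = "fast") -> float:
    """Average inter-individual difference (absolute Gini), in years.

    ``method='exact'`` evaluates the O(n²) double sum directly;
    ``method='fast'`` uses the sorted cumulative form, which is algebraically
    identical (both are kept so one can audit the other).
    """
    d = dist.d
    x = dist.xbar
    if method == "exact":
        return 0.5 * float(d @ np.abs(np.subtract.outer(x, x)) @ d)
    if method != "fast":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ws = d[order]
    # AID = sum_{i<j} w_i w_j (x_j - x_i); split by cumulative weights
    cum = np.cumsum(ws)
    below = cum - ws          # weight strictly before i in sorted order
    above = cum[-1] - cum     # weight strictly after i
    return float(np.sum(xs * ws * below) - np.sum(xs * ws * above))


def gini(dist: AgeAtDeathDistribution) -> float:
    """Relative Gini coefficient G = AID / e0, dimensionless in [0, 1]."""
    e0 = dist.e0
    if e0 <= 0:
        raise LifeTableError("Gini undefined for zero mean age at death")
    return aid(dist) / e0


def std_dev(dist: AgeAtDeathDistribution) -> float:
    """Standard deviation of age at death, in years."""
    e0 = dist.e0
    return float(np.sqrt(dist.d @ (dist.xbar - e0) ** 2))


def cv(dist: AgeAtDeathDistribution) -> float:
    """Coefficient of variation of age at death, dimensionless."""
    e0 = dist.e0
    if e0 <= 0:
        raise LifeTableError("CV undefined for zero mean age at death")
    return std_dev(dist) / e0


def _remaining_expectancy_at(lt: LifeTable, at: str) -> np.ndarray:
    """e(x) evaluated at the mean age at death of each interval."""
    if at == "integer":
        return lt.ex.copy()
    if at != "interpolated":
        raise ValueError(f"unknown evaluation mode {at!r}")
    # linear interpolation of the ex column at x + ax; clamped at the top
    return np.interp(lt.ages + lt.ax, lt.ages.astype(float), lt.ex)


def e_dagger(lt: LifeTable, *, at: str = "interpolated") -> float:
    """Average remaining life expectancy lost at death (e†), in years.

    e† = Σ_x d_x · e(x̄_x) with e(·) the table's remaining life expectancy,
    linearly interpolated at the mean age at death x + a(x) of each interval
    (``at='integer'`` evaluates e(x) at the integer interval start instead).
    """
    dist = deaths_distribution(lt)
    return float(dist.d @ _remaining_expectancy_at(lt, at))


def entropy(lt: LifeTable, *, at: str = "interpolated") -> float:
    """Life-table entropy H = e† / e0, dimensionless."""
    e0 = deaths_distribution(lt).e0
    if e0 <= 0:
        raise LifeTableError("entropy undefined for zero mean age at death")
    return e_dagger(lt, at=at) / e0


def compute_index(name: str, obj) -> float:
    """Evaluate index ``name`` on a distribution or life table.

    ``AID``, ``G``, ``sigma`` and ``CV`` accept either object (a life table
    is reduced to its age-at-death distribution); ``edagger`` and ``H``
    require a full life table.
    """
    if name in ("edagger", "H"):
        if not isinstance(obj, LifeTable):
            raise TypeError(f"index {name!r} requires a LifeTable")
        return e_dagger(obj) if name == "edagger" else entropy(obj)
    dist = deaths_distribution(obj) if isinstance(obj, LifeTable) else obj
    if name == "AID":
        return aid(dist)
    if name == "G":
        return gini(dist)
    if name == "sigma":
        return std_dev(dist)
    if name == "CV":
        return cv(dist)
    raise ValueError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
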