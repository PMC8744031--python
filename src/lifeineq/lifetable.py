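"""Period life tables and age-at-death distributions.

A :class:`LifeTable` holds one single-year-of-age period life table with the
standard columns (mx, qx, ax, lx, dx, Lx, Tx, ex) on an integer age grid
``0 .. A_top`` whose last interval ``[A_top, inf)`` is open.  A
:class:`AgeAtDeathDistribution` is the normalized death-share vector ``d``
together with the within-interval mean ages at death ``x̄ = x + a(x)``; it is
the object every inequality index consumes.

Two within-interval conventions exist and are never mixed silently:

* life-table convention — ``x̄ = x + a(x)``, with ``a(x)`` from the table
  (default 0.5 when no table is available);
* point-mass convention — ``x̄ = x`` exactly, used for worked examples and
  for the two-point maximal-inequality benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LifeTable",
    "AgeAtDeathDistribution",
    "LifeTableError",
    "build_lifetable_from_mx",
    "deaths_distribution",
    "from_counts",
]

_SUM_TOL = 1e-9


class LifeTableError(ValueError):
    """Raised for invalid life-table or distribution inputs."""


@dataclass
class LifeTable:
    """One period life table on integer ages ``0 .. A_top`` (open last interval).

    Parameters
    ----------
    year : int
        Calendar year of the table.
    ages : ndarray of int
        Contiguous grid starting at 0; the last age opens the interval
        ``[A_top, inf)``.
    mx, qx, ax, lx, dx, Lx, Tx, ex : ndarray of float
        Standard life-table columns.  ``lx`` is radix-scaled; ``qx`` of the
        open interval is 1; ``ax`` of the open interval follows the
        ``1/mx`` convention.
    """

    year: int
    ages: np.ndarray
    mx: np.ndarray
    qx: np.ndarray
    ax: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float = field(default=100_000.0)

    def __post_init__(self) -> None:
        for name in ("ages", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.ages = self.ages.astype(int)
        n = self.ages.size
        if n < 2:
            raise LifeTableError("life table needs at least two age groups")
        if self.ages[0] != 0 or np.any(np.diff(self.ages) != 1):
            raise LifeTableError("ages must be contiguous integers starting at 0")
        for name in ("mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"):
            if getattr(self, name).shape != (n,):
                raise LifeTableError(f"column {name!r} has wrong length")
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check the life-table identities; raise :class:`LifeTableError`."""
        finite = np.isfinite(self.qx)
        if np.any((self.qx[finite] < -_SUM_TOL) | (self.qx[finite] > 1 + 1e-6)):
            raise LifeTableError("qx out of [0, 1]")
        if not np.isclose(self.qx[-1], 1.0, atol=1e-6):
            raise LifeTableError("qx at the open interval must be 1")
        if np.any(np.diff(self.lx) > 1e-9 * max(self.lx[0], 1.0)):
            raise LifeTableError("lx must be non-increasing")
        if np.any(self.dx < -1e-9 * max(self.lx[0], 1.0)):
            raise LifeTableError("dx must be non-negative")
        # printed HMD tables carry integer-rounded counts, so allow the
        # accumulated rounding of ~one unit per age group
        if abs(self.dx.sum() - self.lx[0]) > 2e-3 * max(self.lx[0], 1.0):
            raise LifeTableError("sum of dx must equal the radix l0")

    # -- derived quantities ----------------------------------------------

    @property
    def a_top(self) -> int:
        """Starting age of the open interval."""
        return int(self.ages[-1])

    @property
    def e0(self) -> float:
        """Life expectancy at birth from the ex column."""
        return float(self.ex[0])

    def deaths_distribution(self) -> "AgeAtDeathDistribution":
        return deaths_distribution(self)


@dataclass
class AgeAtDeathDistribution:
    """Normalized death shares ``d`` with within-interval mean ages ``x̄``.

    ``e0`` (the mean age at death) is always ``sum(d * xbar)`` by
    construction.  ``ages`` may be fractional for analytic constructions
    such as the two-point benchmark.
    """

    ages: np.ndarray
    d: np.ndarray
    xbar: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.xbar = np.asarray(self.xbar, dtype=float)
        if not (self.ages.shape == self.d.shape == self.xbar.shape):
            raise LifeTableError("ages, d and xbar must have equal length")
        if np.any(self.d < -_SUM_TOL):
            raise LifeTableError("death shares must be non-negative")
        if abs(self.d.sum() - 1.0) > _SUM_TOL:
            raise LifeTableError("death shares must sum to 1")
        if np.any(self.xbar < 0):
            raise LifeTableError("mean ages at death must be non-negative")

    @property
    def e0(self) -> float:
        """Mean age at death (life expectancy at birth)."""
        return float(self.d @ self.xbar)

    @property
    def max_xbar(self) -> float:
        return float(self.xbar[self.d > 0].max())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "d": self.d, "xbar": self.xbar})


# -- constructors ---------------------------------------------------------


def deaths_distribution(lt: LifeTable) -> AgeAtDeathDistribution:
    """Age-at-death distribution of a life table: ``d = dx / sum(dx)``.

    Within-interval mean ages are ``x̄ = x + a(x)``, including the open
    interval where ``a`` follows the ``1/mx`` convention, so the mass of the
    open group sits at a finite age.
    """
    total = lt.dx.sum()
    if total <= 0:
        raise LifeTableError("all-zero death column: distribution undefined")
    d = lt.dx / total
    xbar = lt.ages + lt.ax
    return AgeAtDeathDistribution(ages=lt.ages.astype(float), d=d, xbar=xbar)


def from_counts(
    ages,
    weights,
    xbar=None,
    *,
    point_mass: bool = False,
) -> AgeAtDeathDistribution:
    """Distribution from raw death counts or shares.

    ``xbar`` defaults to ``ages + 0.5`` (mid-interval) or, with
    ``point_mass=True``, to exactly ``ages``.
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise LifeTableError("negative death weight")
    total = weights.sum()
    if total <= 0:
        raise LifeTableError("weights must have positive sum")
    if xbar is None:
        xbar = ages if point_mass else ages + 0.5
    return AgeAtDeathDistribution(ages=ages, d=weights / total, xbar=np.asarray(xbar, float))


def build_lifetable_from_mx(
    mx,
    ax=None,
    *,
    radix: float = 100_000.0,
    year: int = 0,
) -> LifeTable:
    """Construct a full life table from age-specific death rates.

    For closed single-year intervals ``qx = mx / (1 + (1 - ax) mx)``; the
    open interval has ``qx = 1`` and ``ax = 1/mx``.  ``ax`` defaults to 0.5
    at every closed age.

    Parameters
    ----------
    mx : array-like
        Death rates on ages ``0 .. A_top``; the last entry is the open
        interval and must be strictly positive.
    ax : array-like, optional
        Mean years lived in the interval by those dying in it; the last
        entry is ignored (recomputed as ``1/mx``).
    """
    mx = np.asarray(mx, dtype=float)
    if mx.ndim != 1 or mx.size < 2:
        raise LifeTableError("mx must be a 1-D vector of length >= 2")
    if np.any(mx < 0):
        raise LifeTableError("negative death rate")
    if mx[-1] <= 0:
        raise LifeTableError("open-interval mx must be positive")
    n = mx.size
    if ax is None:
        ax = np.full(n, 0.5)
    ax = np.asarray(ax, dtype=float).copy()
    if ax.shape != (n,):
        raise LifeTableError("ax must match mx in length")
    if np.any((ax[:-1] < 0) | (ax[:-1] > 1)):
        raise LifeTableError("closed-interval ax must lie in [0, 1]")
    ax[-1] = 1.0 / mx[-1]

    qx = np.empty(n)
    qx[:-1] = mx[:-1] / (1.0 + (1.0 - ax[:-1]) * mx[:-1])
    np.clip(qx[:-1], 0.0, 1.0, out=qx[:-1])
    qx[-1] = 1.0

    lx = np.empty(n)
    lx[0] = radix
    lx[1:] = radix * np.cumprod(1.0 - qx[:-1])
    dx = lx * qx
    Lx = np.empty(n)
    Lx[:-1] = lx[1:] + ax[:-1] * dx[:-1]
    Lx[-1] = lx[-1] * ax[-1]
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / np.where(lx > 0, lx, 1.0), 0.0)
    ages = np.arange(n)
    return LifeTable(
        year=year, ages=ages, mx=mx, qx=qx, ax=ax, lx=lx, dx=dx,
        Lx=Lx, Tx=Tx, ex=ex, radix=radix,
    )
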