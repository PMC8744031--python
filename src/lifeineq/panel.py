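"""Panel analytics for the longevity–lifespan-inequality nexus.

Operates on tidy panels of (population, sex, year) records carrying life
expectancy and the inequality indices: the e0/ω-record ratio series, rolling
Pearson correlations between longevity and inequality in 5-year windows,
joint-change quadrant shares between consecutive years, and the
maximal-inequality curves that bound every observed scatter point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .indices import INDEX_NAMES, compute_index
from .lifetable import LifeTable, LifeTableError, deaths_distribution
from .normalization import max_index_value, normalized_gini

__all__ = [
    "PanelRecord",
    "RecordLifespanSeries",
    "build_panel",
    "ratio_series",
    "rolling_correlation",
    "rolling_correlation_series",
    "joint_change_quadrants",
    "QuadrantShares",
    "max_inequality_curve",
]

PANEL_INDICES = INDEX_NAMES + ("Gstar",)


@dataclass(frozen=True)
class PanelRecord:
    """All indices of one population-sex-year cell."""

    population: str
    sex: str
    year: int
    e0: float
    omega: float
    indices: Mapping[str, float]


@dataclass
class RecordLifespanSeries:
    """Maximal observed lifespan by year — a non-decreasing step series.

    Lookup at a year returns the record standing in that year, i.e. the
    value at the largest series year not exceeding it.
    """

    values: Dict[int, float]
    _years: np.ndarray = field(init=False, repr=False)
    _omegas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.values:
            raise LifeTableError("empty record-lifespan series")
        years = np.array(sorted(self.values), dtype=int)
        omegas = np.array([self.values[y] for y in years], dtype=float)
        if np.any(np.diff(omegas) < 0):
            raise LifeTableError("record lifespans must be non-decreasing over years")
        self._years = years
        self._omegas = omegas

    def omega_at(self, year: int) -> float:
        idx = np.searchsorted(self._years, year, side="right") - 1
        if idx < 0:
            raise LifeTableError(f"year {year} precedes the record series start")
        return float(self._omegas[idx])

    @classmethod
    def from_csv(cls, path) -> "RecordLifespanSeries":
        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(float))))


OmegaPolicy = Union[float, RecordLifespanSeries]


def build_panel(
    tables: Iterable[Tuple[str, str, LifeTable]],
    omega_policy: OmegaPolicy = 122.0,
) -> pd.DataFrame:
    """Compute every index for each (population, sex, year) life table.

    ``omega_policy`` is either a fixed ω in years or a
    :class:`RecordLifespanSeries` giving the year-specific record lifespan.
    Returns a tidy frame sorted by (population, sex, year) with one column
    per index; ω must exceed each table's e0 (and top mean age at death).
    """
    rows = []
    offending = []
    for population, sex, lt in tables:
        dist = deaths_distribution(lt)
        omega = (
            omega_policy.omega_at(lt.year)
            if isinstance(omega_policy, RecordLifespanSeries)
            else float(omega_policy)
        )
        if omega <= dist.max_xbar:
            offending.append((population, sex, lt.year, omega, dist.max_xbar))
            continue
        row = {
            "population": population,
            "sex": sex,
            "year": lt.year,
            "e0": dist.e0,
            "omega": omega,
        }
        for name in INDEX_NAMES:
            row[name] = compute_index(name, lt if name in ("edagger", "H") else dist)
        row["Gstar"] = normalized_gini(dist, omega)
        rows.append(row)
    if offending:
        detail = "; ".join(
            f"{p}/{s}/{y}: omega={o:g} <= max age at death {m:g}"
            for p, s, y, o, m in offending
        )
        raise LifeTableError(f"omega policy violates the support bound: {detail}")
    if not rows:
        raise LifeTableError("no life tables supplied")
    return (
        pd.DataFrame(rows)
        .sort_values(["population", "sex", "year"], kind="stable")
        .reset_index(drop=True)
    )


def ratio_series(
    panel: pd.DataFrame, record_series: RecordLifespanSeries
) -> pd.DataFrame:
    """e0 / ω_record per record — the longevity-to-record ratio over time."""
    out = panel[["population", "sex", "year", "e0"]].copy()
    out["omega_record"] = [record_series.omega_at(int(y)) for y in out["year"]]
    out["ratio"] = out["e0"] / out["omega_record"]
    return out


def rolling_correlation(
    panel: pd.DataFrame,
    index: str,
    center_year: int,
    window: int = 5,
) -> Optional[float]:
    """Pearson r between e0 and an index over all observations in a year window.

    The window spans ``center_year ± (window−1)//2`` and pools every
    population-sex-year observation it contains.  Returns None when fewer
    than 3 points exist or either variable has zero variance.
    """
    half = (window - 1) // 2
    sub = panel[(panel["year"] >= center_year - half) & (panel["year"] <= center_year + half)]
    if len(sub) < 3:
        return None
    x = sub["e0"].to_numpy(float)
    y = sub[index].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def rolling_correlation_series(
    panel: pd.DataFrame, index: str, window: int = 5
) -> pd.Series:
    """Rolling correlation at every center year present in the panel."""
    years = sorted(panel["year"].unique())
    vals = {y: rolling_correlation(panel, index, int(y), window) for y in years}
    return pd.Series(vals, name=f"corr_e0_{index}", dtype=float)


@dataclass(frozen=True)
class QuadrantShares:
    """Joint-direction shares of consecutive-year changes in (e0, index).

    Quadrant keys pair the e0 direction with the index direction; shares are
    over the ``n_classified`` pairs with movement in both variables, while
    ``n_ties`` counts pairs where at least one change is exactly zero
    (reported, not assigned to a quadrant).
    """

    shares: Mapping[Tuple[str, str], float]
    n_classified: int
    n_ties: int

    @property
    def desirable(self) -> float:
        """Share of changes with rising e0 and falling inequality."""
        return self.shares[("e0_up", "index_down")]


def joint_change_quadrants(
    panel: pd.DataFrame,
    index: str,
    from_year: int = 1980,
    *,
    change: str = "relative",
) -> QuadrantShares:
    """Classify consecutive-year joint changes of e0 and an index into quadrants.

    For every (population, sex) and consecutive year pair from ``from_year``
    on, the change of each variable is ``(v₂ − v₁)/v₁`` (or the log ratio
    with ``change='log'``); the four quadrant shares are computed over pairs
    where both variables moved.
    """
    if change not in ("relative", "log"):
        raise ValueError("change must be 'relative' or 'log'")
    counts = {
        (a, b): 0 for a in ("e0_up", "e0_down") for b in ("index_up", "index_down")
    }
    ties = 0
    n_pairs = 0
    for _, grp in panel.groupby(["population", "sex"], sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        e0 = grp["e0"].to_numpy(float)
        val = grp[index].to_numpy(float)
        for k in range(len(grp) - 1):
            if years[k + 1] != years[k] + 1 or years[k] < from_year:
                continue
            n_pairs += 1
            if change == "relative":
                de = (e0[k + 1] - e0[k]) / e0[k]
                dv = (val[k + 1] - val[k]) / val[k]
            else:
                de = np.log(e0[k + 1] / e0[k])
                dv = np.log(val[k + 1] / val[k])
            if de == 0 or dv == 0:
                ties += 1
                continue
            key = (
                "e0_up" if de > 0 else "e0_down",
                "index_up" if dv > 0 else "index_down",
            )
            counts[key] += 1
    if n_pairs == 0:
        raise LifeTableError("no consecutive-year pairs at or after from_year")
    classified = sum(counts.values())
    shares = {
        k: (v / classified if classified else 0.0) for k, v in counts.items()
    }
    return QuadrantShares(shares=shares, n_classified=classified, n_ties=ties)


def max_inequality_curve(
    index: str, omega: float, e0_grid: Sequence[float]
) -> np.ndarray:
    """Maximal attainable index value at each e0 of a grid (the bounding curve).

    For AID this is the inverted parabola e0(ω−e0)/ω peaking at ω/2; for G
    the straight line (ω−e0)/ω falling to 0 at e0 = ω.
    """
    e0_grid = np.asarray(e0_grid, dtype=float)
    return np.array([max_index_value(index, e0, omega) for e0 in e0_grid])
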