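"""Per-year life-table reconstruction from assessed abundance and catch.

For each stock-year the module derives the demographic schedule feeding
the Euler-Lotka equation:

* an overall recruitment rate ``RPS_y = R_y / SSB_{y-b}`` (recruits per
  kg of spawning biomass, offset by the recruit age b),
* recruits attributed to each spawning age class in proportion to its
  spawning biomass, giving a per-spawner fecundity ``f_{y,a}``; under
  biomass-proportional attribution this reduces algebraically to
  ``W_a * RPS_{y+1}`` at mature ages (fecundity is offset by one year —
  recruits observed in year y+1 enter the renewal equation for year y),
* fishing mortality ``F = C / N`` as an annual proportion, total
  mortality ``Z = F + M``, survival ``l = 1 - Z``,
* survivorship-to-age as the running product of survival within the
  year's schedule (a period life table), with survivorship to the first
  assessed age fixed at 1, both including fishing (``s_real``, under Z)
  and excluding it (``s_dem``, under M only).

Pathological cells are handled explicitly rather than silently: Z >= 1
clamps survival to a small positive floor with a logged warning, and a
mature age class with zero spawners gets zero fecundity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stock import StockTable, StockTableError

__all__ = [
    "LifeTable",
    "DegenerateInputError",
    "ScheduleRangeError",
    "recruitment_rate",
    "fecundity_at_age",
    "mortality_at_age",
    "survivorship_to_age",
    "build_life_table",
    "schedule_years",
    "backfill_young_ages",
]

log = logging.getLogger(__name__)

#: lower clamp for survival when Z >= 1 (keeps survivorship positive)
L_FLOOR = 1e-6


class DegenerateInputError(ValueError):
    """Zero spawning biomass (or similar) makes the schedule undefined."""


class ScheduleRangeError(ValueError):
    """The offset years required by the fecundity schedule are unobserved."""


@dataclass
class LifeTable:
    """One stock-year's reconstructed demographic schedule.

    ``s_real`` is survivorship under total mortality Z = F + M;
    ``s_dem`` is the counterfactual under natural mortality only.  Both
    equal 1 at the first assessed age.  ``fec`` is per-spawner fecundity
    (recruits attributed per mature fish).
    """

    stock_id: str
    year: int
    ages: np.ndarray
    rps: float
    rpa: np.ndarray
    ns: np.ndarray
    fec: np.ndarray
    f_mort: np.ndarray
    m_nat: np.ndarray
    z: np.ndarray
    l: np.ndarray
    s_real: np.ndarray
    s_dem: np.ndarray
    nu: int | None
    omega: int
    delta_x: float = 1.0

    def survivorship(self, include_fishing: bool) -> np.ndarray:
        return self.s_real if include_fishing else self.s_dem

    def with_rates(self, m_nat: np.ndarray, fec: np.ndarray) -> "LifeTable":
        """Rebuild the table from adjusted natural mortality and fecundity,
        keeping the observed fishing mortality fixed."""
        z = self.f_mort + m_nat
        l = clamp_survival(1.0 - z, self.stock_id, self.year, warn=False)
        l_dem = clamp_survival(1.0 - m_nat, self.stock_id, self.year, warn=False)
        mature = fec > 0
        nu = int(self.ages[mature][0]) if mature.any() else None
        return LifeTable(
            stock_id=self.stock_id,
            year=self.year,
            ages=self.ages,
            rps=self.rps,
            rpa=self.rpa,
            ns=self.ns,
            fec=fec,
            f_mort=self.f_mort,
            m_nat=m_nat,
            z=z,
            l=l,
            s_real=survivorship_to_age(l),
            s_dem=survivorship_to_age(l_dem),
            nu=nu,
            omega=self.omega,
        )


def clamp_survival(l: np.ndarray, stock_id: str, year: int, warn: bool = True) -> np.ndarray:
    """Clamp survival into [L_FLOOR, 1]; warn with coordinates when Z >= 1."""
    if warn and np.any(l <= 0):
        log.warning(
            "%s year %s: total mortality >= 1 at %d age(s); survival clamped to %g",
            stock_id, year, int(np.sum(l <= 0)), L_FLOOR,
        )
    return np.clip(l, L_FLOOR, 1.0)


def recruitment_rate(stock: StockTable, year: int) -> float:
    """Recruits per kg of spawning biomass: R_y / SSB_{y-b}."""
    b = stock.first_age
    iy = stock.year_index(year)
    lag = iy - b
    if lag < 0:
        raise ScheduleRangeError(
            f"{stock.stock_id}: recruitment rate for {year} needs SSB in "
            f"{year - b}, before the observed span"
        )
    ssb_lag = float(stock.ssb()[lag])
    if ssb_lag <= 0:
        raise DegenerateInputError(
            f"{stock.stock_id}: zero spawning biomass in {year - b}"
        )
    return float(stock.N[iy, 0]) / ssb_lag


def fecundity_at_age(stock: StockTable, year: int, basis: str = "per_spawner") -> np.ndarray:
    """Per-age fecundity for year ``year`` (recruits attributed per spawner).

    Recruits observed in year y+1 are attributed to the spawning age
    classes of year y+1-b in proportion to their spawning biomass, then
    divided by the spawner numbers of that same year.  Ages with zero
    spawners contribute no attributed recruits and get fecundity 0.

    ``basis='per_capita'`` multiplies by the maturity ogive, turning
    recruits-per-spawner into recruits-per-individual.
    """
    if basis not in ("per_spawner", "per_capita"):
        raise ValueError(f"unknown fecundity basis {basis!r}")
    b = stock.first_age
    iy = stock.year_index(year)
    i_next = iy + 1
    i_spawn = iy + 1 - b
    if i_next >= stock.n_years or i_spawn < 0:
        raise ScheduleRangeError(
            f"{stock.stock_id}: fecundity for {year} needs years "
            f"{year + 1 - b} and {year + 1}, outside the observed span"
        )
    ns_check = stock.spawners()[i_spawn]
    if not np.any(ns_check > 0):
        log.warning("%s year %s: no spawners at any age; fecundity all 0",
                    stock.stock_id, year)
        return np.zeros(stock.n_ages)
    rps_next = recruitment_rate(stock, int(stock.years[i_next]))
    rpa = stock.ssb_at_age()[i_spawn] * rps_next
    ns = stock.spawners()[i_spawn]
    if np.any((ns == 0) & (rpa > 0)):
        log.warning(
            "%s year %s: recruits attributed to an age with zero spawners; "
            "fecundity set to 0 there", stock.stock_id, year,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fec = np.where(ns > 0, rpa / np.where(ns > 0, ns, 1.0), 0.0)
    if basis == "per_capita":
        fec = fec * stock.Mat[i_spawn]
    return fec


def mortality_at_age(
    stock: StockTable, year: int, l_floor: float = L_FLOOR
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(F, Z, l) for one year: F = C/N, Z = F + M, l = 1 - Z clamped."""
    iy = stock.year_index(year)
    N, C = stock.N[iy], stock.C[iy]
    if np.any(N < 0) or np.any(C < 0):
        raise StockTableError(f"{stock.stock_id}: negative catch or abundance")
    if np.any((N == 0) & (C == 0)):
        log.warning(
            "%s year %s: empty age class; F set to 0 there", stock.stock_id, year
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(N > 0, C / np.where(N > 0, N, 1.0), 0.0)
    Z = F + stock.M[iy]
    l = 1.0 - Z
    if np.any(l <= 0):
        log.warning(
            "%s year %s: Z >= 1 at %d age(s); survival clamped to %g",
            stock.stock_id, year, int(np.sum(l <= 0)), l_floor,
        )
    l = np.clip(l, l_floor, 1.0)
    return F, Z, l


def survivorship_to_age(l: np.ndarray) -> np.ndarray:
    """Cumulative survivorship: s[0] = 1, s[a] = s[a-1] * l[a-1]."""
    l = np.asarray(l, dtype=float)
    if l.size == 0:
        raise ValueError("empty survival vector")
    return np.concatenate([[1.0], np.cumprod(l[:-1])])


def build_life_table(
    stock: StockTable,
    year: int,
    basis: str = "per_spawner",
    l_floor: float = L_FLOOR,
) -> LifeTable:
    """Assemble the complete schedule for one stock-year."""
    b = stock.first_age
    iy = stock.year_index(year)
    i_spawn = iy + 1 - b
    fec = fecundity_at_age(stock, year, basis=basis)
    F, Z, l = mortality_at_age(stock, year, l_floor=l_floor)
    m_nat = stock.M[iy].copy()
    l_dem = np.clip(1.0 - m_nat, l_floor, 1.0)
    rps_next = recruitment_rate(stock, int(stock.years[iy + 1]))
    mature = fec > 0
    return LifeTable(
        stock_id=stock.stock_id,
        year=int(year),
        ages=stock.ages.copy(),
        rps=rps_next,
        rpa=stock.ssb_at_age()[i_spawn] * rps_next,
        ns=stock.spawners()[i_spawn].copy(),
        fec=fec,
        f_mort=F,
        m_nat=m_nat,
        z=Z,
        l=l,
        s_real=survivorship_to_age(l),
        s_dem=survivorship_to_age(l_dem),
        nu=int(stock.ages[mature][0]) if mature.any() else None,
        omega=stock.max_age,
    )


def schedule_years(stock: StockTable) -> np.ndarray:
    """Calendar years with a complete fecundity schedule.

    Year y needs year y+1 (for the incoming recruits) and year y+1-b
    (for the spawners that produced them), so the usable years are
    ``first + b - 1 .. last - 1``.
    """
    b = stock.first_age
    lo = stock.years[0] + max(b - 1, 0)
    return np.arange(lo, stock.years[-1])


def backfill_young_ages(stock: StockTable) -> StockTable:
    """Back-calculate abundance down to age 1 for stocks whose first
    assessed age is older.

    Each synthetic cell is filled along the cohort,
    ``N[y-1, a-1] = N[y, a] / (1 - M[y-1, a-1])``, using the youngest
    available natural mortality for the unassessed ages.  Catch at the
    synthetic ages is 0, maturity 0 (they add survivorship, not
    spawners), and weight copies the youngest assessed age.  Trailing
    years whose source cell lies beyond the span repeat the last
    back-calculated value at that age.  A sensitivity tool: survivorship
    to the first assessed age is no longer assumed to be 1.
    """
    b = stock.first_age
    if b <= 1:
        log.info("%s: first age is already 1; backfill is a no-op", stock.stock_id)
        return stock
    n_new = b - 1
    ny = stock.n_years

    def widen(mat: np.ndarray, fill) -> np.ndarray:
        left = np.full((ny, n_new), fill, dtype=float)
        return np.hstack([left, mat])

    M_young = stock.M[:, [0]]  # youngest available M, per year
    M_new = np.hstack([np.repeat(M_young, n_new, axis=1), stock.M])
    N_new = widen(stock.N, np.nan)
    for j in range(n_new - 1, -1, -1):  # ages b-1 down to 1, column index j
        for iy in range(ny):
            if iy + 1 < ny:
                N_new[iy, j] = N_new[iy + 1, j + 1] / (1.0 - M_new[iy, j])
            else:
                N_new[iy, j] = N_new[iy - 1, j]  # repeat last back-calculated value
    C_new = widen(stock.C, 0.0)
    W_new = np.hstack([np.repeat(stock.W[:, [0]], n_new, axis=1), stock.W])
    Mat_new = widen(stock.Mat, 0.0)
    return StockTable(
        stock_id=stock.stock_id,
        species=stock.species,
        region=stock.region,
        years=stock.years.copy(),
        ages=np.arange(1, stock.max_age + 1),
        N=N_new,
        C=C_new,
        W=W_new,
        Mat=Mat_new,
        M=M_new,
        meta={**stock.meta, "backfilled_ages": list(range(1, b))},
    )
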