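"""Cohort lifetime reproductive success and generation length.

A cohort born into the first assessed age class in year ``c`` is tracked
along the diagonal of the per-year schedules: at age ``x`` it sits in
year ``c + x - alpha``.  Only complete cohorts — those for which every
age from the first (alpha) to the terminal age (omega) has a reconstructed
schedule within the observed span — are scored.

Lifetime reproductive success R0 = sum_x s_x f_x counts the spawners one
spawner produces over a lifetime; 1 means exact replacement.  Under the
assumed 50:50 sex ratio, spawners-per-spawner equals females-per-female,
so no extra factor of one half is applied: the per-spawner fecundity and
the per-spawner accounting use the same units and the sex-ratio factor
cancels.  Generation length LG = sum_x x s_x f_x / sum_x s_x f_x is the
mean age of the spawners producing the cohort's recruits.  Both come in
a fishing-inclusive variant (survivorship under Z) and a fishing-excluded
one (survivorship under M only, observed fecundity kept) — the latter
does not fully erase fishing, whose imprint remains in the age structure
behind the observed schedules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .stock import StockTable

__all__ = [
    "CohortRecord",
    "extract_complete_cohorts",
    "lifetime_reproductive_success",
    "generation_length",
    "cohorts_frame",
]

log = logging.getLogger(__name__)


class IncompleteCohortError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


@dataclass
class CohortRecord:
    """One complete cohort's diagonal schedules and derived metrics."""

    stock_id: str
    cohort_year: int
    ages: np.ndarray
    s_x_with_f: np.ndarray
    s_x_no_f: np.ndarray
    f_x: np.ndarray
    r0_with_f: float
    r0_no_f: float
    lg_with_f: float | None
    lg_no_f: float | None
    complete: bool = True


def _survivorship(l_diag: np.ndarray) -> np.ndarray:
    return np.concatenate([[1.0], np.cumprod(l_diag[:-1])])


def extract_complete_cohorts(
    stock: StockTable, schedules: dict[int, LifeTable]
) -> list[CohortRecord]:
    """Assemble every cohort whose full age span is covered by ``schedules``.

    ``schedules`` maps calendar year to that year's (typically calibrated)
    life table, e.g. ``LambdaSeries.life_tables``.  The cohort labelled
    ``c`` occupies cell (year c, age alpha) and runs to
    (year c + omega - alpha, age omega); it is complete when every one of
    those years has a schedule.
    """
    ages = stock.ages
    alpha, omega = int(ages[0]), int(ages[-1])
    span = omega - alpha
    records: list[CohortRecord] = []
    for c in sorted(schedules):
        needed = [c + k for k in range(span + 1)]
        if not all(y in schedules for y in needed):
            continue
        f_x = np.empty(span + 1)
        l_real = np.empty(span + 1)
        l_dem = np.empty(span + 1)
        for k, y in enumerate(needed):
            lt = schedules[y]
            f_x[k] = lt.fec[k]
            l_real[k] = lt.l[k]
            l_dem[k] = np.clip(1.0 - lt.m_nat[k], 0.0, 1.0)
        s_with = _survivorship(l_real)
        s_no = _survivorship(l_dem)
        rec = CohortRecord(
            stock_id=stock.stock_id,
            cohort_year=int(c),
            ages=ages.copy(),
            s_x_with_f=s_with,
            s_x_no_f=s_no,
            f_x=f_x,
            r0_with_f=float(np.sum(s_with * f_x)),
            r0_no_f=float(np.sum(s_no * f_x)),
            lg_with_f=_lg(ages, s_with, f_x),
            lg_no_f=_lg(ages, s_no, f_x),
        )
        records.append(rec)
    if not records:
        log.info("%s: no complete cohorts in the observed span", stock.stock_id)
    return records


def _lg(ages: np.ndarray, s: np.ndarray, f: np.ndarray) -> float | None:
    w = s * f
    tot = w.sum()
    if tot <= 0:
        return None
    return float(np.sum(ages * w) / tot)


def lifetime_reproductive_success(c: CohortRecord, include_fishing: bool) -> float:
    """R0 = sum_x s_x f_x on the requested survivorship basis."""
    if not c.complete:
        raise IncompleteCohortError(f"{c.stock_id} cohort {c.cohort_year} is incomplete")
    s = c.s_x_with_f if include_fishing else c.s_x_no_f
    return float(np.sum(s * c.f_x))


def generation_length(c: CohortRecord, include_fishing: bool) -> float:
    """LG = sum_x x s_x f_x / sum_x s_x f_x (mean age of spawning)."""
    if not c.complete:
        raise IncompleteCohortError(f"{c.stock_id} cohort {c.cohort_year} is incomplete")
    s = c.s_x_with_f if include_fishing else c.s_x_no_f
    lg = _lg(c.ages, s, c.f_x)
    if lg is None:
        raise UndefinedMetricError(
            f"{c.stock_id} cohort {c.cohort_year}: no reproduction, LG undefined"
        )
    return lg


def cohorts_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Tabular summary: one row per cohort."""
    return pd.DataFrame(
        {
            "stock_id": [r.stock_id for r in records],
            "cohort_year": [r.cohort_year for r in records],
            "r0_f": [r.r0_with_f for r in records],
            "r0_nof": [r.r0_no_f for r in records],
            "lg_f": [r.lg_with_f for r in records],
            "lg_nof": [r.lg_no_f for r in records],
            "complete": [r.complete for r in records],
        }
    )
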