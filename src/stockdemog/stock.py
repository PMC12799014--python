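"""Age-structured stock-assessment tables.

A :class:`StockTable` is the common input of every downstream stage: a
year x age panel of assessed numbers, fishery removals (numbers), mean
weight, maturity proportion and annual natural-mortality proportion for
one stock.  Mortality is proportional (a fraction of fish dying per
year), not instantaneous, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StockTable", "StockTableError", "read_stock_table", "write_stock_table"]

#: column order of the long-format CSV interchange schema
CSV_COLUMNS = [
    "stock_id",
    "species",
    "region",
    "year",
    "age",
    "abundance_n",
    "catch_n",
    "weight_kg",
    "maturity_prop",
    "m_annual",
]


class StockTableError(ValueError):
    """Raised when a stock table violates its structural invariants."""


@dataclass
class StockTable:
    """Year x age panel of stock-assessment output for one stock.

    All matrices are year-major with shape ``(len(years), len(ages))``.

    Attributes
    ----------
    N : numbers-at-age
    C : catch-at-age in numbers
    W : mean weight-at-age (kg)
    Mat : proportion mature at age
    M : annual natural mortality proportion at age
    """

    stock_id: str
    species: str
    region: str
    years: np.ndarray
    ages: np.ndarray
    N: np.ndarray
    C: np.ndarray
    W: np.ndarray
    Mat: np.ndarray
    M: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        for name in ("N", "C", "W", "Mat", "M"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def first_age(self) -> int:
        """Recruit age b (youngest assessed age class)."""
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        """Terminal age omega; no plus-group beyond it."""
        return int(self.ages[-1])

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    def year_index(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise StockTableError(
                f"{self.stock_id}: year {year} outside observed span "
                f"{self.years[0]}-{self.years[-1]}"
            )
        return int(year - self.years[0])

    # -- derived series ----------------------------------------------------

    def total_abundance(self) -> np.ndarray:
        """Total numbers per year, summed over age classes."""
        return self.N.sum(axis=1)

    def ssb_at_age(self) -> np.ndarray:
        """Spawning biomass per (year, age) in kg: W * Mat * N."""
        return self.W * self.Mat * self.N

    def ssb(self) -> np.ndarray:
        """Spawning stock biomass per year (kg)."""
        return self.ssb_at_age().sum(axis=1)

    def spawners(self) -> np.ndarray:
        """Numbers of mature fish per (year, age): Mat * N."""
        return self.Mat * self.N

    # -- validation --------------------------------------------------------

    def validate(self) -> "StockTable":
        shape = (len(self.years), len(self.ages))
        for name in ("N", "C", "W", "Mat", "M"):
            mat = getattr(self, name)
            if mat.shape != shape:
                raise StockTableError(
                    f"{self.stock_id}: {name} has shape {mat.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(mat)):
                bad = np.argwhere(~np.isfinite(mat))[0]
                raise StockTableError(
                    f"{self.stock_id}: non-finite {name} at year "
                    f"{self.years[bad[0]]}, age {self.ages[bad[1]]}"
                )
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise StockTableError(f"{self.stock_id}: years must be consecutive")
        if np.any(np.diff(self.ages) != 1):
            raise StockTableError(f"{self.stock_id}: ages must be consecutive")
        self._check_range("N", self.N >= 0, "abundance must be >= 0")
        self._check_range("C", self.C >= 0, "catch must be >= 0")
        self._check_range("W", self.W > 0, "weight must be > 0")
        self._check_range("Mat", (self.Mat >= 0) & (self.Mat <= 1), "maturity must be in [0,1]")
        self._check_range("M", (self.M >= 0) & (self.M < 1), "natural mortality must be in [0,1)")
        # cannot remove more fish than were assessed to exist
        self._check_range("C", self.C <= self.N * (1 + 1e-12), "catch exceeds abundance")
        return self

    def _check_range(self, name: str, ok: np.ndarray, msg: str) -> None:
        if not np.all(ok):
            bad = np.argwhere(~ok)
            coords = ", ".join(
                f"(year {self.years[i]}, age {self.ages[j]})" for i, j in bad[:5]
            )
            raise StockTableError(f"{self.stock_id}: {msg} at {coords}")

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame, one row per (year, age)."""
        yy, aa = np.meshgrid(self.years, self.ages, indexing="ij")
        return pd.DataFrame(
            {
                "stock_id": self.stock_id,
                "species": self.species,
                "region": self.region,
                "year": yy.ravel(),
                "age": aa.ravel(),
                "abundance_n": self.N.ravel(),
                "catch_n": self.C.ravel(),
                "weight_kg": self.W.ravel(),
                "maturity_prop": self.Mat.ravel(),
                "m_annual": self.M.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StockTable":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise StockTableError(f"missing columns: {missing}")
        stock_ids = df["stock_id"].unique()
        if len(stock_ids) != 1:
            raise StockTableError(
                f"expected a single stock per table, found {list(stock_ids)}"
            )
        df = df.sort_values(["year", "age"])
        years = np.sort(df["year"].unique())
        ages = np.sort(df["age"].unique())
        shape = (len(years), len(ages))
        if len(df) != shape[0] * shape[1]:
            raise StockTableError(
                f"{stock_ids[0]}: panel is not rectangular "
                f"({len(df)} rows for {shape[0]} years x {shape[1]} ages)"
            )

        def mat(col: str) -> np.ndarray:
            return df[col].to_numpy(dtype=float).reshape(shape)

        return cls(
            stock_id=str(stock_ids[0]),
            species=str(df["species"].iloc[0]),
            region=str(df["region"].iloc[0]),
            years=years,
            ages=ages,
            N=mat("abundance_n"),
            C=mat("catch_n"),
            W=mat("weight_kg"),
            Mat=mat("maturity_prop"),
            M=mat("m_annual"),
        )


def write_stock_table(stocks, path) -> None:
    """Write one or more stock tables to a long-format CSV."""
    if isinstance(stocks, StockTable):
        stocks = [stocks]
    pd.concat([s.to_frame() for s in stocks]).to_csv(path, index=False)


def read_stock_table(path) -> list[StockTable]:
    """Read all stocks from a long-format CSV; every table is validated."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise StockTableError(f"{path}: missing columns {missing}")
    return [StockTable.from_frame(g) for _, g in df.groupby("stock_id", sort=True)]
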