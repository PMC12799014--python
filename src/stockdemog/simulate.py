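"""Synthetic age-structured stock generator and exact hand-checkable fixtures.

The generator forward-simulates a single stock by cohort under
proportional mortality: survivors to the next age are
``N[y+1, a+1] = N[y, a] * (1 - M[a] - F[a])`` and the terminal age class
simply dies (no plus group).  Recruitment is proportional to spawning
biomass ``b`` years earlier, with mean-corrected lognormal variability
and an independent Bernoulli chance of a large recruitment event — the
pattern of infrequent very strong year classes that real assessed stocks
display.  Catch is generated as ``F * N`` with no mid-year timing
adjustment, consistent with treating fishing mortality as a simple
annual proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .stock import StockTable, StockTableError

__all__ = [
    "SimConfig",
    "SimulationError",
    "generate_stock",
    "default_config",
    "replacement_rps",
    "make_stationary_fixture",
    "make_geometric_fixture",
    "make_trajectory_fixture",
    "read_config",
    "write_config",
]


class SimulationError(RuntimeError):
    """Raised when forward simulation produces non-finite abundance."""


@dataclass
class SimConfig:
    """Parameters of the synthetic stock simulator.

    Per-age vectors run over ages ``first_age .. max_age`` inclusive.
    ``recruits_per_kg_mean`` is the expected number of recruits produced
    per kilogram of spawning biomass; recruitment noise is lognormal with
    coefficient of variation ``recruitment_cv``, multiplied by
    ``large_event_multiplier`` with probability ``large_event_prob`` in
    any year.  Both noise sources are mean-corrected so the expectation
    stays at ``recruits_per_kg_mean``: infrequent strong year classes
    make the distribution right-skewed without making the stock trend.
    """

    n_years: int = 40
    first_age: int = 1
    max_age: int = 10
    recruits_per_kg_mean: float = 0.05
    recruitment_cv: float = 0.6
    large_event_prob: float = 0.1
    large_event_multiplier: float = 8.0
    m_at_age: np.ndarray = field(default_factory=lambda: np.full(10, 0.2))
    f_selectivity: np.ndarray = field(default_factory=lambda: np.zeros(10))
    weight_at_age: np.ndarray = field(default_factory=lambda: np.arange(1.0, 11.0))
    maturity_at_age: np.ndarray = field(default_factory=lambda: np.ones(10))
    initial_abundance: float = 1e6
    seed: int = 0
    stock_id: str = "SIM"
    species: str = "synthetic"
    region: str = "synthetic"

    @property
    def n_ages(self) -> int:
        return self.max_age - self.first_age + 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.first_age, self.max_age + 1)

    def validate(self) -> "SimConfig":
        for name in ("m_at_age", "f_selectivity", "weight_at_age", "maturity_at_age"):
            vec = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, vec)
            if vec.shape != (self.n_ages,):
                raise ValueError(
                    f"{name} has length {len(vec)}, expected {self.n_ages} "
                    f"(ages {self.first_age}..{self.max_age})"
                )
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not (0 < self.first_age <= self.max_age):
            raise ValueError("need 0 < first_age <= max_age")
        if np.any(self.m_at_age < 0) or np.any(self.m_at_age >= 1):
            raise ValueError("m_at_age must lie in [0, 1)")
        if np.any(self.f_selectivity < 0) or np.any(self.f_selectivity >= 1):
            raise ValueError("f_selectivity must lie in [0, 1)")
        if np.any(self.m_at_age + self.f_selectivity >= 1):
            raise ValueError("m_at_age + f_selectivity must stay below 1 at every age")
        if np.any(self.weight_at_age <= 0):
            raise ValueError("weight_at_age must be positive")
        if np.any((self.maturity_at_age < 0) | (self.maturity_at_age > 1)):
            raise ValueError("maturity_at_age must lie in [0, 1]")
        if not (0 <= self.large_event_prob <= 1):
            raise ValueError("large_event_prob must lie in [0, 1]")
        if self.large_event_multiplier < 1:
            raise ValueError("large_event_multiplier must be >= 1")
        if self.recruitment_cv < 0 or self.recruits_per_kg_mean <= 0:
            raise ValueError("recruitment parameters must be positive")
        if self.initial_abundance <= 0:
            raise ValueError("initial_abundance must be positive")
        return self

    def spawning_weight(self) -> np.ndarray:
        """kg of spawning biomass contributed per fish at age: W * Mat."""
        return self.weight_at_age * self.maturity_at_age


def replacement_rps(config: SimConfig) -> float:
    """Recruits per kg of SSB at which the fished stock exactly replaces itself.

    Solves ``1 = rps * sum_a s_a W_a Mat_a`` with survivorship under total
    mortality M + F; a stock simulated at this rate with no process noise
    is stationary.
    """
    l = 1.0 - config.m_at_age - config.f_selectivity
    s = np.concatenate([[1.0], np.cumprod(l[:-1])])
    denom = float(np.sum(s * config.weight_at_age * config.maturity_at_age))
    if denom <= 0:
        raise ValueError("no spawning biomass per recruit; check maturity/weights")
    return 1.0 / denom


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-condition default: a 40-year, 10-age stock fished at moderate
    age-selective rates, fluctuating around replacement.

    Natural mortality 0.2/yr at all ages, fishing selectivity ramping from
    0 to 0.25/yr by age 4, weight increasing with age, knife-edge-ish
    maturity ogive centred at age 3, lognormal recruitment with CV 0.6 and
    an 8x large event with probability 0.1/yr.  ``recruits_per_kg_mean``
    defaults to the replacement rate so simulated stocks wander around
    their initial abundance rather than trending.
    """
    ages = np.arange(1, 11)
    cfg = SimConfig(
        n_years=40,
        first_age=1,
        max_age=10,
        recruitment_cv=0.6,
        large_event_prob=0.1,
        large_event_multiplier=8.0,
        m_at_age=np.full(10, 0.2),
        f_selectivity=np.minimum(0.25, 0.25 * np.maximum(ages - 1, 0) / 3.0),
        weight_at_age=0.05 * ages**1.5 + 0.1,
        maturity_at_age=1.0 / (1.0 + np.exp(-2.0 * (ages - 3.0))),
        initial_abundance=1e6,
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    if "recruits_per_kg_mean" not in overrides:
        cfg.recruits_per_kg_mean = replacement_rps(cfg)
    return cfg.validate()


def _stable_age_structure(config: SimConfig) -> np.ndarray:
    l = 1.0 - config.m_at_age - config.f_selectivity
    return np.concatenate([[1.0], np.cumprod(l[:-1])])


def generate_stock(config: SimConfig) -> StockTable:
    """Forward-simulate one stock; deterministic given ``config.seed``.

    The initial year is seeded with the stable age structure implied by
    the mortality schedule scaled to ``initial_abundance`` recruits, and
    spawning biomass before the first simulated year is held at its
    initial value so early recruitments are well defined.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ny, na = config.n_years, config.n_ages
    b = config.first_age
    F = config.f_selectivity
    M = config.m_at_age
    surv = 1.0 - M - F

    N = np.zeros((ny, na))
    N[0] = config.initial_abundance * _stable_age_structure(config)
    ssb0 = float(np.sum(N[0] * config.spawning_weight()))

    sigma = np.sqrt(np.log1p(config.recruitment_cv**2))
    # mean of the Bernoulli event mixture, divided out to keep E[R|SSB] fixed
    event_mean = 1.0 + config.large_event_prob * (config.large_event_multiplier - 1.0)
    for y in range(1, ny):
        N[y, 1:] = N[y - 1, :-1] * surv[:-1]
        lag = y - b
        ssb_lag = ssb0 if lag < 0 else float(np.sum(N[lag] * config.spawning_weight()))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if sigma > 0 else 1.0
        event = (
            config.large_event_multiplier
            if config.large_event_prob > 0 and rng.random() < config.large_event_prob
            else 1.0
        )
        N[y, 0] = ssb_lag * config.recruits_per_kg_mean * noise * event / event_mean
        if not np.all(np.isfinite(N[y])):
            raise SimulationError(f"non-finite abundance in simulation year {y}")

    C = N * F[np.newaxis, :]
    return StockTable(
        stock_id=config.stock_id,
        species=config.species,
        region=config.region,
        years=np.arange(2001, 2001 + ny),
        ages=config.ages,
        N=N,
        C=C,
        W=np.tile(config.weight_at_age, (ny, 1)),
        Mat=np.tile(config.maturity_at_age, (ny, 1)),
        M=np.tile(config.m_at_age, (ny, 1)),
    )


# ---------------------------------------------------------------------------
# Exact fixtures
# ---------------------------------------------------------------------------

#: the stationary reference stock: ages 1-3, constant columns, knife-edge
#: maturity at age 2, internally self-consistent (R0 under fishing = 1).
_STAT = {
    "N": np.array([1000.0, 800.0, 400.0]),
    "W": np.array([1.0, 2.0, 4.0]),
    "Mat": np.array([0.0, 1.0, 1.0]),
    "M": np.array([0.2, 0.2, 0.2]),
    "F": np.array([0.0, 0.3, 0.3]),
}


def make_stationary_fixture(n_years: int = 10, start_year: int = 2001) -> StockTable:
    """Stationary stock with every year identical.

    N=[1000, 800, 400], W=[1, 2, 4] kg, Mat=[0, 1, 1], M=0.2 at all ages,
    F=[0, 0.3, 0.3] hence C=[0, 240, 120]; SSB = 3200 kg and 1000 recruits
    per year, so the recruitment rate is exactly 0.3125 recruits/kg and
    the fished cohort exactly replaces itself.
    """
    ny = n_years
    return StockTable(
        stock_id="FIX-STAT",
        species="synthetic",
        region="synthetic",
        years=np.arange(start_year, start_year + ny),
        ages=np.array([1, 2, 3]),
        N=np.tile(_STAT["N"], (ny, 1)),
        C=np.tile(_STAT["N"] * _STAT["F"], (ny, 1)),
        W=np.tile(_STAT["W"], (ny, 1)),
        Mat=np.tile(_STAT["Mat"], (ny, 1)),
        M=np.tile(_STAT["M"], (ny, 1)),
    )


def make_trajectory_fixture(
    totals, stock_id: str = "FIX-TRAJ", start_year: int = 2001
) -> StockTable:
    """Stock whose assessed total abundance follows ``totals`` exactly.

    The age composition is the stationary fixture's stable structure
    rescaled each year, so every StockTable invariant holds while the
    totals trace an arbitrary positive trajectory.  Useful for exercising
    the abundance-matching calibration against known year-to-year ratios.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.ndim != 1 or len(totals) < 2 or np.any(totals <= 0):
        raise ValueError("totals must be a 1-D positive sequence of length >= 2")
    props = _STAT["N"] / _STAT["N"].sum()
    ny = len(totals)
    N = totals[:, None] * props[None, :]
    return StockTable(
        stock_id=stock_id,
        species="synthetic",
        region="synthetic",
        years=np.arange(start_year, start_year + ny),
        ages=np.array([1, 2, 3]),
        N=N,
        C=N * _STAT["F"][None, :],
        W=np.tile(_STAT["W"], (ny, 1)),
        Mat=np.tile(_STAT["Mat"], (ny, 1)),
        M=np.tile(_STAT["M"], (ny, 1)),
    )


def make_geometric_fixture(ratio: float, n_years: int = 10) -> StockTable:
    """Stock whose total abundance grows (or shrinks) by ``ratio`` each year."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    totals = 1000.0 * ratio ** np.arange(n_years)
    return make_trajectory_fixture(totals, stock_id=f"FIX-GEOM-{ratio:g}")


# ---------------------------------------------------------------------------
# Plain-text config round trip
# ---------------------------------------------------------------------------

_VEC_FIELDS = {"m_at_age", "f_selectivity", "weight_at_age", "maturity_at_age"}


def write_config(config: SimConfig, path) -> None:
    """Write a SimConfig as key = value lines; vectors are comma-separated."""
    with open(path, "w") as fh:
        for key, val in asdict(config).items():
            if key in _VEC_FIELDS:
                val = ",".join(repr(float(v)) for v in val)
            fh.write(f"{key} = {val}\n")


def read_config(path) -> SimConfig:
    """Read a SimConfig written by :func:`write_config`."""
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in _VEC_FIELDS:
                kwargs[key] = np.array([float(v) for v in val.split(",")])
            elif key in ("n_years", "first_age", "max_age", "seed"):
                kwargs[key] = int(val)
            elif key in ("stock_id", "species", "region"):
                kwargs[key] = val
            else:
                kwargs[key] = float(val)
    return SimConfig(**kwargs).validate()
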