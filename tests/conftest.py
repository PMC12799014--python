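import numpy as np
import pytest

import stockdemog as sd


@pytest.fixture(scope="session")
def fix_stat():
    """10-year stationary reference stock (ages 1-3, constant columns)."""
    return sd.make_stationary_fixture(n_years=10)


@pytest.fixture(scope="session")
def fix_stat_series(fix_stat):
    """Calibrated growth-rate series of the stationary fixture."""
    return sd.lambda_series(fix_stat)


@pytest.fixture(scope="session")
def fix_stat_lt(fix_stat):
    """One year's life table of the stationary fixture."""
    return sd.build_life_table(fix_stat, 2003)


@pytest.fixture(scope="session")
def default_stock():
    """A 40-year stock generated under the default study conditions."""
    return sd.generate_stock(sd.default_config(seed=7))


def stationary_config(**overrides):
    """SimConfig reproducing the stationary fixture via the simulator."""
    cfg = sd.SimConfig(
        n_years=8,
        first_age=1,
        max_age=3,
        m_at_age=np.array([0.2, 0.2, 0.2]),
        f_selectivity=np.array([0.0, 0.3, 0.3]),
        weight_at_age=np.array([1.0, 2.0, 4.0]),
        maturity_at_age=np.array([0.0, 1.0, 1.0]),
        recruitment_cv=0.0,
        large_event_prob=0.0,
        recruits_per_kg_mean=0.3125,
        initial_abundance=1000.0,
        seed=0,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg.validate()


def random_life_table(rng, max_ages=12):
    """Random valid (ages, survivorship, fecundity) schedule for oracle tests."""
    k = int(rng.integers(3, max_ages))
    ages = np.arange(1, k + 1)
    l = rng.uniform(0.2, 0.95, k)
    fec = np.where(rng.random(k) < 0.3, 0.0, rng.uniform(0.05, 5.0, k))
    if not fec.any():
        fec[-1] = 1.0
    s = np.concatenate([[1.0], np.cumprod(l[:-1])])
    return ages, l, s, fec


def leslie_dominant_eigenvalue(ages, l, fec):
    """Independent oracle: dominant eigenvalue of the Leslie matrix with
    top-row fertilities ``fec`` and subdiagonal survival ``l``."""
    k = len(ages)
    L = np.zeros((k, k))
    L[0, :] = fec
    L[np.arange(1, k), np.arange(k - 1)] = l[:-1]
    return float(np.max(np.abs(np.linalg.eigvals(L))))
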