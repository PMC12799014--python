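"""Density dependence of the annual growth rate.

Annual growth rates are modelled against relative abundance (each year's
total abundance as a proportion of the stock's observed maximum) with a
hierarchical penalized-spline regression on the log scale:

    log lambda_ij = beta0 + g(prop_ij) + u_j + g_j(prop_ij) + eps_ij

where ``g`` is a global cubic smooth, ``u_j`` ridge-penalized per-stock
intercepts (random effects), and ``g_j`` per-stock smooth deviations
sharing a single penalty (their whole coefficient vector is shrunk, so
they behave as random curves).  Smoothing parameters are chosen by
generalized cross-validation; pointwise intervals come from the Bayesian
posterior covariance of the penalized fit.  Gaussian errors on the log
scale are the operational form of a lognormal response.

Life-table reconstructions constrain the fitted surface: at the year of
maximum abundance the growth rate cannot exceed 1, at the minimum it
cannot fall below 1, and at 50% (25%) of the maximum it is capped at 2
(4) — the curve is therefore expected to decline as abundance rises.
Per-stock curves are summarized at three anchors: the stock's own
minimum observed proportion, 40% of maximum, and the maximum itself;
the 40% anchor is undefined for stocks that never dropped to 40%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .stock import StockTable

__all__ = [
    "DDObservation",
    "DDFit",
    "abundance_proportion",
    "dd_observations",
    "fit_dd_gam",
    "lambda_at_anchors",
    "anchors_frame",
]

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class DDObservation:
    """One stock-year point: relative abundance and growth rate."""

    stock_id: str
    prop: float
    lam: float
    year: int = 0


class DDFitError(RuntimeError):
    pass


def abundance_proportion(stock: StockTable) -> np.ndarray:
    """Per-year total abundance as a proportion of the observed maximum."""
    totals = stock.total_abundance()
    peak = totals.max()
    if peak <= 0:
        raise ValueError(f"{stock.stock_id}: all-zero abundance")
    return totals / peak


def dd_observations(stocks, series_list, basis: str = "real") -> pd.DataFrame:
    """Join calibrated growth-rate series with relative abundance.

    ``basis`` selects lambda_real or lambda_dem as the response.
    """
    frames = []
    for stock, series in zip(stocks, series_list):
        props = abundance_proportion(stock)
        idx = np.array([stock.year_index(y) for y in series.years])
        lam = series.lambda_real if basis == "real" else series.lambda_dem
        frames.append(
            pd.DataFrame(
                {
                    "stock_id": stock.stock_id,
                    "year": series.years,
                    "prop": props[idx],
                    "lam": lam,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _bspline_basis(k: int):
    """Cubic B-spline basis with ``k`` functions on [0, 1]; returns an
    evaluator x -> (n, k) design block."""
    if k < 4:
        raise ValueError("need at least 4 basis functions for a cubic spline")
    interior = np.linspace(0, 1, k - 2)[1:-1]
    knots = np.r_[[0.0] * 4, interior, [1.0] * 4]

    def design(x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        return BSpline.design_matrix(x, knots, 3).toarray()

    return design


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


@dataclass
class DDFit:
    """Fitted hierarchical smooth with per-stock curves and anchors."""

    basis: str
    stock_ids: list
    beta: np.ndarray
    cov: np.ndarray
    sigma2: float
    edf: float
    gcv: float
    smoothing: tuple
    min_props: dict
    _design_global: object
    _design_stock: object
    _center_global: np.ndarray
    _center_stock: np.ndarray
    _k_global: int
    _k_stock: int

    # -- design rows -------------------------------------------------------

    def _row_global(self, prop: np.ndarray) -> np.ndarray:
        prop = np.atleast_1d(np.asarray(prop, dtype=float))
        X = np.zeros((len(prop), len(self.beta)))
        X[:, 0] = 1.0
        X[:, 1 : 1 + self._k_global] = self._design_global(prop) - self._center_global
        return X

    def _row_stock(self, stock_id, prop: np.ndarray) -> np.ndarray:
        if stock_id not in self.stock_ids:
            raise KeyError(f"stock {stock_id!r} not in fit")
        j = self.stock_ids.index(stock_id)
        X = self._row_global(prop)
        base = 1 + self._k_global
        X[:, base + j] = 1.0  # stock intercept
        sbase = base + len(self.stock_ids) + j * self._k_stock
        X[:, sbase : sbase + self._k_stock] = (
            self._design_stock(np.atleast_1d(prop)) - self._center_stock
        )
        return X

    # -- predictions -------------------------------------------------------

    def global_curve(self, prop) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Population-level lambda with pointwise 95% interval."""
        X = self._row_global(prop)
        mu = X @ self.beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return np.exp(mu), np.exp(mu - Z95 * se), np.exp(mu + Z95 * se)

    def stock_curve(self, stock_id, prop) -> np.ndarray:
        """Per-stock lambda (global smooth + stock deviation)."""
        X = self._row_stock(stock_id, prop)
        return np.exp(X @ self.beta)


def fit_dd_gam(
    obs: pd.DataFrame,
    basis: str = "real",
    k_global: int = 10,
    k_stock: int = 5,
    grid: np.ndarray | None = None,
) -> DDFit:
    """Fit the hierarchical smooth of log(lambda) on relative abundance.

    ``obs`` needs columns stock_id, prop, lam.  Smoothing parameters for
    the global smooth, the stock intercepts and the shared stock-smooth
    penalty are selected jointly by GCV over a log-spaced grid.
    """
    obs = pd.DataFrame(obs)
    if np.any(obs["lam"] <= 0):
        raise ValueError("growth rates must be positive")
    if np.any((obs["prop"] <= 0) | (obs["prop"] > 1)):
        raise ValueError("proportions must lie in (0, 1]")
    stock_ids = sorted(obs["stock_id"].unique())
    if len(stock_ids) < 2:
        raise DDFitError("need at least 2 stocks to separate global and stock curves")
    counts = obs.groupby("stock_id").size()
    if (counts < 10).any():
        log.warning(
            "stocks with fewer than 10 observations: %s",
            list(counts[counts < 10].index),
        )

    y = np.log(obs["lam"].to_numpy(dtype=float))
    prop = obs["prop"].to_numpy(dtype=float)
    n = len(y)

    design_g = _bspline_basis(k_global)
    design_s = _bspline_basis(k_stock)
    Bg = design_g(prop)
    Bs = design_s(prop)
    center_g = Bg.mean(axis=0, keepdims=True)
    center_s = Bs.mean(axis=0, keepdims=True)
    Bg = Bg - center_g
    Bs = Bs - center_s

    n_stocks = len(stock_ids)
    j_of = obs["stock_id"].map({s: j for j, s in enumerate(stock_ids)}).to_numpy()
    p = 1 + k_global + n_stocks + n_stocks * k_stock
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    X[:, 1 : 1 + k_global] = Bg
    X[np.arange(n), 1 + k_global + j_of] = 1.0
    sbase = 1 + k_global + n_stocks
    for j in range(n_stocks):
        rows = j_of == j
        X[rows, sbase + j * k_stock : sbase + (j + 1) * k_stock] = Bs[rows]

    P_g = _diff_penalty(k_global)
    P_s = _diff_penalty(k_stock) + np.eye(k_stock)  # shrink the whole deviation

    def penalty(lam_g, lam_u, lam_s) -> np.ndarray:
        S = np.zeros((p, p))
        S[1 : 1 + k_global, 1 : 1 + k_global] = lam_g * P_g + 1e-9 * np.eye(k_global)
        iu = slice(1 + k_global, 1 + k_global + n_stocks)
        S[iu, iu] = 0.0
        S[np.arange(1 + k_global, 1 + k_global + n_stocks),
          np.arange(1 + k_global, 1 + k_global + n_stocks)] = lam_u
        for j in range(n_stocks):
            blk = slice(sbase + j * k_stock, sbase + (j + 1) * k_stock)
            S[blk, blk] = lam_s * P_s
        return S

    XtX = X.T @ X
    Xty = X.T @ y
    if grid is None:
        grid = 10.0 ** np.arange(-1.0, 4.1, 1.25)
    best = None
    for lam_g in grid:
        for lam_u in grid:
            for lam_s in grid:
                S = penalty(lam_g, lam_u, lam_s)
                try:
                    c = cho_factor(XtX + S, lower=True)
                except np.linalg.LinAlgError:
                    continue
                beta = cho_solve(c, Xty)
                edf = float(np.trace(cho_solve(c, XtX)))
                rss = float(np.sum((y - X @ beta) ** 2))
                denom = max(n - edf, 1e-8)
                gcv = n * rss / denom**2
                if best is None or gcv < best[0]:
                    best = (gcv, lam_g, lam_u, lam_s, beta, c, edf, rss)
    if best is None:
        raise DDFitError("penalized fit singular at every smoothing level")
    gcv, lam_g, lam_u, lam_s, beta, c, edf, rss = best
    sigma2 = rss / max(n - edf, 1.0)
    cov = sigma2 * cho_solve(c, np.eye(p))

    min_props = {s: float(obs.loc[obs["stock_id"] == s, "prop"].min()) for s in stock_ids}
    return DDFit(
        basis=basis,
        stock_ids=stock_ids,
        beta=beta,
        cov=cov,
        sigma2=sigma2,
        edf=edf,
        gcv=gcv,
        smoothing=(lam_g, lam_u, lam_s),
        min_props=min_props,
        _design_global=design_g,
        _design_stock=design_s,
        _center_global=center_g,
        _center_stock=center_s,
        _k_global=k_global,
        _k_stock=k_stock,
    )


def lambda_at_anchors(fit: DDFit, stock_id, min_prop: float | None = None) -> dict:
    """Per-stock lambda at its minimum observed proportion, at 40% of the
    maximum, and at the maximum, plus the pairwise differences.

    The 40% anchor is missing when the stock never dropped to 40% of its
    maximum.  Positive differences mean the growth rate increases as
    abundance declines (compensation).
    """
    if min_prop is None:
        min_prop = fit.min_props[stock_id]
    lam_min = float(fit.stock_curve(stock_id, min_prop)[0])
    lam_max = float(fit.stock_curve(stock_id, 1.0)[0])
    lam_40 = float(fit.stock_curve(stock_id, 0.40)[0]) if min_prop <= 0.40 else np.nan
    return {
        "stock_id": stock_id,
        "min_prop": float(min_prop),
        "lam_min": lam_min,
        "lam_40": lam_40,
        "lam_max": lam_max,
        "d_min_40": lam_min - lam_40,
        "d_min_max": lam_min - lam_max,
        "d_40_max": lam_40 - lam_max,
    }


def anchors_frame(fit: DDFit) -> pd.DataFrame:
    """Anchor summary for every stock in the fit."""
    return pd.DataFrame([lambda_at_anchors(fit, s) for s in fit.stock_ids])
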