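"""Model interpretation: partial dependence and broken-stick threshold fits.

Partial dependence is computed exactly (no approximation): for each grid
value g of the chosen feature, that feature is overwritten with g in
*every* row of the reference table and the model predictions are
averaged. 1-D profiles are centered at the leftmost grid point, so a
value reads as "change in predicted response relative to the low end of
the feature". 2-D surfaces are reported uncentered (absolute predicted
response), with the Cartesian product of the two 1-D grids.

The broken-stick (two-segment continuous piecewise linear) fit profiles
the breakpoint over interior observed predictor values, solving ordinary
least squares for (level, left slope, right slope) at each candidate and
keeping the SSE-minimizing one; an optional nonparametric bootstrap gives
a percentile confidence interval for the breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gbdt import BoostedModel, predict_gbdt

__all__ = ["PDPResult", "PDP2DResult", "PiecewiseFit",
           "pdp_1d", "pdp_2d", "piecewise_fit"]


@dataclass
class PDPResult:
    feature: str
    grid: np.ndarray           # strictly increasing
    centered_pd: np.ndarray    # centered_pd[0] == 0
    n_grid: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid,
                             "centered_pd": self.centered_pd})


@dataclass
class PDP2DResult:
    feature_a: str
    feature_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    mean_prediction: np.ndarray  # shape (|grid_a|, |grid_b|), uncentered

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, self.mean_prediction[i, j])
                for i, a in enumerate(self.grid_a)
                for j, b in enumerate(self.grid_b)]
        return pd.DataFrame(rows, columns=[self.feature_a, self.feature_b,
                                           "mean_prediction"])


@dataclass
class PiecewiseFit:
    """Continuous two-segment linear fit y = a + b1·(x−c)·[x≤c] + b2·(x−c)·[x>c]."""

    breakpoint: float
    level: float        # fitted value at the breakpoint
    slope_left: float
    slope_right: float
    sse: float
    sse_line: float     # single-line OLS SSE, for judging the break
    breakpoint_ci: tuple[float, float] | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = x - self.breakpoint
        return self.level + np.where(d <= 0, self.slope_left * d,
                                     self.slope_right * d)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if d["breakpoint_ci"] is not None:
            d["breakpoint_ci"] = list(d["breakpoint_ci"])
        return d


def _grid(values: np.ndarray, max_grid: int) -> np.ndarray:
    uniq = np.unique(values)
    if len(uniq) <= max_grid:
        return uniq
    qs = np.quantile(values, np.linspace(0.0, 1.0, max_grid))
    return np.unique(qs)


def pdp_1d(model: BoostedModel, X: pd.DataFrame, feature: str,
           max_grid: int = 10) -> PDPResult:
    """Exact 1-D partial dependence, centered at the leftmost grid point.

    The grid is the sorted unique observed values when there are at most
    ``max_grid`` of them, otherwise empirical quantiles at ``max_grid``
    evenly spaced probabilities.
    """
    if feature not in X.columns:
        raise ValueError(f"unknown feature {feature!r}")
    if len(X) == 0:
        raise ValueError("empty reference table")
    grid = _grid(X[feature].to_numpy(dtype=float), max_grid)
    pd_values = np.empty(len(grid))
    work = X.copy()
    for g_idx, g in enumerate(grid):
        work[feature] = g
        pd_values[g_idx] = predict_gbdt(model, work).mean()
    return PDPResult(feature, grid, pd_values - pd_values[0], len(grid))


def pdp_2d(model: BoostedModel, X: pd.DataFrame, feature_a: str,
           feature_b: str, max_grid: int = 10) -> PDP2DResult:
    """Exact 2-D partial dependence over the product of the two 1-D grids."""
    if feature_a == feature_b:
        raise ValueError("the two features must be distinct")
    for f in (feature_a, feature_b):
        if f not in X.columns:
            raise ValueError(f"unknown feature {f!r}")
    grid_a = _grid(X[feature_a].to_numpy(dtype=float), max_grid)
    grid_b = _grid(X[feature_b].to_numpy(dtype=float), max_grid)
    mat = np.empty((len(grid_a), len(grid_b)))
    work = X.copy()
    for i, a in enumerate(grid_a):
        work[feature_a] = a
        for j, b in enumerate(grid_b):
            work[feature_b] = b
            mat[i, j] = predict_gbdt(model, work).mean()
    return PDP2DResult(feature_a, feature_b, grid_a, grid_b, mat)


def _fit_at(x: np.ndarray, y: np.ndarray, c: float
            ) -> tuple[float, float, float, float]:
    d = x - c
    A = np.column_stack([np.ones_like(x),
                         np.where(d <= 0, d, 0.0),
                         np.where(d > 0, d, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(coef[2]), float(resid @ resid)


def _profile_breakpoint(x: np.ndarray, y: np.ndarray,
                        candidates: np.ndarray) -> PiecewiseFit:
    best = None
    for c in candidates:  # ascending; strict < keeps the smallest tied c
        a, b1, b2, sse = _fit_at(x, y, float(c))
        if best is None or sse < best.sse:
            best = PiecewiseFit(float(c), a, b1, b2, sse, np.nan)
    return best


def piecewise_fit(x, y, n_boot: int = 0, seed: int = 0) -> PiecewiseFit:
    """Two-segment continuous piecewise regression with profiled breakpoint.

    Candidate breakpoints are the interior observed x values (the two
    extreme unique values on each side are excluded so both segments keep
    support). Ties in SSE resolve to the smaller breakpoint. With
    ``n_boot`` > 0, a seeded nonparametric bootstrap supplies a 95 %
    percentile confidence interval for the breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 6:
        raise ValueError("need at least 6 paired points")
    uniq = np.unique(x)
    if len(uniq) < 5:
        raise ValueError("need at least 5 distinct x values")
    candidates = uniq[2:-2]
    fit = _profile_breakpoint(x, y, candidates)
    # single straight line for comparison (feasible special case b1 == b2)
    A = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    fit.sse_line = float(resid @ resid)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        bps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(x), len(x))
            xb, yb = x[idx], y[idx]
            ub = np.unique(xb)
            if len(ub) < 5:
                continue
            bps.append(_profile_breakpoint(xb, yb, ub[2:-2]).breakpoint)
        if bps:
            lo, hi = np.percentile(bps, [2.5, 97.5])
            fit.breakpoint_ci = (float(lo), float(hi))
    return fit
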