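"""Hyperparameter grid and EBIC-driven model choice.

The spike variance v0 controls how aggressively near-zero effects are
shrunk away; the slab variance v1 how freely large effects move.  Fits are
run over a small grid of (v0, v1) candidates and compared by the extended
Bayesian information criterion

    EBIC_tau = -2 log L + p_m log n + 2 tau log C(p, p_m),   0 <= tau <= 1,

where p_m counts the selected markers (clinical covariates and intercept
are always in the model and are not penalised) and log L is the Weibull
log-likelihood at the converged posterior-mode parameters.  tau = 0 is the
ordinary BIC; larger tau penalises the size of the model space and yields
sparser choices when p >> n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import SurvivalDataset
from .em import FitResult, FitSettings, PriorSpec, fit

__all__ = ["GridPoint", "make_grid", "ebic", "tune"]

TAUS = (0.0, 0.5, 1.0)


@dataclass
class GridPoint:
    v0: float
    v1: float
    result: FitResult
    ebic: dict[float, float]


def make_grid(
    p: int, v1_candidates: tuple[float, ...] = (10.0, 100.0, 500.0)
) -> list[tuple[float, float]]:
    """Candidate (v0, v1) pairs.

    v0 runs over {1/10p, 1/5p, 1/2p, 1/p, 2/p, 5/p, 10/p} plus 0.05 when
    p > 500, crossed with v1 in {10, 100, 500}; duplicates and pairs with
    v0 >= v1 are dropped.  For p = 1000 this gives 24 combinations.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    v0s = [1 / (10 * p), 1 / (5 * p), 1 / (2 * p), 1 / p, 2 / p, 5 / p, 10 / p]
    if p > 500:
        v0s.append(0.05)
    grid = []
    seen = set()
    for v1 in v1_candidates:
        for v0 in v0s:
            if v0 >= v1 or (v0, v1) in seen:
                continue
            seen.add((v0, v1))
            grid.append((v0, v1))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    return grid


def ebic(loglik: float, p_m: int, n: int, p: int, tau: float) -> float:
    """EBIC at size-of-model p_m; the binomial term uses log-gamma so large
    p never overflows."""
    if p_m < 0 or p_m > p:
        raise ValueError("need 0 <= p_m <= p")
    log_binom = gammaln(p + 1) - gammaln(p_m + 1) - gammaln(p - p_m + 1)
    return float(-2.0 * loglik + p_m * math.log(n) + 2.0 * tau * log_binom)


def _grid_point(data: SurvivalDataset, v0: float, v1: float, prior: PriorSpec,
                settings: FitSettings | None) -> GridPoint:
    res = fit(data, PriorSpec(v0, v1, prior.nu, prior.eta_ig, prior.a, prior.b),
              settings)
    e = {t: ebic(res.loglik, res.n_selected, data.n, data.p, t) for t in TAUS}
    return GridPoint(v0, v1, res, e)


def tune(
    data: SurvivalDataset,
    tau: float = 0.5,
    grid: list[tuple[float, float]] | None = None,
    prior: PriorSpec | None = None,
    settings: FitSettings | None = None,
) -> tuple[GridPoint, pd.DataFrame]:
    """Fit every grid point and return the EBIC winner plus the full table.

    Ties are broken toward the sparser prior (larger v0, then smaller v1).
    Grid fits are independent, so results do not depend on evaluation order.
    If no fit converged the best-effort winner is returned with a warning.
    """
    grid = grid if grid is not None else make_grid(data.p)
    if not grid:
        raise ValueError("empty grid")
    base = prior or PriorSpec(grid[0][0], grid[0][1])
    points = [_grid_point(data, v0, v1, base, settings) for v0, v1 in grid]
    if not any(pt.result.converged for pt in points):
        warnings.warn("no grid fit converged; returning best-effort EBIC winner")
    best = min(points, key=lambda pt: (pt.ebic[tau], -pt.v0, pt.v1))
    table = pd.DataFrame(
        {
            "v0": [pt.v0 for pt in points],
            "v1": [pt.v1 for pt in points],
            "n_selected": [pt.result.n_selected for pt in points],
            "loglik": [pt.result.loglik for pt in points],
            "EBIC_0": [pt.ebic[0.0] for pt in points],
            "EBIC_0.5": [pt.ebic[0.5] for pt in points],
            "EBIC_1": [pt.ebic[1.0] for pt in points],
            "converged": [pt.result.converged for pt in points],
            "n_iter": [pt.result.n_iter for pt in points],
        }
    )
    return best, table


def tune_all_taus(
    data: SurvivalDataset,
    grid: list[tuple[float, float]] | None = None,
    settings: FitSettings | None = None,
) -> dict[float, GridPoint]:
    """One pass over the grid, returning the winner for each tau in
    {0, 0.5, 1} (the grid fits are shared, not repeated)."""
    grid = grid if grid is not None else make_grid(data.p)
    base = PriorSpec(grid[0][0], grid[0][1])
    points = [_grid_point(data, v0, v1, base, settings) for v0, v1 in grid]
    return {
        t: min(points, key=lambda pt: (pt.ebic[t], -pt.v0, pt.v1)) for t in TAUS
    }
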