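"""Synthetic survival-study generator and the six-scenario evaluation.

The generator emulates an omics cohort: markers come in independent blocks
of 50 columns with within-block correlation 0.6^|i-j| (an AR-style decay,
mimicking local LD / co-expression), six randomly placed causal markers
carry effects {±0.2, ±0.3, ±0.4}, and survival times are drawn with scale
lambda_i = exp(-X_i beta) from an exponential, Weibull(shape 2) or
Gamma(shape 0.8) law.  Right censoring is uniform U(0, K) with K calibrated
so that on average 40% of subjects are censored.  Each replication also
draws a 100-subject test set from the same law for prediction scoring.

Scenario table (n = 500 throughout):

    1: exponential, p = 1000      2: exponential, p = 5000
    3: Weibull(2),  p = 1000      4: Weibull(2),  p = 5000
    5: Gamma(0.8),  p = 1000      6: Gamma(0.8),  p = 5000
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .data import SurvivalDataset
from .em import FitSettings
from .metrics import harrells_c, mse, selection_metrics
from .select import TAUS, make_grid, tune_all_taus

__all__ = [
    "SimScenario",
    "SimulatedDataset",
    "MetricReport",
    "gen_markers",
    "gen_survival",
    "calibrate_censoring",
    "make_scenario",
    "run_study",
    "SCENARIOS",
]

# scenario id -> (family, shape, p)
SCENARIOS: dict[int, tuple[str, float, int]] = {
    1: ("exponential", 1.0, 1000),
    2: ("exponential", 1.0, 5000),
    3: ("weibull", 2.0, 1000),
    4: ("weibull", 2.0, 5000),
    5: ("gamma", 0.8, 1000),
    6: ("gamma", 0.8, 5000),
}

CAUSAL_EFFECTS = np.array([0.2, -0.2, 0.3, -0.3, 0.4, -0.4])


@dataclass(frozen=True)
class SimScenario:
    """Generator settings for one simulation scenario."""

    family: str
    shape: float
    n: int = 500
    p: int = 1000
    block: int = 50
    rho: float = 0.6
    censoring: float = 0.40
    effects: np.ndarray = field(default_factory=lambda: CAUSAL_EFFECTS.copy())
    n_test: int = 100
    n_reps: int = 50

    @classmethod
    def from_id(cls, scenario_id: int, **kw) -> "SimScenario":
        if scenario_id not in SCENARIOS:
            raise ValueError(f"scenario_id must be in 1..6, got {scenario_id}")
        family, shape, p = SCENARIOS[scenario_id]
        return cls(family=family, shape=shape, p=p, **kw)


@dataclass
class SimulatedDataset:
    train: SurvivalDataset
    test: SurvivalDataset
    beta_true: np.ndarray
    causal_idx: np.ndarray
    uncensored_times: np.ndarray  # training lifetimes before censoring
    K: float


@dataclass
class MetricReport:
    per_rep: pd.DataFrame
    summary: pd.DataFrame
    n_failed: int = 0


def _block_chol(block: int, rho: float) -> np.ndarray:
    idx = np.arange(block)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return cholesky(cov, lower=True)


def gen_markers(
    n: int, p: int, rho: float = 0.6, block: int = 50, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Block-correlated multivariate-normal markers.

    Each consecutive group of ``block`` columns is N(0, Sigma) with
    Sigma_jj = 1, Sigma_ij = rho^|i-j|; blocks are mutually independent.
    """
    if p % block != 0:
        raise ValueError("p must be a multiple of the block size")
    assert -1 < rho < 1, "AR covariance requires |rho| < 1"
    rng = rng or np.random.default_rng()
    L = _block_chol(block, rho)
    z = rng.standard_normal((n, p // block, block))
    return np.einsum("nkb,cb->nkc", z, L).reshape(n, p)


def gen_survival(
    X: np.ndarray,
    beta_true: np.ndarray,
    family: str,
    shape: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uncensored lifetimes with scale lambda_i = exp(-X_i beta).

    exponential: t ~ Exp(rate lambda_i); weibull: survival exp(-lambda t^shape)
    (shape 2 in the study); gamma: shape 0.8 with rate 1/lambda_i.
    """
    rng = rng or np.random.default_rng()
    lam = np.exp(-np.asarray(X) @ np.asarray(beta_true))
    if family == "exponential":
        return rng.exponential(scale=1.0 / lam)
    if family == "weibull":
        # S(t) = exp(-lam t^shape)  =>  t = (E / lam)^(1/shape), E ~ Exp(1)
        return (rng.exponential(size=lam.shape) / lam) ** (1.0 / shape)
    if family == "gamma":
        return rng.gamma(shape=shape, scale=lam)
    raise ValueError(f"unknown survival family {family!r}")


def calibrate_censoring(
    time_sampler,
    target: float = 0.40,
    rng: np.random.Generator | None = None,
    n_pilot: int = 50_000,
    tol: float = 0.001,
) -> float:
    """Censoring bound K such that c ~ U(0, K) censors ``target`` of subjects.

    Given lifetime t, P(censored | t) = P(c < t) = min(t, K)/K, so the
    expected censored fraction on a pilot sample {t_m} is
    mean(min(t_m, K))/K — monotone decreasing in K — and bisection finds the
    root.  ``time_sampler(rng, size)`` draws pilot lifetimes.
    """
    if not 0.05 < target < 0.95:
        raise ValueError("target censoring must lie in (0.05, 0.95)")
    rng = rng or np.random.default_rng()
    t = np.asarray(time_sampler(rng, n_pilot), dtype=float)

    def frac(K: float) -> float:
        return float(np.minimum(t, K).mean() / K)

    lo = float(np.min(t)) * 0.5
    hi = float(np.max(t))
    for _ in range(200):
        if frac(hi) < target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the censoring target from above")
    for _ in range(200):
        if frac(lo) > target:
            break
        lo *= 0.5
    else:
        raise RuntimeError("could not bracket the censoring target from below")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        assert frac(lo) >= f >= frac(hi) - 1e-12  # monotone in K
        if abs(f - target) < tol:
            return mid
        if f > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_scenario(
    scenario_id: int,
    seed: int | np.random.SeedSequence = 0,
    scenario: SimScenario | None = None,
) -> SimulatedDataset:
    """Assemble one replication: markers, causal placement, lifetimes,
    calibrated uniform censoring and a test set from the same law.

    Training marker columns are standardised after generation; the test
    matrix is scaled with the training constants.
    """
    sc = scenario or SimScenario.from_id(scenario_id)
    rng = np.random.default_rng(seed)
    n_all = sc.n + sc.n_test
    X = gen_markers(n_all, sc.p, sc.rho, sc.block, rng)
    causal = np.sort(rng.choice(sc.p, size=len(sc.effects), replace=False))
    beta_true = np.zeros(sc.p)
    beta_true[causal] = rng.permutation(sc.effects)
    t_all = gen_survival(X, beta_true, sc.family, sc.shape, rng)

    lam_train = np.exp(-X[: sc.n] @ beta_true)

    # pilot lifetimes re-use the realised training lambdas
    def pilot(r: np.random.Generator, size: int) -> np.ndarray:
        lam = np.resize(lam_train, size)
        if sc.family == "exponential":
            return r.exponential(scale=1.0 / lam)
        if sc.family == "weibull":
            return (r.exponential(size=size) / lam) ** (1.0 / sc.shape)
        return r.gamma(shape=sc.shape, scale=lam)

    K = calibrate_censoring(pilot, sc.censoring, rng)
    c_all = rng.uniform(0.0, K, size=n_all)
    T_all = np.minimum(t_all, c_all)
    d_all = (t_all <= c_all).astype(float)

    train = SurvivalDataset(T_all[: sc.n], d_all[: sc.n], X[: sc.n])
    Xte = (X[sc.n :] - train.x_center) / train.x_scale
    test = SurvivalDataset(T_all[sc.n :], d_all[sc.n :], Xte, standardize=False)
    return SimulatedDataset(train, test, beta_true, causal, t_all[: sc.n], K)


def run_study(
    scenario_id: int,
    n_replications: int = 50,
    seed: int = 0,
    taus: tuple[float, ...] = TAUS,
    settings: FitSettings | None = None,
    scenario: SimScenario | None = None,
) -> MetricReport:
    """Replicate the full pipeline: generate data, tune (v0, v1) over the
    grid, and score selection (TPR/FPR/FDR), estimation (MSE) and test-set
    prediction (Harrell's c) for each EBIC variant.

    One EBIC pass shares the grid fits across tau values.  A replication
    that fails numerically is excluded and counted in ``n_failed``.
    """
    sc = scenario or SimScenario.from_id(scenario_id)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replications)
    rows = []
    n_failed = 0
    grid = make_grid(sc.p)
    for rep, child in enumerate(children):
        try:
            sim = make_scenario(scenario_id, seed=child, scenario=sc)
            winners = tune_all_taus(sim.train, grid=grid, settings=settings)
        except Exception:  # noqa: BLE001 - a bad replication must not kill the study
            n_failed += 1
            continue
        for tau in taus:
            pt = winners[tau]
            res = pt.result
            tpr, fpr, fdr = selection_metrics(res.selected, sim.causal_idx, sc.p)
            risk = -(sim.test.X @ res.state.beta)
            rows.append(
                {
                    "rep": rep,
                    "tau": tau,
                    "tpr": tpr,
                    "fpr": fpr,
                    "fdr": fdr,
                    "mse": mse(res.state.beta, sim.beta_true),
                    "cindex": harrells_c(risk, sim.test.times, sim.test.events),
                    "v0": pt.v0,
                    "v1": pt.v1,
                    "n_selected": res.n_selected,
                    "n_iter": res.n_iter,
                    "converged": res.converged,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("tau")[["tpr", "fpr", "fdr", "mse", "cindex"]].mean().reset_index()
        if len(per_rep)
        else pd.DataFrame()
    )
    return MetricReport(per_rep=per_rep, summary=summary, n_failed=n_failed)
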