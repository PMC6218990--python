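"""The SurvEMVS EM loop: posterior-mode Bayesian variable selection.

Each marker effect beta_j carries a two-component normal spike-and-slab
prior N(0, sigma^2 a_j) with a_j = (1-gamma_j) v0 + gamma_j v1 and latent
inclusion indicator gamma_j ~ Bernoulli(theta).  Treating gamma as missing
data, the E-step computes posterior inclusion probabilities p_j* and the
expected inverse prior variances d_j* = (1-p_j*)/v0 + p_j*/v1, which act as
adaptive ridge weights.  The M-step maximises the expected log-posterior:

  * beta  — trust-region cyclic coordinate descent on
            -logL + ||D*^{1/2} beta||^2 / (2 sigma^2), one damped Newton
            step per coordinate per sweep;
  * u, alpha — one safeguarded Newton step per coordinate;
  * sigma^2  — closed form (sum beta_j^2 d_j* + nu eta) / (p + nu + 2);
  * theta    — closed form (sum p_j* + a - 1) / (a + b + p - 2).

Iteration stops when the relative change of the marker predictor,
sum_i |X_i'(beta^(k) - beta^(k-1))| / (1 + sum_i |X_i' beta^(k)|),
falls below xi.  A marker is selected when its final p_j* >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import weibull
from ._ccd import ccd_sweep
from .data import SurvivalDataset

__all__ = [
    "PriorSpec",
    "FitSettings",
    "ModelState",
    "FitResult",
    "e_step",
    "update_beta_ccd",
    "update_u",
    "update_alpha",
    "update_sigma2",
    "update_theta",
    "convergence_stat",
    "fit",
]


@dataclass(frozen=True)
class PriorSpec:
    """Spike/slab variances and hyperprior constants.

    v0 (spike) must be smaller than v1 (slab).  The inverse-gamma prior on
    sigma^2 is IG(nu/2, nu*eta_ig/2) and the Beta(a, b) prior on theta is
    uniform at the defaults a = b = 1; nu = eta_ig = 1 keeps the sigma^2
    prior weakly informative.
    """

    v0: float
    v1: float
    nu: float = 1.0
    eta_ig: float = 1.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.v0 < self.v1):
            raise ValueError("need 0 < v0 < v1")
        if min(self.nu, self.eta_ig, self.a, self.b) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass(frozen=True)
class FitSettings:
    """EM loop controls.

    xi is the convergence tolerance on the relative marker-predictor change;
    full_sweeps (k') full CCD cycles are run before restricting sweeps to
    the active set {j : |beta_j| > active_threshold}, refreshed from scratch
    every refresh_every EM iterations thereafter.
    """

    xi: float = 1e-4
    max_iter: int = 500
    full_sweeps: int = 5
    active_threshold: float = 1e-8
    refresh_every: int = 10
    trust_init: float = 1.0
    inner_tol: float = 1e-6
    max_inner: int = 50
    polish_tol: float = 1e-8
    polish_iter: int = 50

    def __post_init__(self) -> None:
        if self.xi <= 0 or self.active_threshold <= 0 or self.full_sweeps < 1:
            raise ValueError("invalid fit settings")


@dataclass
class ModelState:
    beta: np.ndarray
    u: np.ndarray
    alpha: float
    sigma2: float
    theta: float
    p_star: np.ndarray
    d_star: np.ndarray
    iteration: int = 0


@dataclass
class FitResult:
    state: ModelState
    converged: bool
    n_iter: int
    loglik: float
    selected: np.ndarray  # indices j with p_j* >= 0.5
    trace: list[float] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.selected.size)


def e_step(
    beta: np.ndarray, sigma2: float, theta: float, prior: PriorSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities p* and precision weights d*.

    p_j* is the slab's posterior share under the two-normal mixture for
    beta_j, computed through the log-odds (so neither component can
    underflow to 0/0):

      logit p_j* = log(theta/(1-theta)) - (1/2) log(v1/v0)
                   + beta_j^2 / (2 sigma^2) * (1/v0 - 1/v1)
    """
    if sigma2 <= 0 or not (0 < theta < 1):
        raise ValueError("need sigma2 > 0 and theta in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    log_odds = (
        np.log(theta / (1.0 - theta))
        - 0.5 * np.log(prior.v1 / prior.v0)
        + beta**2 / (2.0 * sigma2) * (1.0 / prior.v0 - 1.0 / prior.v1)
    )
    p_star = expit(log_odds)
    d_star = (1.0 - p_star) / prior.v0 + p_star / prior.v1
    return p_star, d_star


def update_beta_ccd(
    data: SurvivalDataset,
    beta: np.ndarray,
    eta_m: np.ndarray,
    w: np.ndarray,
    d_star: np.ndarray,
    sigma2: float,
    radii: np.ndarray,
    active: np.ndarray | None = None,
) -> int:
    """One CCD cycle over all coordinates (or ``active`` only), in place.

    eta_m = X beta and w = exp(alpha log T - eta) must be consistent with
    beta on entry; they are kept consistent.  Returns the number of
    degenerate (skipped) coordinates.
    """
    order = (
        np.arange(data.p, dtype=np.int64) if active is None else active.astype(np.int64)
    )
    n_bad = ccd_sweep(
        data.X, data.events, beta, eta_m, w, np.asarray(d_star) / sigma2, radii, order
    )
    if n_bad:
        warnings.warn(f"{n_bad} coordinate(s) skipped: non-positive curvature")
    return n_bad


def _newton_1d(value, grad, curv, eval_ll, ll0, positive=False):
    """Safeguarded 1-D Newton step: halve until the log-likelihood does not
    decrease (and the parameter stays positive if required).  Returns
    (new_value, new_ll)."""
    if curv >= 0 or not np.isfinite(grad):
        raise weibull.NumericalError("degenerate curvature in Newton update")
    step = -grad / curv
    for _ in range(21):
        cand = value + step
        if not positive or cand > 0:
            ll = eval_ll(cand)
            if ll >= ll0 - 1e-12:
                return cand, ll
        step *= 0.5
    warnings.warn("Newton step rejected after 20 halvings; parameter unchanged")
    return value, ll0


def update_u(
    data: SurvivalDataset,
    beta: np.ndarray,
    u: np.ndarray,
    alpha: float,
    eta_m: np.ndarray | None = None,
) -> np.ndarray:
    """One safeguarded Newton step per covariate coordinate, cycled in fixed
    order with the freshest values of the others."""
    u = np.asarray(u, dtype=float).copy()
    if eta_m is None:
        eta_m = data.X @ np.asarray(beta, dtype=float)
    d = data.events
    alw = alpha * data.log_times
    for j in range(data.Z.shape[1]):
        zj = data.Z[:, j]
        eta = eta_m + data.Z @ u
        w = np.exp(alw - eta)
        g = float(zj @ (w - d))
        h = float(-(zj**2) @ w)

        def ll_at(uj, j=j, zj=zj, w=w):
            de = zj * (uj - u[j])
            return float(-np.sum(d * de) - np.sum(w * np.exp(-de)))

        # constant terms cancel: compare the eta-dependent part only
        ll0 = float(-np.sum(w))
        u[j], _ = _newton_1d(u[j], g, h, ll_at, ll0)
    return u


def update_alpha(
    data: SurvivalDataset, beta: np.ndarray, u: np.ndarray, alpha: float
) -> float:
    """One safeguarded Newton step for the shape; alpha stays positive."""
    eta = weibull.linear_predictor(data, beta, u)
    d, lt = data.events, data.log_times

    def ll_at(a):
        return float(
            np.sum(d * (np.log(a) + (a - 1.0) * lt - eta)) - np.sum(np.exp(a * lt - eta))
        )

    w = np.exp(alpha * lt - eta)
    g = float(np.sum(d * (1.0 / alpha + lt)) - np.sum(w * lt))
    h = float(-np.sum(d) / alpha**2 - np.sum(w * lt**2))
    new, _ = _newton_1d(alpha, g, h, ll_at, ll_at(alpha), positive=True)
    return new


def update_sigma2(beta: np.ndarray, d_star: np.ndarray, prior: PriorSpec) -> float:
    """Closed-form sigma^2 update: (sum beta_j^2 d_j* + nu eta) / (p + nu + 2)."""
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    return float(
        (np.sum(beta**2 * d_star) + prior.nu * prior.eta_ig) / (p + prior.nu + 2.0)
    )


def update_theta(p_star: np.ndarray, prior: PriorSpec) -> float:
    """Closed-form theta update: (sum p_j* + a - 1) / (a + b + p - 2)."""
    p_star = np.asarray(p_star, dtype=float)
    p = p_star.shape[0]
    theta = (np.sum(p_star) + prior.a - 1.0) / (prior.a + prior.b + p - 2.0)
    return float(np.clip(theta, 1e-12, 1.0 - 1e-12))


def convergence_stat(
    data: SurvivalDataset, beta_new: np.ndarray, beta_old: np.ndarray
) -> float:
    """Relative change of the marker predictor X beta between EM iterations."""
    num = float(np.sum(np.abs(data.X @ (np.asarray(beta_new) - np.asarray(beta_old)))))
    den = 1.0 + float(np.sum(np.abs(data.X @ np.asarray(beta_new))))
    return num / den


def _initial_state(data: SurvivalDataset, p: int) -> ModelState:
    u0 = np.zeros(data.Z.shape[1])
    n_events = float(np.sum(data.events))
    # exponential-MLE intercept: log(sum T / sum delta)
    if n_events > 0:
        u0[0] = np.log(np.sum(data.times) / n_events)
    return ModelState(
        beta=np.zeros(p),
        u=u0,
        alpha=1.0,
        sigma2=1.0,
        theta=0.5,
        p_star=np.full(p, 0.5),
        d_star=np.full(p, 1.0),
    )


def fit(
    data: SurvivalDataset,
    prior: PriorSpec,
    settings: FitSettings | None = None,
) -> FitResult:
    """Run the SurvEMVS EM loop to the posterior mode.

    Deterministic given the data; non-convergence within ``max_iter``
    iterations returns ``converged=False`` rather than raising.
    """
    settings = settings or FitSettings()
    p = data.p
    st = _initial_state(data, p)
    radii = np.full(p, settings.trust_init)
    eta_m = np.zeros(data.n)
    trace: list[float] = []
    converged = False
    active: np.ndarray | None = None

    for k in range(1, settings.max_iter + 1):
        st.p_star, st.d_star = e_step(st.beta, st.sigma2, st.theta, prior)
        beta_old = st.beta.copy()

        # --- M-step for beta: CCD cycles until the penalized objective is
        # stationary (one damped Newton step per coordinate per cycle).
        # The first cycle is full unless the EM iteration is past k' full
        # sweeps and not a refresh iteration, in which case only the active
        # set {j : |beta_j| > beta'} is visited at all.
        w = np.exp(weibull.log_weights(data, eta_m + data.Z @ st.u, st.alpha))
        start_full = True
        if k > settings.full_sweeps and active is not None:
            refresh = (k - settings.full_sweeps - 1) % settings.refresh_every == 0
            start_full = refresh
        for inner in range(settings.max_inner):
            sweep = None if (start_full and inner == 0) else active
            beta_prev = st.beta.copy()
            update_beta_ccd(
                data, st.beta, eta_m, w, st.d_star, st.sigma2, radii, sweep
            )
            if inner == 0:
                active = np.flatnonzero(np.abs(st.beta) > settings.active_threshold)
            if np.max(np.abs(st.beta - beta_prev), initial=0.0) < settings.inner_tol:
                break

        # --- u, alpha (one-step Newton each), then closed forms
        st.u = update_u(data, st.beta, st.u, st.alpha, eta_m=eta_m)
        st.alpha = update_alpha(data, st.beta, st.u, st.alpha)
        st.sigma2 = update_sigma2(st.beta, st.d_star, prior)
        st.theta = update_theta(st.p_star, prior)
        st.iteration = k

        stat = convergence_stat(data, st.beta, beta_old)
        trace.append(stat)
        if stat < settings.xi:
            converged = True
            break

    # polish (u, alpha) to stationarity so log L is comparable across fits
    for _ in range(settings.polish_iter):
        u_prev, a_prev = st.u.copy(), st.alpha
        st.u = update_u(data, st.beta, st.u, st.alpha, eta_m=eta_m)
        st.alpha = update_alpha(data, st.beta, st.u, st.alpha)
        if max(np.max(np.abs(st.u - u_prev)), abs(st.alpha - a_prev)) < settings.polish_tol:
            break

    st.p_star, st.d_star = e_step(st.beta, st.sigma2, st.theta, prior)
    ll = weibull.log_likelihood(data, st.beta, st.u, st.alpha)
    selected = np.flatnonzero(st.p_star >= 0.5)
    return FitResult(
        state=st,
        converged=converged,
        n_iter=st.iteration,
        loglik=ll,
        selected=selected,
        trace=trace,
    )
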