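"""Weibull regression log-likelihood and coordinatewise derivatives.

The model: scale lambda_i = exp(-eta_i) with linear predictor
eta_i = Z_i u + X_i beta, and shape alpha > 0, so that

    f(T | lambda, alpha) = alpha T^(alpha-1) lambda exp(-lambda T^alpha)
    S(T | lambda, alpha) = exp(-lambda T^alpha)

The censored-data log-likelihood is

    log L = sum_i [ delta_i log f(T_i) + (1 - delta_i) log S(T_i) ]
          = sum_i [ delta_i (log alpha + (alpha-1) log T_i - eta_i) - w_i ]

with w_i = exp(alpha log T_i - eta_i) = lambda_i T_i^alpha.  All arithmetic
stays in eta/log space; lambda and T^alpha are never formed on their own, so
large |eta| cannot overflow before the guarded exp.

Coordinatewise partials (other coordinates fixed), used by the one-step
Newton updates:

    d logL / d beta_j  =  sum_i x_ij (w_i - delta_i)
    d2 logL / d beta_j2 = -sum_i x_ij^2 w_i          (< 0: coordinatewise concave)
    d logL / d alpha   =  sum_i delta_i (1/alpha + log T_i) - sum_i w_i log T_i
    d2 logL / d alpha2 = -sum_i delta_i / alpha^2 - sum_i w_i (log T_i)^2
"""

from __future__ import annotations

import numpy as np

from .data import SurvivalDataset

__all__ = [
    "linear_predictor",
    "log_weights",
    "log_likelihood",
    "loglik_gradients",
    "loglik_curvatures",
]


class NumericalError(ArithmeticError):
    """Raised when the likelihood or a curvature becomes unusable."""


def linear_predictor(data: SurvivalDataset, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    if beta.shape[0] != data.p or u.shape[0] != data.Z.shape[1]:
        raise ValueError("beta/u dimensions do not conform to the dataset")
    return data.Z @ u + data.X @ beta


def log_weights(data: SurvivalDataset, eta: np.ndarray, alpha: float) -> np.ndarray:
    """log w_i = alpha log T_i - eta_i, the log cumulative hazard."""
    return alpha * data.log_times - eta


def log_likelihood(
    data: SurvivalDataset, beta: np.ndarray, u: np.ndarray, alpha: float
) -> float:
    """Censored Weibull log-likelihood at (beta, u, alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    eta = linear_predictor(data, beta, u)
    lw = log_weights(data, eta, alpha)
    d = data.events
    ll = np.sum(d * (np.log(alpha) + (alpha - 1.0) * data.log_times - eta)) - np.sum(
        np.exp(lw)
    )
    if not np.isfinite(ll):
        raise NumericalError("non-finite log-likelihood (overflow in linear predictor?)")
    return float(ll)


def loglik_gradients(
    data: SurvivalDataset, beta: np.ndarray, u: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic first partials with respect to each beta_j, u_j and alpha."""
    eta = linear_predictor(data, beta, u)
    w = np.exp(log_weights(data, eta, alpha))
    r = w - data.events
    grad_beta = data.X.T @ r
    grad_u = data.Z.T @ r
    grad_alpha = float(
        np.sum(data.events * (1.0 / alpha + data.log_times)) - np.sum(w * data.log_times)
    )
    if not (np.all(np.isfinite(grad_beta)) and np.all(np.isfinite(grad_u))):
        raise NumericalError("non-finite gradient")
    return grad_beta, grad_u, grad_alpha


def loglik_curvatures(
    data: SurvivalDataset, beta: np.ndarray, u: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coordinatewise second partials; beta/u entries are < 0 away from
    degenerate (all-zero) columns, which are flagged with NumericalError."""
    eta = linear_predictor(data, beta, u)
    w = np.exp(log_weights(data, eta, alpha))
    d2_beta = -(data.X**2).T @ w
    d2_u = -(data.Z**2).T @ w
    d2_alpha = float(
        -np.sum(data.events) / alpha**2 - np.sum(w * data.log_times**2)
    )
    if np.any(d2_beta >= 0) or np.any(d2_u >= 0):
        raise NumericalError(
            "non-negative curvature along a beta/u coordinate (degenerate column?)"
        )
    return d2_beta, d2_u, d2_alpha
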