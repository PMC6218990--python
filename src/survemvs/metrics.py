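"""Selection, estimation and prediction metrics.

TPR/FPR/FDR score a selected marker set against the known causal set;
MSE = sum_j (beta_hat_j - beta_j)^2 / p scores effect estimation; Harrell's
c (equivalently the AUC for survival prediction) scores test-set risk
ordering under right censoring.
"""

from __future__ import annotations

import numpy as np

__all__ = ["selection_metrics", "mse", "harrells_c"]


def selection_metrics(
    selected: np.ndarray, true_set: np.ndarray, p: int
) -> tuple[float, float, float]:
    """(TPR, FPR, FDR) for a selected index set.

    TPR = |S ∩ T| / |T|, FPR = |S \\ T| / (p - |T|), FDR = |S \\ T| / |S|
    with the empty-selection convention FDR = 0.
    """
    S = set(np.asarray(selected, dtype=int).tolist())
    T = set(np.asarray(true_set, dtype=int).tolist())
    tp = len(S & T)
    fp = len(S - T)
    tpr = tp / len(T) if T else 0.0
    fpr = fp / (p - len(T)) if p > len(T) else 0.0
    fdr = fp / len(S) if S else 0.0
    return tpr, fpr, fdr


def mse(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Mean squared error over all p coefficients."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("coefficient vectors must have equal length")
    return float(np.mean((beta_hat - beta_true) ** 2))


def harrells_c(risk: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance over usable pairs under right censoring.

    A pair is usable when the shorter observed time belongs to a subject
    with an event and the times differ, so the survival ordering is
    determined.  Concordance credits the pair when the earlier failure has
    the higher risk score; tied risk scores credit 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if not (risk.shape == t.shape == d.shape):
        raise ValueError("risk, times and events must have equal length")
    # pair (i, j) usable iff t_i < t_j and d_i == 1 (i is the determined earlier failure)
    ti = t[:, None]
    usable = (ti < t[None, :]) & (d[:, None] == 1.0)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (all censored or fully tied times)")
    ri = risk[:, None]
    conc = np.where(ri > risk[None, :], 1.0, np.where(ri == risk[None, :], 0.5, 0.0))
    return float(conc[usable].sum() / n_usable)
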