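"""Numba kernel for the trust-region cyclic-coordinate-descent beta sweep.

One sweep visits each coordinate in ``order`` once and applies a single
damped Newton step to

    F(beta_j) = -log L(beta) + d_j* beta_j^2 / (2 sigma^2),

holding all other coordinates fixed.  The step is clipped to the per-marker
trust radius Delta_j; if the clipped step still increases F it is halved
(up to 20 times) and otherwise skipped, so F never increases at an accepted
step.  After a step the radius follows the CLG schedule
Delta_j <- max(2 |step|, Delta_j / 2).

State carried across coordinates (and returned updated in place):
``eta_m`` = X beta (marker part of the linear predictor) and
``w`` = exp(alpha log T - eta), the per-subject cumulative hazards.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def ccd_sweep(X, events, beta, eta_m, w, d_over_s2, radii, order):
    """One CCD cycle over the coordinates listed in ``order``.

    X must be Fortran-ordered for contiguous column access.  Returns the
    number of coordinates whose curvature was non-positive (skipped).
    """
    n = X.shape[0]
    n_bad = 0
    for idx in range(order.shape[0]):
        j = order[idx]
        g = 0.0  # d logL / d beta_j
        h = 0.0  # d2 logL / d beta_j2
        for i in range(n):
            xij = X[i, j]
            g += xij * (w[i] - events[i])
            h -= xij * xij * w[i]
        dj = d_over_s2[j]
        fp = -g + dj * beta[j]  # F'
        fpp = -h + dj  # F'' > 0 unless the column is degenerate
        if fpp <= 0.0:
            n_bad += 1
            continue
        step = -fp / fpp
        if step > radii[j]:
            step = radii[j]
        elif step < -radii[j]:
            step = -radii[j]
        # monotonicity safeguard: halve until F does not increase
        accepted = False
        for _ in range(21):
            if step == 0.0:
                break
            # change in -logL from beta_j -> beta_j + step
            dsum = 0.0
            ssum = 0.0
            for i in range(n):
                xs = X[i, j] * step
                dsum += events[i] * xs
                ssum += w[i] * (np.exp(-xs) - 1.0)
            d_negll = dsum + ssum
            d_pen = dj * step * (beta[j] + 0.5 * step)
            if d_negll + d_pen <= 1e-12:
                accepted = True
                break
            step *= 0.5
        if accepted:
            for i in range(n):
                w[i] *= np.exp(-X[i, j] * step)
                eta_m[i] += X[i, j] * step
            beta[j] += step
            new_r = 2.0 * abs(step)
            half_r = 0.5 * radii[j]
            radii[j] = new_r if new_r > half_r else half_r
    return n_bad
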