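"""Coordinate-descent solver for elastic-net penalized logistic regression.

Minimizes, over (b0, beta),

    (1/n) * sum_i d(y_i, b0 + x_i'beta)  +  lam * P_alpha(beta)

with P_alpha(beta) = alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 and an
unpenalized intercept, using an IRLS outer loop with a cyclic
coordinate-descent inner loop over an active set (glmnet-style).
Numba-compiled; the path variant warm-starts along a descending lambda
sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# probability clamp inside the working-response computation (glmnet uses 1e-5)
_PMIN = 1e-5
_MAX_OUTER = 1000


@njit(cache=True)
def _soft(u: float, t: float) -> float:
    if u > t:
        return u - t
    if u < -t:
        return u + t
    return 0.0


@njit(cache=True)
def _wls_pass(X, w, r, beta, beta0, lam_l1, lam_l2, denom, n, idx):
    """One cyclic CD pass over the columns listed in idx (plus intercept).

    r is the working residual z - b0 - X@beta, updated in place.
    Returns the largest absolute coefficient change of the pass.
    """
    max_delta = 0.0
    wsum = 0.0
    wr = 0.0
    for i in range(n):
        wsum += w[i]
        wr += w[i] * r[i]
    d0 = wr / wsum
    if d0 != 0.0:
        beta0[0] += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > max_delta:
            max_delta = abs(d0)
    for jj in range(idx.shape[0]):
        j = idx[jj]
        dj = denom[j]
        if dj <= 0.0:
            continue
        bj = beta[j]
        u = 0.0
        for i in range(n):
            u += w[i] * X[i, j] * r[i]
        u = u / n + bj * (dj - lam_l2)
        bnew = _soft(u, lam_l1) / dj
        if bnew != bj:
            d = bnew - bj
            beta[j] = bnew
            for i in range(n):
                r[i] -= d * X[i, j]
            if abs(d) > max_delta:
                max_delta = abs(d)
    return max_delta


@njit(cache=True)
def cd_enet_logistic(X, y, lam, alpha, beta0_init, beta_init, tol, max_pass):
    """Fit one (lam, alpha) point. Returns (beta0, beta, n_pass, converged)."""
    n, p = X.shape
    beta = beta_init.copy()
    beta0 = np.empty(1)
    beta0[0] = beta0_init
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    lam_l1 = lam * alpha
    lam_l2 = lam * (1.0 - alpha)
    denom = np.empty(p)
    all_idx = np.arange(p)
    n_pass = 0
    converged = False
    obj_best = np.inf
    no_improve = 0
    for _outer in range(_MAX_OUTER):
        # IRLS working quantities at the current iterate
        obj = 0.0
        for i in range(n):
            e = beta0[0]
            for j in range(p):
                if beta[j] != 0.0:
                    e += X[i, j] * beta[j]
            eta[i] = e
            pi = 1.0 / (1.0 + np.exp(-e))
            # deviance contribution, numerically stable
            if e >= 0.0:
                obj += np.log1p(np.exp(-e)) + e * (1.0 - y[i])
            else:
                obj += np.log1p(np.exp(e)) - e * y[i]
            if pi < _PMIN:
                pi = 0.0
                w[i] = _PMIN
            elif pi > 1.0 - _PMIN:
                pi = 1.0
                w[i] = _PMIN
            else:
                w[i] = pi * (1.0 - pi)
            r[i] = (y[i] - pi) / w[i]
        obj /= n
        pen = 0.0
        for j in range(p):
            if beta[j] != 0.0:
                pen += lam_l1 * abs(beta[j]) + 0.5 * lam_l2 * beta[j] * beta[j]
        obj += pen
        # IRLS can limit-cycle with sub-1e-11 objective oscillation; treat
        # several outer iterations without material progress as converged
        if obj >= obj_best - 1e-11 * (1.0 + abs(obj_best)):
            no_improve += 1
            if no_improve >= 3:
                converged = True
                break
        else:
            no_improve = 0
            obj_best = obj
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            denom[j] = s / n + lam_l2
        # CD on the quadratic approximation: full pass, then active set
        outer_delta = 0.0
        quad_done = False
        while n_pass < max_pass:
            d_full = _wls_pass(X, w, r, beta, beta0, lam_l1, lam_l2, denom, n, all_idx)
            n_pass += 1
            if d_full > outer_delta:
                outer_delta = d_full
            if d_full < tol:
                quad_done = True
                break
            active = np.flatnonzero(beta)
            while n_pass < max_pass:
                d_act = _wls_pass(X, w, r, beta, beta0, lam_l1, lam_l2, denom, n, active)
                n_pass += 1
                if d_act < tol:
                    break
        if outer_delta < tol:
            converged = True
            break
        if not quad_done and n_pass >= max_pass:
            break
    return beta0[0], beta, n_pass, converged


@njit(cache=True)
def cd_enet_logistic_path(X, y, lams, alpha, tol, max_pass):
    """Warm-started fits along a descending lambda sequence.

    Returns (beta0s, betas, n_pass_total, all_converged).
    """
    L = lams.shape[0]
    p = X.shape[1]
    beta0s = np.zeros(L)
    betas = np.zeros((L, p))
    beta = np.zeros(p)
    beta0 = 0.0
    n_pass_total = 0
    all_conv = True
    for l in range(L):
        beta0, beta, npass, conv = cd_enet_logistic(
            X, y, lams[l], alpha, beta0, beta, tol, max_pass
        )
        beta0s[l] = beta0
        betas[l] = beta
        n_pass_total += npass
        if not conv:
            all_conv = False
    return beta0s, betas, n_pass_total, all_conv
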