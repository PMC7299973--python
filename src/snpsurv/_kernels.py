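"""Numba kernels for the elastic-net Cox coordinate-descent solver.

The solver works on patients sorted by follow-up time.  Tied times are
grouped into blocks (Breslow handling): ``starts`` holds the first sorted
index of each block, ``dcounts`` the number of events in it, and
``block_of`` maps each sorted patient to their block.  Predictors are
standardised (population mean/variance) before entering the kernels;
coefficients are returned on the standardised scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cox_breslow_derivs(eta, event, block_of, starts, dcounts):
    """Log partial likelihood + per-patient gradient/curvature at ``eta``.

    Returns (loglik, g, w) where g_i = dll/deta_i and w_i is the diagonal
    of the negated Hessian (floored at 1e-10 for the IRLS working weights).
    """
    n = eta.shape[0]
    nblocks = starts.shape[0]
    c = eta[0]
    for i in range(n):
        if eta[i] > c:
            c = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - c)
    suf = np.empty(n + 1)
    suf[n] = 0.0
    for i in range(n - 1, -1, -1):
        suf[i] = suf[i + 1] + r[i]
    ll = 0.0
    cumA = np.empty(nblocks)
    cumB = np.empty(nblocks)
    a = 0.0
    b = 0.0
    for k in range(nblocks):
        Sk = suf[starts[k]]
        if dcounts[k] > 0:
            ll -= dcounts[k] * (np.log(Sk) + c)
            a += dcounts[k] / Sk
            b += dcounts[k] / (Sk * Sk)
        cumA[k] = a
        cumB[k] = b
    g = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        k = block_of[i]
        ri = r[i]
        gi = event[i] - ri * cumA[k]
        wi = ri * cumA[k] - ri * ri * cumB[k]
        if wi < 1e-10:
            wi = 1e-10
        g[i] = gi
        w[i] = wi
        if event[i] > 0:
            ll += eta[i]
    return ll, g, w


@njit(cache=True, inline="always")
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _penalty(beta, pf, l1, l2):
    s1 = 0.0
    s2 = 0.0
    for j in range(beta.shape[0]):
        s1 += pf[j] * abs(beta[j])
        s2 += pf[j] * beta[j] * beta[j]
    return l1 * s1 + 0.5 * l2 * s2


@njit(cache=True)
def fit_path(X, event, block_of, starts, dcounts, lambdas, alpha, pf,
             max_outer, max_cd, cd_tol, outer_tol, dfmax):
    """Warm-started elastic-net Cox path by IRLS + cyclic coordinate descent.

    ``X`` must be Fortran-ordered standardised predictors; ``pf`` is the
    per-column penalty factor (0 = unpenalised).  Inner coordinate descent
    runs on the active set; the full KKT sweep is performed after each
    IRLS convergence and the subproblem re-entered on violations, so every
    reported solution passes a complete KKT audit.  The path stops early
    once the nonzero count exceeds ``dfmax`` (saturated fits carry no
    selection information).

    Returns (betas, n_iter, status, n_computed): betas (p, n_lambda) on
    the standardised scale; status 1 flags a lambda where step-halving
    could not restore descent, status 2 an iteration cap hit before
    convergence.
    """
    n, p = X.shape
    nlam = lambdas.shape[0]
    betas = np.zeros((p, nlam))
    n_iter = np.zeros(nlam, dtype=np.int64)
    status = np.zeros(nlam, dtype=np.int64)
    beta = np.zeros(p)
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        if pf[j] == 0.0:
            active[j] = True
    eta = np.zeros(n)
    aj = np.empty(p)
    res = np.empty(n)
    n_computed = nlam

    ll, g, w = cox_breslow_derivs(eta, event, block_of, starts, dcounts)
    ll_null = ll
    dr_prev = 0.0
    for li in range(nlam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        obj = -ll / n + _penalty(beta, pf, l1, l2)
        outer = 0
        ok = False
        # alternate: IRLS-to-convergence on the active set, then a full KKT
        # sweep on the true score; re-enter when new predictors activate
        for _round in range(max_outer):
            done = False
            while not done and outer < max_outer:
                outer += 1
                beta_prev = beta.copy()
                eta_prev = eta.copy()
                for i in range(n):
                    res[i] = g[i] / w[i]
                for j in range(p):
                    aj[j] = -1.0
                for _sweep in range(max_cd):
                    dmax = 0.0
                    for j in range(p):
                        if not active[j]:
                            continue
                        if aj[j] < 0.0:
                            s = 0.0
                            for i in range(n):
                                s += w[i] * X[i, j] * X[i, j]
                            aj[j] = s / n
                        bj = beta[j]
                        num = 0.0
                        for i in range(n):
                            num += w[i] * X[i, j] * res[i]
                        num = num / n + bj * aj[j]
                        if pf[j] > 0.0:
                            bnew = _soft(num, l1 * pf[j]) / (aj[j] + l2 * pf[j])
                        else:
                            bnew = num / aj[j]
                        if bnew != bj:
                            delta = bnew - bj
                            for i in range(n):
                                res[i] -= delta * X[i, j]
                            beta[j] = bnew
                            ch = abs(delta) * np.sqrt(aj[j])
                            if ch > dmax:
                                dmax = ch
                    if dmax < cd_tol:
                        break
                # eta_new = eta + g/w - res (incremental WLS fitted values)
                for i in range(n):
                    eta[i] = eta_prev[i] + g[i] / w[i] - res[i]
                ll, g, w = cox_breslow_derivs(eta, event, block_of, starts, dcounts)
                obj_new = -ll / n + _penalty(beta, pf, l1, l2)
                halvings = 0
                while obj_new > obj + 1e-12 and halvings < 20:
                    for j in range(p):
                        beta[j] = 0.5 * (beta[j] + beta_prev[j])
                    for i in range(n):
                        eta[i] = 0.5 * (eta[i] + eta_prev[i])
                    ll, g, w = cox_breslow_derivs(eta, event, block_of, starts, dcounts)
                    obj_new = -ll / n + _penalty(beta, pf, l1, l2)
                    halvings += 1
                if obj_new > obj + 1e-10:
                    status[li] = 1
                dbeta = 0.0
                for j in range(p):
                    dlt = abs(beta[j] - beta_prev[j])
                    if dlt > dbeta:
                        dbeta = dlt
                if dbeta < outer_tol or abs(obj - obj_new) < 1e-11 * (abs(obj_new) + 1.0):
                    done = True
                obj = obj_new
            # full KKT sweep with the true partial-likelihood score
            violation = False
            for j in range(p):
                if active[j]:
                    continue
                s = 0.0
                for i in range(n):
                    s += X[i, j] * g[i]
                if abs(s / n) > l1 * pf[j] + 1e-9:
                    active[j] = True
                    violation = True
            if not violation:
                ok = done
                break
        if not ok and status[li] == 0:
            status[li] = 2  # iteration cap without convergence
        n_iter[li] = outer
        nnz = 0
        for j in range(p):
            betas[j, li] = beta[j]
            active[j] = beta[j] != 0.0 or pf[j] == 0.0
            if beta[j] != 0.0:
                nnz += 1
        if nnz > dfmax:
            n_computed = li + 1
            break
        # deviance-ratio early stopping (saturation carries no selection
        # information and the partial likelihood degenerates)
        dr = 1.0 - ll / ll_null if ll_null != 0.0 else 0.0
        if li > 0 and (dr > 0.999 or dr - dr_prev < 1e-5):
            n_computed = li + 1
            break
        dr_prev = dr
    return betas, n_iter, status, n_computed
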