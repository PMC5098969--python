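"""L1-penalized sparse inverse-covariance (graphical lasso) solver.

Block coordinate descent in the covariance space (one lasso problem per
column), with the diagonal left unpenalized so that the estimated covariance
keeps the sample variances.  The whole lambda path runs warm-started inside
a single jitted kernel, which is what makes the bootstrap machinery (each
replicate refits a full path) affordable on one CPU.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso", "glasso_path", "covsel"]


@njit(cache=True)
def _lasso_cd(W11, s12, beta, lam, tol, max_iter):
    """Coordinate descent for 0.5 b'W11 b - s12'b + lam*||b||_1 (in place)."""
    p1 = W11.shape[0]
    for _ in range(max_iter):
        d_max = 0.0
        for j in range(p1):
            old = beta[j]
            # residual gradient excluding coordinate j
            r = s12[j]
            for k in range(p1):
                if k != j:
                    r -= W11[j, k] * beta[k]
            if r > lam:
                new = (r - lam) / W11[j, j]
            elif r < -lam:
                new = (r + lam) / W11[j, j]
            else:
                new = 0.0
            beta[j] = new
            d = abs(new - old)
            if d > d_max:
                d_max = d
        if d_max < tol:
            break
    return beta


@njit(cache=True)
def _glasso_one(S, lam, W, B, tol, max_iter, inner_max_iter):
    """One glasso fit, warm-started from covariance W and coefficients B.

    Returns (W, B, K, n_iter, converged).  B[:, j] holds the lasso
    coefficients of column j against the other variables.
    """
    p = S.shape[0]
    # diagonal is unpenalized: keep sample variances
    for i in range(p):
        W[i, i] = S[i, i]
    off = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off += abs(S[i, j])
                cnt += 1
    thr = tol * (off / cnt if cnt > 0 and off > 0 else 1.0)
    inner_tol = 0.1 * thr

    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        delta = 0.0
        for j in range(p):
            # partition: W11 = W[-j,-j], s12 = S[-j,j]
            W11 = np.empty((p - 1, p - 1))
            s12 = np.empty(p - 1)
            beta = np.empty(p - 1)
            r = 0
            for a in range(p):
                if a == j:
                    continue
                s12[r] = S[a, j]
                beta[r] = B[a, j] if a < j else B[a, j]
                c = 0
                for b in range(p):
                    if b == j:
                        continue
                    W11[r, c] = W[a, b]
                    c += 1
                r += 1
            _lasso_cd(W11, s12, beta, lam, inner_tol, inner_max_iter)
            # w12 = W11 @ beta
            r = 0
            for a in range(p):
                if a == j:
                    continue
                w = 0.0
                for c in range(p - 1):
                    w += W11[r, c] * beta[c]
                d = abs(w - W[a, j])
                if d > delta:
                    delta = d
                W[a, j] = w
                W[j, a] = w
                B[a, j] = beta[r]
                r += 1
        if delta < thr:
            converged = True
            break

    # recover precision from (W, B):  K_jj = 1/(w_jj - w12'beta), K_1j = -beta*K_jj
    K = np.zeros((p, p))
    for j in range(p):
        q = W[j, j]
        r = 0
        for a in range(p):
            if a == j:
                continue
            q -= W[a, j] * B[a, j]
            r += 1
        if q < 1e-12:
            q = 1e-12
        kjj = 1.0 / q
        K[j, j] = kjj
        for a in range(p):
            if a != j:
                K[a, j] = -B[a, j] * kjj
    # symmetrize (the two column solutions agree at convergence)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            # preserve exact zeros of the lasso support
            if K[i, j] == 0.0 or K[j, i] == 0.0:
                v = 0.0
            K[i, j] = v
            K[j, i] = v
    return W, B, K, n_iter, converged


@njit(cache=True)
def _glasso_path_kernel(S, lams, tol, max_iter, inner_max_iter):
    p = S.shape[0]
    n_l = lams.shape[0]
    Ks = np.zeros((n_l, p, p))
    Ws = np.zeros((n_l, p, p))
    iters = np.zeros(n_l, dtype=np.int64)
    ok = np.zeros(n_l, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p))
    for li in range(n_l):
        W, B, K, it, conv = _glasso_one(
            S, lams[li], W, B, tol, max_iter, inner_max_iter
        )
        Ks[li] = K
        Ws[li] = W
        iters[li] = it
        ok[li] = conv
    return Ks, Ws, iters, ok


@njit(cache=True)
def _covsel_kernel(S, support, tol, max_iter):
    """Support-restricted MLE of the precision matrix (covariance selection).

    Block coordinate ascent: each column solves the unpenalized regression
    over its allowed (support) entries only.  Returns (K, converged).
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    off = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off += abs(S[i, j])
                cnt += 1
    thr = tol * (off / cnt if cnt > 0 and off > 0 else 1.0)
    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            sup = np.empty(p - 1, dtype=np.int64)
            ns = 0
            r = 0
            for a in range(p):
                if a == j:
                    continue
                if support[a, j]:
                    sup[ns] = r
                    ns += 1
                r += 1
            beta = np.zeros(p - 1)
            if ns > 0:
                W11s = np.empty((ns, ns))
                s12s = np.empty(ns)
                rows = np.empty(ns, dtype=np.int64)
                r = 0
                k = 0
                for a in range(p):
                    if a == j:
                        continue
                    if support[a, j]:
                        rows[k] = a
                        k += 1
                    r += 1
                for x in range(ns):
                    s12s[x] = S[rows[x], j]
                    for y in range(ns):
                        W11s[x, y] = W[rows[x], rows[y]]
                bs = np.linalg.solve(W11s, s12s)
                for x in range(ns):
                    beta[sup[x]] = bs[x]
            # w12 = W11 @ beta
            r = 0
            for a in range(p):
                if a == j:
                    continue
                w = 0.0
                c = 0
                for b in range(p):
                    if b == j:
                        continue
                    w += W[a, b] * beta[c]
                    c += 1
                d = abs(w - W[a, j])
                if d > delta:
                    delta = d
                W[a, j] = w
                W[j, a] = w
                B[a, j] = beta[r]
                r += 1
        if delta < thr:
            converged = True
            break
    K = np.zeros((p, p))
    for j in range(p):
        q = W[j, j]
        for a in range(p):
            if a != j:
                q -= W[a, j] * B[a, j]
        if q < 1e-12:
            q = 1e-12
        kjj = 1.0 / q
        K[j, j] = kjj
        for a in range(p):
            if a != j:
                if support[a, j]:
                    K[a, j] = -B[a, j] * kjj
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, converged


def covsel(S, support, tol=1e-6, max_iter=500):
    """MLE precision with zeros enforced off the given symmetric support."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    support = np.ascontiguousarray(support, dtype=np.bool_)
    K, converged = _covsel_kernel(S, support, tol, max_iter)
    return K, converged


def glasso(S, lam, tol=1e-4, max_iter=200, inner_max_iter=500):
    """Single graphical-lasso fit; returns (covariance, precision, info)."""
    S = np.ascontiguousarray(S, dtype=np.float64)
    lams = np.array([float(lam)])
    Ks, Ws, iters, ok = _glasso_path_kernel(S, lams, tol, max_iter, inner_max_iter)
    info = {"n_iter": int(iters[0]), "converged": bool(ok[0])}
    return Ws[0], Ks[0], info


def glasso_path(S, lams, tol=1e-4, max_iter=200, inner_max_iter=500):
    """Warm-started fits along a decreasing lambda sequence.

    Returns (precisions, covariances, n_iters, converged_flags), precisions
    of shape (n_lambda, p, p).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    Ks, Ws, iters, ok = _glasso_path_kernel(S, lams, tol, max_iter, inner_max_iter)
    return Ks, Ws, iters, ok
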