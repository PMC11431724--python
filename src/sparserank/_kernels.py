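"""Coordinate-descent inner loops.

Written in njit-compatible Python and compiled with numba when available;
the uncompiled functions are exact fallbacks.  Each kernel mutates
``beta`` in place and alternates full cyclic sweeps with active-set
refinement sweeps until the largest absolute coefficient change in a full
sweep falls below ``tol``.
"""

from __future__ import annotations

import numpy as np


def _cd_gram(G, c, beta, pen, tol, max_iter):
    """Gaussian CD with cached Gram matrix G = X'X/n, c = X'y_c/n."""
    p = beta.shape[0]
    grad = c - G @ beta
    iters = 0
    converged = False
    while iters < max_iter:
        dmax = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            u = grad[j] + gjj * beta[j]
            t = pen[j]
            if u > t:
                bj = (u - t) / gjj
            elif u < -t:
                bj = (u + t) / gjj
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                for i in range(p):
                    grad[i] -= G[i, j] * d
                beta[j] = bj
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        iters += 1
        if dmax < tol:
            converged = True
            break
        while iters < max_iter:
            dmax = 0.0
            for j in range(p):
                if beta[j] == 0.0 and pen[j] > 0.0:
                    continue
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                u = grad[j] + gjj * beta[j]
                t = pen[j]
                if u > t:
                    bj = (u - t) / gjj
                elif u < -t:
                    bj = (u + t) / gjj
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    for i in range(p):
                        grad[i] -= G[i, j] * d
                    beta[j] = bj
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            iters += 1
            if dmax < tol:
                break
    return iters, converged


def _cd_naive(X, r, beta, pen, xsq, tol, max_iter):
    """Gaussian CD with residual updates; r = y_c - X beta kept in place."""
    n, p = X.shape
    iters = 0
    converged = False
    while iters < max_iter:
        dmax = 0.0
        for j in range(p):
            gjj = xsq[j]
            if gjj <= 0.0:
                continue
            u = 0.0
            for i in range(n):
                u += X[i, j] * r[i]
            u = u / n + gjj * beta[j]
            t = pen[j]
            if u > t:
                bj = (u - t) / gjj
            elif u < -t:
                bj = (u + t) / gjj
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = bj
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        iters += 1
        if dmax < tol:
            converged = True
            break
        while iters < max_iter:
            dmax = 0.0
            for j in range(p):
                if beta[j] == 0.0 and pen[j] > 0.0:
                    continue
                gjj = xsq[j]
                if gjj <= 0.0:
                    continue
                u = 0.0
                for i in range(n):
                    u += X[i, j] * r[i]
                u = u / n + gjj * beta[j]
                t = pen[j]
                if u > t:
                    bj = (u - t) / gjj
                elif u < -t:
                    bj = (u + t) / gjj
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bj
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            iters += 1
            if dmax < tol:
                break
    return iters, converged


def _cd_weighted(A, v, sxw, sw, swz, beta, b0, pen, tol, max_iter):
    """Weighted least squares CD (IRLS inner loop) on cached products.

    A = X'WX/n, v = X'Wz/n, sxw = X'w/n, sw = mean(w), swz = w.z/n; the
    unpenalized intercept b0 is refreshed at the top of every sweep.
    """
    p = beta.shape[0]
    m = A @ beta
    iters = 0
    converged = False
    while iters < max_iter:
        b0_new = (swz - np.dot(sxw, beta)) / sw
        dmax = abs(b0_new - b0)
        b0 = b0_new
        for j in range(p):
            gjj = A[j, j]
            if gjj <= 0.0:
                continue
            u = v[j] - m[j] - sxw[j] * b0 + gjj * beta[j]
            t = pen[j]
            if u > t:
                bj = (u - t) / gjj
            elif u < -t:
                bj = (u + t) / gjj
            else:
                bj = 0.0
            d = bj - beta[j]
            if d != 0.0:
                for i in range(p):
                    m[i] += A[i, j] * d
                beta[j] = bj
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
        iters += 1
        if dmax < tol:
            converged = True
            break
        while iters < max_iter:
            b0_new = (swz - np.dot(sxw, beta)) / sw
            dmax = abs(b0_new - b0)
            b0 = b0_new
            for j in range(p):
                if beta[j] == 0.0 and pen[j] > 0.0:
                    continue
                gjj = A[j, j]
                if gjj <= 0.0:
                    continue
                u = v[j] - m[j] - sxw[j] * b0 + gjj * beta[j]
                t = pen[j]
                if u > t:
                    bj = (u - t) / gjj
                elif u < -t:
                    bj = (u + t) / gjj
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    for i in range(p):
                        m[i] += A[i, j] * d
                    beta[j] = bj
                    ad = abs(d)
                    if ad > dmax:
                        dmax = ad
            iters += 1
            if dmax < tol:
                break
    return b0, iters, converged


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    cd_gram = njit(cache=True)(_cd_gram)
    cd_naive = njit(cache=True)(_cd_naive)
    cd_weighted = njit(cache=True)(_cd_weighted)
except Exception:  # numba unavailable: identical, slower
    cd_gram = _cd_gram
    cd_naive = _cd_naive
    cd_weighted = _cd_weighted
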