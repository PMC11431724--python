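"""Independent oracles used by the test suite.

These deliberately avoid the package's solution paths: the weighted-lasso
oracle enumerates active-set sign patterns and solves the stationarity
system directly, and the AUC oracle counts positive-negative pairs.
"""

from __future__ import annotations

import itertools

import numpy as np


def weighted_lasso_oracle(X, y, w, lam, tol=1e-9):
    """Exact minimizer of (1/2n)||y - b0 - Xb||^2 + lam * sum w_j |b_j|.

    Enumerates all 3^p sign patterns, solves the stationarity equations on
    the active set, and returns the first pattern whose solution satisfies
    the KKT conditions.  Feasible only for small p.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        active = np.flatnonzero(s != 0)
        beta = np.zeros(p)
        if active.size:
            XA = Xc[:, active]
            rhs = XA.T @ yc / n - lam * w[active] * s[active]
            try:
                beta_a = np.linalg.solve(XA.T @ XA / n, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(np.sign(beta_a) != s[active]):
                continue
            beta[active] = beta_a
        g = Xc.T @ (yc - Xc @ beta) / n
        inactive = s == 0
        if np.any(np.abs(g[inactive]) > lam * w[inactive] + tol):
            continue
        intercept = y.mean() - X.mean(axis=0) @ beta
        return beta, intercept
    raise RuntimeError("no sign pattern satisfied the KKT conditions")


def auc_pair_count(truth, score):
    """AUC by brute force over all positive-negative pairs (ties count 1/2)."""
    truth = np.asarray(truth)
    score = np.asarray(score, float)
    pos = score[truth == 1]
    neg = score[truth == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
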