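"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: ranking uses
scipy.stats.pearsonr per column, OLS uses the normal equations, the nested
cross-validation is a literal double loop, and BH is the literal
min-over-tail formula.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def oracle_rank(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Sort columns by decreasing |r|, ties by input order, zero-variance last."""
    keys = []
    y_sd = np.std(y)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0:
            keys.append((1, 0.0, j))
            continue
        r = stats.pearsonr(col, y)[0] if y_sd > 0 else 0.0
        if not np.isfinite(r):
            r = 0.0
        keys.append((0, -abs(r), j))
    return [j for _, _, j in sorted(keys)]


def oracle_fit_predict(X_tr, y_tr, x_new, standardize=True):
    """OLS via the explicit normal equations, training-fold z-scoring."""
    X_tr = np.atleast_2d(np.asarray(X_tr, float))
    x_new = np.asarray(x_new, float)
    if X_tr.shape[1] == 0:
        return float(np.mean(y_tr))
    if standardize:
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(X_tr.shape[1]), np.ones(X_tr.shape[1])
    Z = (X_tr - mu) / sd
    D = np.column_stack([np.ones(len(y_tr)), Z])
    beta = np.linalg.solve(D.T @ D, D.T @ np.asarray(y_tr, float))
    zn = (x_new - mu) / sd
    return float(beta[0] + zn @ beta[1:])


def oracle_inner_k(X_tr, y_tr, k_grid):
    """Literal inner LOO over every candidate k, re-ranking per split."""
    n = len(y_tr)
    feasible = [k for k in k_grid if k <= n - 3] or [min(k_grid)]
    mses = {}
    for k in feasible:
        errs = []
        for m in range(n):
            tr = np.arange(n) != m
            order = oracle_rank(X_tr[tr], y_tr[tr])
            sel = order[:k]
            pred = oracle_fit_predict(X_tr[tr][:, sel], y_tr[tr], X_tr[m, sel])
            errs.append((y_tr[m] - pred) ** 2)
        mses[k] = float(np.mean(errs))
    best = min(mses, key=lambda k: (mses[k], k))
    return best, mses


def oracle_nested_loocv(X, y, k_grid):
    """Literal double-loop nested LOOCV."""
    n = len(y)
    preds = np.empty(n)
    ks, sels = [], []
    for i in range(n):
        tr = np.arange(n) != i
        k, _ = oracle_inner_k(X[tr], y[tr], k_grid)
        order = oracle_rank(X[tr], y[tr])
        sel = order[:k]
        preds[i] = oracle_fit_predict(X[tr][:, sel], y[tr], X[i, sel])
        ks.append(k)
        sels.append(list(sel))
    r, p = stats.pearsonr(y, preds)
    return preds, ks, sels, float(r), float(p)


def oracle_bh(p_values):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def oracle_permutation_pearson_p(x, y, n_perm=100_000, seed=0):
    """Two-sided permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(stats.pearsonr(x, y)[0])
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = len(x)
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_perm = np.abs(perms @ xc) / n
    return float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))
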