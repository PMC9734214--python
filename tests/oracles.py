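"""Independent reference implementations used as test oracles.

These deliberately use naive dense linear algebra (explicit inverses,
double loops) and never share code paths with the package internals.
"""

from __future__ import annotations

import numpy as np


def gls_conditional_oracle(
    y_train: np.ndarray,
    x_full: np.ndarray,
    components: list[tuple[np.ndarray, float]],
    sigma_e: float,
    train: np.ndarray,
    test: np.ndarray,
) -> np.ndarray:
    """Dense GLS + conditional-Gaussian prediction with fixed variances.

    ``components`` is a list of (full kernel, variance).  Returns predicted
    values for the test samples.
    """
    n_tr = train.size
    v = sigma_e * np.eye(n_tr)
    for k, s2 in components:
        v = v + s2 * k[np.ix_(train, train)]
    vinv = np.linalg.inv(v)
    x_tr = x_full[train]
    beta = np.linalg.inv(x_tr.T @ vinv @ x_tr) @ (x_tr.T @ vinv @ y_train)
    resid = y_train - x_tr @ beta
    pred = x_full[test] @ beta
    for k, s2 in components:
        pred = pred + s2 * k[np.ix_(test, train)] @ vinv @ resid
    return pred


def henderson_mme_predict(
    y_train: np.ndarray,
    g_full: np.ndarray,
    lam: float,
    train: np.ndarray,
    test: np.ndarray,
) -> np.ndarray:
    """Henderson mixed-model equations for an intercept + one kernel.

    Solves [X'X X'Z; Z'X Z'Z + lam*Ginv][b;u] = [X'y; Z'y] on the training
    block (Z = I) and extends BLUPs to test samples through the conditional
    mean of the joint kernel.
    """
    n_tr = train.size
    x = np.ones((n_tr, 1))
    z = np.eye(n_tr)
    g_tr = g_full[np.ix_(train, train)]
    ginv = np.linalg.inv(g_tr)
    top = np.hstack([x.T @ x, x.T @ z])
    bot = np.hstack([z.T @ x, z.T @ z + lam * ginv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([x.T @ y_train, z.T @ y_train])
    sol = np.linalg.solve(lhs, rhs)
    mu, u_tr = sol[0], sol[1:]
    u_te = g_full[np.ix_(test, train)] @ ginv @ u_tr
    return mu + u_te


def brute_force_vanraden(dosage: np.ndarray) -> np.ndarray:
    """Two-loop additive relationship matrix (VanRaden method 1)."""
    n, m = dosage.shape
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = dosage[:, poly]
    p = p[poly]
    denom = 2.0 * sum(pj * (1 - pj) for pj in p)
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(d.shape[1]):
                acc += (d[i, k] - 2 * p[k]) * (d[j, k] - 2 * p[k])
            g[i, j] = acc / denom
    return g


def brute_force_rogers(dosage: np.ndarray) -> np.ndarray:
    """Per-marker sqrt(0.5 * sum of squared allele-frequency differences),
    averaged over markers, by explicit loops."""
    n, m = dosage.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0.0
            for k in range(m):
                pi, pj = dosage[i, k] / 2.0, dosage[j, k] / 2.0
                # two alleles: frequencies (p, 1-p)
                total += np.sqrt(0.5 * ((pi - pj) ** 2 + ((1 - pi) - (1 - pj)) ** 2))
            d[i, j] = total / m
    return d


def classical_scaling_oracle(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Direct eigendecomposition route for classical scaling."""
    n = dist.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * h @ (dist**2) @ h
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1]
    return w[idx], v[:, idx]


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / np.sqrt((am @ am) * (bm @ bm)))
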