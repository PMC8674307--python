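"""Independently coded parametric ComBat, used only as a test oracle.

Deliberately plain: explicit per-feature and per-site loops, normal-equations
solves, and scalar EB updates, written directly from the location/scale model

    y_ijv = alpha_v + X_ij' beta_v + gamma_iv + delta_iv eps_ijv

with moment-matched normal / inverse-gamma hyperpriors and iterated
conditional posterior-mean updates. It shares no code with
fcharmonize.harmonize.combat.
"""

from __future__ import annotations

import numpy as np


def reference_combat(
    y: np.ndarray,
    site_labels: list[str],
    covariates: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """Return the ComBat-adjusted copy of ``y`` (n subjects x V features)."""
    y = np.asarray(y, dtype=float)
    n, V = y.shape
    sites = sorted(set(site_labels))
    S = len(sites)
    members = {s: [j for j, lab in enumerate(site_labels) if lab == s] for s in sites}
    n_i = {s: len(members[s]) for s in sites}
    q = covariates.shape[1] if covariates.size else 0

    # design: site one-hot then covariates
    X = np.zeros((n, S + q))
    for k, s in enumerate(sites):
        for j in members[s]:
            X[j, k] = 1.0
    if q:
        X[:, S:] = covariates

    alpha = np.zeros(V)
    cov_fit = np.zeros((n, V))
    sigma2 = np.zeros(V)
    for v in range(V):
        b = np.linalg.solve(X.T @ X, X.T @ y[:, v])
        alpha[v] = sum(n_i[s] * b[k] for k, s in enumerate(sites)) / n
        for j in range(n):
            cov_fit[j, v] = sum(X[j, S + c] * b[S + c] for c in range(q))
        resid = y[:, v] - X @ b
        sigma2[v] = float(resid @ resid) / n

    z = np.zeros_like(y)
    for v in range(V):
        z[:, v] = (y[:, v] - alpha[v] - cov_fit[:, v]) / np.sqrt(sigma2[v])

    out = np.zeros_like(y)
    for k, s in enumerate(sites):
        idx = members[s]
        ni = n_i[s]
        g_hat = np.array([np.mean([z[j, v] for j in idx]) for v in range(V)])
        d_hat = np.array(
            [sum((z[j, v] - g_hat[v]) ** 2 for j in idx) / (ni - 1) for v in range(V)]
        )
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        lam = (m**2 + 2 * s2) / s2
        theta = (m**3 + m * s2) / s2

        g_star = g_hat.copy()
        d_star = d_hat.copy()
        for _ in range(max_iter):
            g_new = (ni * t2 * g_hat + d_star * g_bar) / (ni * t2 + d_star)
            d_new = np.array(
                [
                    (theta + 0.5 * sum((z[j, v] - g_new[v]) ** 2 for j in idx))
                    / (ni / 2 + lam - 1)
                    for v in range(V)
                ]
            )
            change = max(abs(g_new - g_star).max(), abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change <= tol:
                break
        for v in range(V):
            for j in idx:
                out[j, v] = (
                    np.sqrt(sigma2[v]) * (z[j, v] - g_star[v]) / np.sqrt(d_star[v])
                    + alpha[v]
                    + cov_fit[j, v]
                )
    return out
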