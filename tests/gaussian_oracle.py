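"""Brute-force joint-Gaussian oracle for linear state-space smoothing.

Independent of the Kalman recursions: stacks all states of a short series
into one multivariate normal, conditions on the observed entries directly,
and evaluates the observed-data log-density in closed form. Only feasible
for n*k of a few hundred — which is the point: it cross-checks the filter
and RTS smoother on small problems without sharing any code with them.
"""

import numpy as np
from scipy.stats import multivariate_normal


def joint_gaussian_smooth(ssm, y):
    """Return (smoothed state means (n, k), loglik of observed entries)."""
    y = np.asarray(y, dtype=float)
    n, k = y.size, ssm.k
    T, Z, H = ssm.T, ssm.Z, ssm.H
    RQRt = ssm.R @ ssm.Q @ ssm.R.T

    # state means: a_mean_t = T^t a0
    a_means = np.empty((n, k))
    a = ssm.a0.copy()
    for t in range(n):
        a = T @ a
        a_means[t] = a

    # state covariance blocks: C[t][t] by recursion, C[t][u] = C[t][t] (T^T)^(u-t)
    diag = []
    P = T @ ssm.P0 @ T.T + RQRt
    for t in range(n):
        diag.append(P)
        P = T @ P @ T.T + RQRt
    C = [[None] * n for _ in range(n)]
    for t in range(n):
        C[t][t] = diag[t]
        for u in range(t + 1, n):
            C[t][u] = C[t][u - 1] @ T.T
            C[u][t] = C[t][u].T
    C = np.block(C)

    Zfull = np.kron(np.eye(n), Z.reshape(1, -1))
    Cy = Zfull @ C @ Zfull.T + H * np.eye(n)
    mu_y = Zfull @ a_means.ravel()

    obs = ~np.isnan(y)
    Coo = Cy[np.ix_(obs, obs)]
    resid = y[obs] - mu_y[obs]
    loglik = multivariate_normal(mean=np.zeros(obs.sum()), cov=Coo,
                                 allow_singular=True).logpdf(resid)
    gain = C @ Zfull.T[:, obs]
    cond_mean = a_means.ravel() + gain @ np.linalg.solve(Coo, resid)
    return cond_mean.reshape(n, k), float(loglik)


def random_ssm(rng, k_max=5):
    """A random stable time-invariant model for oracle comparisons."""
    from gapfill.kalman import StateSpaceModel

    k = int(rng.integers(1, k_max + 1))
    A = rng.normal(size=(k, k))
    # scale to spectral radius < 1 so covariances stay moderate
    T = 0.9 * A / max(np.abs(np.linalg.eigvals(A)).max(), 1e-6)
    Z = rng.normal(size=k)
    q = int(rng.integers(1, k + 1))
    R = rng.normal(size=(k, q))
    L = rng.normal(size=(q, q)) * 0.5
    Q = L @ L.T + 0.1 * np.eye(q)
    H = float(rng.uniform(0.05, 1.0))
    a0 = rng.normal(size=k)
    P0 = np.eye(k) * float(rng.uniform(0.5, 2.0))
    return StateSpaceModel(T=T, Z=Z, R=R, Q=Q, H=H, a0=a0, P0=P0)
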