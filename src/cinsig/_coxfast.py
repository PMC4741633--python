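"""Lean Newton solver for the Cox partial likelihood (Breslow ties).

This is the inner engine of the bagged subset search, where hundreds of
thousands of small unadjusted fits are needed; it trades generality for
speed (dense numpy, p <= ~10 covariates).  It is validated against the
general-purpose fitter in :mod:`cinsig.survival` in the test suite.
"""

from __future__ import annotations

import numpy as np


def breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Breslow partial log-likelihood at ``beta`` (reference evaluation)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return float(ll)


def breslow_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Returns (beta, converged).  Ties share a common risk set (Breslow).
    Degenerate designs (no events, constant columns) return zero
    coefficients with ``converged=False`` for the affected directions
    handled by a tiny ridge.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    d = event.astype(float)
    if d.sum() == 0:
        return np.zeros(p), False

    # sort by descending time: risk sets become prefixes
    order = np.argsort(-time, kind="stable")
    X = X[order]
    t = time[order]
    d = d[order]
    # last index of each tie group (all subjects with t >= t_i)
    # t is descending, so -t ascending; rightmost equal element:
    last = np.searchsorted(-t, -t, side="right") - 1

    ev = d > 0
    lastev = last[ev]
    # risk-set sums S0/S1/S2 come from one cumulative sum of [1, x, x x^T]*w
    A = np.empty((n, 1 + p + p * p))
    A[:, 0] = 1.0
    A[:, 1:1 + p] = X
    A[:, 1 + p:] = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    Xev = X[ev]
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max()  # ratios of cumsums are shift-invariant
        w = np.exp(eta)
        C = np.cumsum(A * w[:, None], axis=0)[lastev]
        S0 = C[:, 0]
        S1 = C[:, 1:1 + p]
        S2 = C[:, 1 + p:].reshape(-1, p, p)

        mean = S1 / S0[:, None]
        grad = (Xev - mean).sum(axis=0)
        hess = (S2 / S0[:, None, None]).sum(axis=0) - mean.T @ mean
        ll = float(np.sum(eta[ev] - np.log(S0)))

        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, False
        # step-halving if the likelihood does not improve
        new = beta + step
        for _half in range(20):
            eta_n = X @ new
            eta_n -= eta_n.max()
            w_n = np.exp(eta_n)
            S0_n = np.cumsum(w_n)[lastev]
            ll_new = float(np.sum(eta_n[ev] - np.log(S0_n)))
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
            new = beta + step
        beta = new
        if np.max(np.abs(grad)) < tol or abs(ll_new - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll_new
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50:
        return np.zeros(p), False
    return beta, converged
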