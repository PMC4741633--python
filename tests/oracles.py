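"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent route
available (grid search, exhaustive enumeration, textbook message
passing) and is kept independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from lifelines import KaplanMeierFitter


def grid_breslow_coefficient(x, time, event, lo=-5.0, hi=5.0, steps=100001):
    """Brute-force maximization of the Breslow partial likelihood for a
    single covariate over a fine grid."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    grid = np.linspace(lo, hi, steps)
    ll = np.zeros_like(grid)
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        eta = np.outer(grid, x[risk])
        ll += grid * x[i] - np.log(np.exp(eta).sum(axis=1))
    return float(grid[np.argmax(ll)])


def nested_km_roc_auc(marker, time, event, t_star):
    """Cumulative/dynamic AUC by exhaustive per-cutpoint evaluation.

    For every observed cutpoint c the sensitivity/specificity formulas
    are evaluated directly with a product-limit estimate inside the
    subgroup {X > c} (via lifelines); the curve is rectified to be
    monotone and integrated by the trapezoid rule.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    kmf = KaplanMeierFitter().fit(time, event)
    s_all = float(kmf.predict(t_star))
    pts_f, pts_t = [0.0], [0.0]
    for c in np.unique(marker)[::-1]:
        above = marker > c
        p = above.mean()
        if above.sum() == 0:
            s_sub = 1.0
        else:
            s_sub = float(KaplanMeierFitter()
                          .fit(time[above], event[above]).predict(t_star))
        pts_t.append((1.0 - s_sub) * p / (1.0 - s_all))
        pts_f.append(s_sub * p / s_all)
    pts_f.append(1.0)
    pts_t.append(1.0)
    f = np.clip(np.maximum.accumulate(pts_f), 0, 1)
    t = np.clip(np.maximum.accumulate(pts_t), 0, 1)
    return float(np.trapezoid(t, f))


def reference_affinity_propagation(S, preference, damping=0.9, max_iter=500,
                                   conv_iter=15):
    """Textbook affinity propagation (responsibility/availability message
    passing with the standard post-convergence exemplar refinement)."""
    S = S.copy().astype(float)
    n = S.shape[0]
    np.fill_diagonal(S, preference)
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    e_hist = np.zeros((n, conv_iter), dtype=bool)
    for it in range(max_iter):
        AS = A + S
        idx1 = np.argmax(AS, axis=1)
        m1 = AS[np.arange(n), idx1]
        AS[np.arange(n), idx1] = -np.inf
        m2 = AS.max(axis=1)
        Rnew = S - m1[:, None]
        Rnew[np.arange(n), idx1] = S[np.arange(n), idx1] - m2
        R = damping * R + (1 - damping) * Rnew
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, np.diag(R))
        Anew = Rp.sum(axis=0)[None, :] - Rp
        dA = np.diag(Anew).copy()
        Anew = np.minimum(Anew, 0)
        np.fill_diagonal(Anew, dA)
        A = damping * A + (1 - damping) * Anew
        E = (np.diag(A) + np.diag(R)) > 0
        e_hist[:, it % conv_iter] = E
        if it >= conv_iter:
            se = e_hist.sum(axis=1)
            if ((se == conv_iter) | (se == 0)).all() and E.sum() > 0:
                break
    exemplars = np.flatnonzero(E)
    if exemplars.size == 0:
        return None
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    for k in range(exemplars.size):
        members = np.flatnonzero(labels == k)
        exemplars[k] = members[np.argmax(
            S[np.ix_(members, members)].sum(axis=0))]
    exemplars = np.sort(exemplars)
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    return labels, exemplars
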