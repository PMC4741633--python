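"""Time-dependent (cumulative/dynamic) ROC for censored survival data.

At a horizon t, cases are subjects with events by t and controls those
event-free beyond t.  Censoring before t is handled through a
conditional survival estimator: either nested Kaplan-Meier estimates
within marker-defined subsets (``km``), or a nearest-neighbour smoothed
bivariate survival estimate (``nne``).  Sensitivity and specificity at a
marker cutpoint c follow

    TP(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
    FP(c) =      S(t | X > c)  P(X > c) /      S(t)

and the AUC is the trapezoidal integral over all observed cutpoints.
The raw KM-based curve can be locally non-monotone; curves are
rectified by a running maximum over decreasing cutpoints so the stored
(fpr, tpr) pairs are monotone with endpoints (0,0) and (1,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .survival import SurvivalOutcome

__all__ = ["TdRocResult", "survival_auc", "choose_eval_time", "km_auc"]


@dataclass
class TdRocResult:
    eval_time: float
    cutpoints: np.ndarray  # descending marker cutpoints (curve order)
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    estimator: str
    n_cases: float
    n_controls: float


class _TimeStruct:
    """Precomputed event-time incidence used by the nested-KM estimator.

    ``atrisk[i, k] = 1{t_i >= u_k}`` and ``dev[i, k] = 1{t_i = u_k, d_i = 1}``
    over the unique times ``u_k <= t_star``; reusable across markers on
    the same (time, event, t_star) triple.
    """

    def __init__(self, time, event, t_star, dtype=np.float64):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event)
        self.t_star = float(t_star)
        time = self.time
        event = self.event
        # only death times contribute product-limit factors
        u = np.unique(time[(event == 1) & (time <= t_star)])
        self.n = time.size
        k = self.k = u.size
        both = np.zeros((self.n, 2 * k), dtype=dtype)
        both[:, :k] = time[:, None] >= u[None, :]
        hit = (event == 1) & (time <= t_star)
        if hit.any():
            both[np.flatnonzero(hit), k + np.searchsorted(u, time[hit])] = 1.0
        self.both = both  # [at-risk | death] incidence, one cumsum at use

    def km_prefix(self, order):
        """KM survival at t_star for every prefix of ``order`` (descending-
        marker subject order); element j is S(t_star | first j+1 subjects)."""
        k = self.k
        C = np.cumsum(self.both[order], axis=0)
        R = C[:, :k]
        D = C[:, k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(R > 0, 1.0 - D / np.where(R > 0, R, 1.0), 1.0)
        return np.prod(frac, axis=1)


def _km_curve_points(marker, time, event, t_star, struct=None):
    """Nested-KM sensitivity/specificity at every cutpoint.

    Subjects above a cutpoint form a prefix of the descending-marker
    ordering, so all subgroup KM estimates come from one pass of prefix
    cumulative sums.  Returns (cutpoints descending, tpr, fpr, S_all)
    before monotone rectification and endpoint padding.
    """
    n = marker.size
    if struct is None:
        struct = _TimeStruct(time, event, t_star)
    order = np.argsort(-marker, kind="stable")
    S_prefix = struct.km_prefix(order)
    S_all = float(S_prefix[-1])
    if S_all >= 1.0:
        raise ValueError("no events at or before eval_time")
    if S_all <= 0.0:
        raise ValueError("no probability mass beyond eval_time (no controls)")

    m_sorted = marker[order]
    cuts = np.unique(marker)[::-1]  # descending
    # subjects strictly above cut c form a prefix; count them
    counts = np.searchsorted(-m_sorted, -cuts, side="left")
    P = counts / n
    S_sub = np.where(counts > 0, S_prefix[np.maximum(counts - 1, 0)], 1.0)
    tpr = (1.0 - S_sub) * P / (1.0 - S_all)
    fpr = S_sub * P / S_all
    return cuts, tpr, fpr, S_all


def _finalize(cuts, tpr, fpr, S_all, n, t_star, estimator):
    # running maximum over decreasing cutpoints enforces monotone curves
    tpr = np.clip(np.maximum.accumulate(tpr), 0.0, 1.0)
    fpr = np.clip(np.maximum.accumulate(fpr), 0.0, 1.0)
    fpr_c = np.concatenate([[0.0], fpr, [1.0]])
    tpr_c = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_c, fpr_c))
    return TdRocResult(
        eval_time=float(t_star),
        cutpoints=np.concatenate([[np.inf], cuts, [-np.inf]]),
        tpr=tpr_c,
        fpr=fpr_c,
        auc=auc,
        estimator=estimator,
        n_cases=float(n * (1.0 - S_all)),
        n_controls=float(n * S_all),
    )


def km_auc(marker: np.ndarray, time: np.ndarray, event: np.ndarray,
           t_star: float, struct: "_TimeStruct | None" = None) -> float:
    """Fast scalar AUC via the nested-KM estimator (engine of the search).

    ``struct`` may carry the precomputed time incidence for repeated
    calls on the same (time, event, t_star).
    """
    marker = np.asarray(marker, dtype=float)
    if np.ptp(marker) == 0:
        return 0.5
    cuts, tpr, fpr, S_all = _km_curve_points(marker, np.asarray(time, float),
                                             np.asarray(event), t_star, struct)
    tpr = np.clip(np.maximum.accumulate(tpr), 0.0, 1.0)
    fpr = np.clip(np.maximum.accumulate(fpr), 0.0, 1.0)
    return float(np.trapezoid(np.concatenate([[0.0], tpr, [1.0]]),
                              np.concatenate([[0.0], fpr, [1.0]])))


def _nne_curve_points(marker, time, event, t_star, span):
    """Nearest-neighbour smoothed bivariate survival estimator."""
    n = marker.size
    order = np.argsort(marker, kind="stable")
    pct = np.empty(n)
    pct[order] = (np.arange(n) + 1.0) / n
    u, inv = np.unique(time, return_inverse=True)
    k = u.size
    atrisk = (time[:, None] >= u[None, :]).astype(float)
    dev = np.zeros((n, k))
    dev[np.arange(n), inv] = event.astype(float)
    use = u <= t_star

    # neighbourhood kernel: percentile window of half-width `span`
    K = (np.abs(pct[:, None] - pct[None, :]) <= span).astype(float)  # i x j
    R = K @ atrisk
    D = K @ dev
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(R > 0, 1.0 - D / np.where(R > 0, R, 1.0), 1.0)
    S_i = np.prod(np.where(use[None, :], frac, 1.0), axis=1)  # S(t* | X = x_i)

    S_all = float(np.mean(S_i))
    if S_all >= 1.0:
        raise ValueError("no events at or before eval_time")
    if S_all <= 0.0:
        raise ValueError("no probability mass beyond eval_time (no controls)")
    cuts = np.unique(marker)[::-1]
    above = marker[None, :] > cuts[:, None]
    S_c = (above * S_i[None, :]).mean(axis=1)  # S(c, t*)
    P = above.mean(axis=1)
    tpr = (P - S_c) / (1.0 - S_all)
    fpr = S_c / S_all
    return cuts, tpr, fpr, S_all


def survival_auc(
    marker,
    outcome: SurvivalOutcome,
    eval_time: float,
    estimator: str = "km",
    span: float | None = None,
) -> TdRocResult:
    """Cumulative/dynamic ROC curve and AUC at horizon ``eval_time``.

    ``marker`` is a per-sample numeric array/Series aligned with
    ``outcome``.  A constant marker yields a degenerate diagonal curve
    (AUC 0.5) with a warning.
    """
    m = np.asarray(getattr(marker, "values", marker), dtype=float)
    time = outcome.time.to_numpy(dtype=float)
    event = outcome.event.to_numpy()
    if eval_time <= 0:
        raise ValueError("eval_time must be > 0")
    if m.shape[0] != time.shape[0]:
        raise ValueError("marker and outcome lengths differ")
    if not np.all(np.isfinite(m)):
        raise ValueError("marker contains non-finite values")
    if ((time <= eval_time) & (event == 1)).sum() == 0:
        raise ValueError("no events at or before eval_time")
    if np.ptp(m) == 0:
        warnings.warn("constant marker: degenerate ROC curve, AUC = 0.5")
        return TdRocResult(
            eval_time=float(eval_time),
            cutpoints=np.array([np.inf, m[0], -np.inf]),
            tpr=np.array([0.0, 0.0, 1.0]),
            fpr=np.array([0.0, 0.0, 1.0]),
            auc=0.5,
            estimator=estimator,
            n_cases=float(((time <= eval_time) & (event == 1)).sum()),
            n_controls=float((time > eval_time).sum()),
        )
    if estimator == "km":
        pts = _km_curve_points(m, time, event, eval_time)
    elif estimator == "nne":
        if span is None:
            span = 0.25 * m.size ** (-0.20)
        pts = _nne_curve_points(m, time, event, eval_time, span)
    else:
        raise ValueError("estimator must be 'km' or 'nne'")
    return _finalize(*pts, n=m.size, t_star=eval_time, estimator=estimator)


def choose_eval_time(outcome: SurvivalOutcome, rule: str = "median_followup",
                     value: float | None = None) -> float:
    """Deterministic ROC horizon.

    ``median_followup`` — median of all observed times; ``fixed`` — the
    given value; ``quantile`` — linear-interpolation quantile of the
    observed times at the given probability.
    """
    if outcome.n == 0:
        raise ValueError("empty outcome")
    times = outcome.time.to_numpy(dtype=float)
    if rule == "median_followup":
        return float(np.median(times))
    if rule == "fixed":
        if value is None or value <= 0:
            raise ValueError("fixed rule needs a positive time")
        return float(value)
    if rule == "quantile":
        if value is None or not 0 < value < 1:
            raise ValueError("quantile rule needs a probability in (0,1)")
        return float(np.quantile(times, value))
    raise ValueError(f"unknown rule {rule!r}")
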