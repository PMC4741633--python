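"""Derivation of a minimal predictive signature from an expression panel.

The search pipeline:

1. cluster the panel genes by their expression profiles (affinity
   propagation on negative squared Euclidean distances);
2. screen every gene with an adjusted Cox model per treatment arm,
   looking for genes significant in the anthracycline arm but not in the
   CMF arm;
3. build a candidate list with cluster-size-weighted quotas (each
   cluster represented at least once);
4. enumerate every candidate subset of the requested sizes;
5. score each subset by bagged time-dependent survival AUC: repeated
   event-stratified 60/40 train/test splits per arm, an unadjusted Cox
   fit of the subset on the training part, and the test-set
   cumulative/dynamic AUC at the arm's median follow-up; the median AUC
   over replicates is the bagged statistic;
6. rank subsets by the treated-minus-control median-AUC differential
   (a predictive signature should rank outcomes well only in the
   treated arm) and pick the winner;
7. refit the winning genes jointly with the clinical covariates on the
   merged cohort; their coefficients become the signature weights.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from ._coxfast import breslow_fit
from .matrix import ExpressionMatrix
from .signatures import SignatureDefinition
from .survival import SurvivalOutcome, fit_cox
from .tdroc import choose_eval_time, km_auc

__all__ = [
    "GeneClustering", "GeneScreenResult", "CandidateList",
    "BaggedSubsetResult", "DerivationResult", "cluster_genes",
    "screen_genes", "select_candidates", "cluster_quotas",
    "enumerate_subsets", "bagged_auc", "select_best_signature",
    "fit_signature_weights", "run_derivation",
]


# ---------------------------------------------------------------------------
# clustering

@dataclass
class GeneClustering:
    labels: pd.Series          # gene -> cluster id (0..k-1)
    exemplars: dict[int, str]  # cluster id -> exemplar gene
    k: int
    preference: float
    damping: float

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    @property
    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()


def _similarity(profiles: np.ndarray) -> np.ndarray:
    """Negative squared Euclidean distance between standardized profiles."""
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (profiles - mu) / sd
    sq = np.sum(z * z, axis=1)
    return -(sq[:, None] + sq[None, :] - 2.0 * z @ z.T)


def _run_ap(S: np.ndarray, preference: float, damping: float,
            max_iter: int, random_state: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ap = AffinityPropagation(affinity="precomputed", damping=damping,
                                 preference=preference, max_iter=max_iter,
                                 convergence_iter=15,
                                 random_state=random_state)
        labels = ap.fit_predict(S)
    if labels.min() < 0 or ap.cluster_centers_indices_ is None:
        return None
    return labels, ap.cluster_centers_indices_


def cluster_genes(
    expr: ExpressionMatrix,
    preference: float | str = "auto",
    damping: float = 0.9,
    target_k: int | None = None,
    max_iter: int = 500,
    random_state: int = 0,
) -> GeneClustering:
    """Affinity-propagation clustering of gene expression profiles.

    ``preference="auto"`` uses the median similarity.  If ``target_k`` is
    given, the preference is adjusted by bisection until the cluster
    count equals ``target_k`` (or the nearest achievable count, which is
    then reported in the result).
    """
    genes = list(expr.endogenous_probes)
    if len(genes) < 1:
        raise ValueError("no endogenous genes to cluster")
    profiles = expr.values.loc[genes].to_numpy(dtype=float)
    if len(genes) == 1:
        return GeneClustering(labels=pd.Series([0], index=genes),
                              exemplars={0: genes[0]}, k=1,
                              preference=0.0, damping=damping)
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    S = _similarity(profiles)
    off = S[~np.eye(len(genes), dtype=bool)]
    pref = float(np.median(off)) if preference == "auto" else float(preference)

    def attempt(p):
        return _run_ap(S, p, damping, max_iter, random_state)

    res = attempt(pref)
    if res is None:
        raise RuntimeError(
            f"affinity propagation failed to converge (preference={pref:.4g}, "
            f"damping={damping}); try higher damping or max_iter")
    if target_k is not None:
        lo, hi = float(off.min()) * 4.0, 0.0  # k grows with preference
        best = (abs(len(set(res[0])) - target_k), pref, res)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            r = attempt(mid)
            if r is None:
                lo = mid
                continue
            k = len(set(r[0]))
            if abs(k - target_k) < best[0]:
                best = (abs(k - target_k), mid, r)
            if k == target_k:
                break
            if k < target_k:
                lo = mid
            else:
                hi = mid
        _, pref, res = best
    labels, centers = res
    labels = pd.Series(labels, index=genes, name="cluster")
    exemplars = {int(labels.iloc[c]): genes[c] for c in centers}
    return GeneClustering(labels=labels, exemplars=exemplars,
                          k=int(labels.nunique()), preference=pref,
                          damping=damping)


# ---------------------------------------------------------------------------
# per-arm gene screening

@dataclass
class GeneScreenResult:
    table: pd.DataFrame  # index gene; coef/p per arm + flags
    covariates_used: list[str]

    def p_treated(self, gene: str) -> float:
        return float(self.table.loc[gene, "p_anthracycline"])

    def p_control(self, gene: str) -> float:
        return float(self.table.loc[gene, "p_cmf"])


def screen_genes(
    expr: ExpressionMatrix,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    covariates: pd.DataFrame,
    genes=None,
    ties: str = "breslow",
) -> GeneScreenResult:
    """Adjusted Cox screen of every gene, separately in each arm.

    Per gene and arm: a Cox model with the gene's log2 expression as a
    continuous term plus the clinical covariates; the gene term's Wald
    p-value is recorded.  Non-converged or non-identifiable fits are
    flagged and their p set to 1.
    """
    if expr.scale != "log2":
        raise ValueError("screen expects log2-scale expression")
    genes = list(genes) if genes is not None else list(expr.endogenous_probes)
    ids = outcome.sample_ids
    treatment = treatment.reindex(ids)
    arms = {"anthracycline": ids[treatment == 1], "cmf": ids[treatment == 0]}
    for name, aids in arms.items():
        if outcome.subset(aids).n_events == 0:
            raise ValueError(f"no events in the {name} arm")
    rows = {}
    for gene in genes:
        row = {}
        flagged = False
        for name, aids in arms.items():
            design = covariates.reindex(aids).astype(float).copy()
            design.insert(0, "gene", expr.values.loc[gene, aids].to_numpy())
            try:
                fit = fit_cox(design, outcome.subset(aids), ties=ties)
                if fit.flagged_terms:
                    raise RuntimeError("non-identifiable")
                row[f"coef_{name}"] = fit.coef("gene")
                row[f"p_{name}"] = fit.p("gene")
            except Exception:
                row[f"coef_{name}"] = np.nan
                row[f"p_{name}"] = 1.0
                flagged = True
        row["flagged"] = flagged
        rows[gene] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return GeneScreenResult(table=table, covariates_used=list(covariates.columns))


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class CandidateList:
    genes: list[str]
    per_cluster_allocation: dict[int, int]

    def __post_init__(self) -> None:
        if min(self.per_cluster_allocation.values()) < 1:
            raise ValueError("every cluster must contribute at least one gene")
        if sum(self.per_cluster_allocation.values()) != len(self.genes):
            raise ValueError("allocation does not sum to the list length")


def cluster_quotas(sizes, total: int) -> list[int]:
    """Cluster-size-weighted quotas, each >= 1, summing to ``total``.

    Largest-remainder apportionment of ``total`` over the cluster sizes
    with a floor of one gene per cluster.
    """
    sizes = [int(s) for s in sizes]
    k = len(sizes)
    if total < k:
        raise ValueError(f"total ({total}) must be >= number of clusters ({k})")
    s = float(sum(sizes))
    ideal = [total * x / s for x in sizes]
    quotas = [max(1, math.floor(v)) for v in ideal]
    rem = [v - math.floor(v) for v in ideal]
    order = sorted(range(k), key=lambda i: (-rem[i], i))
    i = 0
    while sum(quotas) < total:
        quotas[order[i % k]] += 1
        i += 1
    # floors of 1 can overshoot; take back from the largest quotas
    while sum(quotas) > total:
        j = max(range(k), key=lambda i: (quotas[i], rem[i]))
        if quotas[j] <= 1:
            break
        quotas[j] -= 1
    return quotas


def select_candidates(
    clusters: GeneClustering,
    screen: GeneScreenResult,
    total: int = 21,
    alpha_cmf: float = 0.05,
) -> CandidateList:
    """Pick the candidate list with per-cluster quotas.

    Within each cluster, genes qualifying as arm-specific (CMF-arm p >=
    ``alpha_cmf``) are ranked by ascending anthracycline-arm p and taken
    up to the cluster quota; a cluster with no qualifying gene still
    contributes its single smallest-p gene.  If a cluster cannot fill
    its quota, the shortfall is re-allocated to the best remaining
    qualifying genes across the other clusters.
    """
    cluster_ids = sorted(clusters.sizes)
    sizes = [clusters.sizes[c] for c in cluster_ids]
    quotas = dict(zip(cluster_ids, cluster_quotas(sizes, total)))

    chosen: list[str] = []
    allocation: dict[int, int] = {}
    leftovers: list[tuple[float, str, int]] = []
    for c in cluster_ids:
        members = clusters.members(c)
        tab = screen.table.loc[members].sort_values("p_anthracycline")
        qualifying = list(tab.index[tab["p_cmf"] >= alpha_cmf])
        if not qualifying:
            take = [tab.index[0]]  # cluster must be represented
        else:
            take = qualifying[: quotas[c]]
            for g in qualifying[quotas[c]:]:
                leftovers.append((float(tab.loc[g, "p_anthracycline"]), g, c))
        chosen.extend(take)
        allocation[c] = len(take)
    # re-allocate any shortfall to the best remaining qualifying genes
    leftovers.sort()
    for p, g, c in leftovers:
        if len(chosen) >= total:
            break
        chosen.append(g)
        allocation[c] += 1
    return CandidateList(genes=chosen, per_cluster_allocation=allocation)


# ---------------------------------------------------------------------------
# subset enumeration and bagged scoring

def enumerate_subsets(candidates, sizes) -> "itertools.chain":
    """Every size-k combination of the candidate genes, lexicographic in
    candidate order, each exactly once."""
    genes = candidates.genes if isinstance(candidates, CandidateList) else list(candidates)
    sizes = sorted(set(int(s) for s in sizes))
    for k in sizes:
        if not 1 <= k <= len(genes):
            raise ValueError(f"subset size {k} out of range for {len(genes)} genes")
    return itertools.chain.from_iterable(
        itertools.combinations(genes, k) for k in sizes)


@dataclass
class BaggedSubsetResult:
    genes: tuple[str, ...]
    replicate_aucs_treated: list[float]  # NaN = replicate unscored
    replicate_aucs_control: list[float]
    seed: int

    @property
    def median_auc_treated(self) -> float:
        return float(np.nanmedian(self.replicate_aucs_treated))

    @property
    def median_auc_control(self) -> float:
        return float(np.nanmedian(self.replicate_aucs_control))

    @property
    def differential(self) -> float:
        return self.median_auc_treated - self.median_auc_control


def _stratified_split(rng, event: np.ndarray, train_frac: float):
    """Event-stratified random train/test split (indices)."""
    train = []
    test = []
    for val in (1, 0):
        idx = np.flatnonzero(event == val)
        rng.shuffle(idx)
        n_train = int(round(train_frac * idx.size))
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.concatenate(train), np.concatenate(test)


def _build_plan(seed, time, event, B, train_frac, eval_time, mode):
    """Pre-draw the B replicate splits for one arm and precompute the
    test-set time structure of each scorable replicate."""
    from .tdroc import _TimeStruct

    rng = np.random.default_rng(seed)
    n = time.size
    reps = []
    for _ in range(B):
        if mode == "split":
            tr, te = _stratified_split(rng, event, train_frac)
        else:  # true bootstrap: resample n, score out-of-bag
            tr = rng.integers(0, n, size=n)
            te = np.setdiff1d(np.arange(n), tr)
        scorable = (te.size > 0 and event[tr].sum() > 0
                    and ((time[te] <= eval_time) & (event[te] == 1)).sum() > 0)
        struct = _TimeStruct(time[te], event[te], eval_time,
                             dtype=np.float32) if scorable else None
        reps.append((tr, te, struct))
    return reps


# replicate plans are shared across the (many) subsets scored on one arm
_PLAN_CACHE: dict = {}


def _cached_plan(seed, time, event, B, train_frac, eval_time, mode):
    key = (int(seed), int(B), float(train_frac), float(eval_time), mode,
           time.tobytes(), event.tobytes())
    if key not in _PLAN_CACHE:
        if len(_PLAN_CACHE) >= 4:
            _PLAN_CACHE.pop(next(iter(_PLAN_CACHE)))
        _PLAN_CACHE[key] = _build_plan(seed, time, event, B, train_frac,
                                       eval_time, mode)
    return _PLAN_CACHE[key]


def _score_plan(X, time, event, reps, eval_time):
    aucs = []
    beta0 = None
    for tr, te, struct in reps:
        if struct is None:
            aucs.append(np.nan)
            continue
        beta, _conv = breslow_fit(X[tr], time[tr], event[tr], beta0=beta0)
        beta0 = beta  # warm start: replicates share most of their data
        lp = X[te] @ beta
        if np.ptp(lp) == 0:
            aucs.append(0.5)
            continue
        aucs.append(km_auc(lp, time[te], event[te], eval_time, struct))
    return aucs


def bagged_auc(
    subset,
    expr: ExpressionMatrix,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    B: int = 100,
    train_frac: float = 0.6,
    eval_rule: str = "median_followup",
    seed: int = 0,
    mode: str = "split",
) -> BaggedSubsetResult:
    """Bagged time-dependent AUC of a gene subset, per arm.

    For each of ``B`` replicates the arm's samples are split (event-
    stratified) into ``train_frac`` training and the rest test; an
    unadjusted Cox model of the subset genes is fitted on the training
    part and its linear predictor scored on the test part with the
    cumulative/dynamic AUC at the arm's median follow-up.  The same
    procedure runs on both arms; medians of the replicate AUCs are the
    bagged statistics.  ``mode="bootstrap"`` instead resamples n with
    replacement and scores the out-of-bag samples.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0,1)")
    subset = tuple(subset)
    missing = [g for g in subset if g not in expr.values.index]
    if missing:
        raise KeyError(f"subset genes missing from matrix: {missing}")
    ids = outcome.sample_ids
    treatment = treatment.reindex(ids)
    Xall = expr.values.loc[list(subset), ids].to_numpy(dtype=float).T

    ss = np.random.SeedSequence(seed)
    arm_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    out: dict[str, list[float]] = {}
    for (arm_val, arm_name), arm_seed in zip(((1, "treated"), (0, "control")),
                                             arm_seeds):
        sel = (treatment == arm_val).to_numpy()
        time = outcome.time.to_numpy(dtype=float)[sel]
        event = outcome.event.to_numpy()[sel]
        eval_time = choose_eval_time(
            SurvivalOutcome(time=pd.Series(time, index=ids[sel]),
                            event=pd.Series(event, index=ids[sel]),
                            endpoint=outcome.endpoint),
            rule=eval_rule)
        reps = _cached_plan(arm_seed, time, event, B, train_frac, eval_time,
                            mode)
        aucs = _score_plan(Xall[sel], time, event, reps, eval_time)
        if np.isnan(aucs).sum() > 0.5 * B:
            raise RuntimeError(
                f"more than half of the {arm_name}-arm replicates unscorable")
        out[arm_name] = aucs
    return BaggedSubsetResult(genes=subset,
                              replicate_aucs_treated=out["treated"],
                              replicate_aucs_control=out["control"],
                              seed=seed)


def _batched_breslow(Xs, time, event, max_iter=30, tol=1e-8):
    """Newton-Raphson for many small Cox models at once.

    ``Xs`` is (m, n, p): m subsets, same n subjects, p genes.  Returns
    (m, p) coefficients.  Same Breslow tie handling as
    :func:`cinsig._coxfast.breslow_fit`; non-converged or exploding
    models get zero coefficients (constant predictor downstream).
    """
    m, n, p = Xs.shape
    order = np.argsort(-time, kind="stable")
    Xs = Xs[:, order, :]
    t = time[order]
    d = event[order].astype(bool)
    last = np.searchsorted(-t, -t, side="right") - 1
    lastev = last[d]
    q = 1 + p + p * p
    A = np.empty((m, n, q))
    A[:, :, 0] = 1.0
    A[:, :, 1:1 + p] = Xs
    A[:, :, 1 + p:] = (Xs[:, :, :, None] * Xs[:, :, None, :]).reshape(m, n, p * p)
    Xev = Xs[:, d, :]
    beta = np.zeros((m, p))
    eye = np.eye(p)

    def loglik(b):
        eta = np.einsum("mnp,mp->mn", Xs, b)
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        S0 = np.cumsum(w, axis=1)[:, lastev]
        return np.sum(eta[:, d] - np.log(S0), axis=1), eta, w

    ll, eta, w = loglik(beta)
    for _ in range(max_iter):
        C = np.cumsum(A * w[:, :, None], axis=1)[:, lastev, :]
        S0 = C[:, :, 0]
        S1 = C[:, :, 1:1 + p]
        S2 = C[:, :, 1 + p:].reshape(m, -1, p, p)
        mean = S1 / S0[:, :, None]
        grad = (Xev - mean).sum(axis=1)
        hess = (S2 / S0[:, :, None, None]).sum(axis=1) \
            - np.einsum("mkp,mkq->mpq", mean, mean)
        try:
            step = np.linalg.solve(hess + 1e-10 * eye, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        new = beta + step
        ll_new, eta_n, w_n = loglik(new)
        for _half in range(15):
            worse = ll_new < ll - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
            new = beta + step
            ll_new, eta_n, w_n = loglik(new)
        done = (np.abs(grad).max(axis=1) < tol) | (np.abs(ll_new - ll) < tol)
        beta, ll, eta, w = new, ll_new, eta_n, w_n
        if done.all():
            break
    bad = ~np.isfinite(beta).all(axis=1) | (np.abs(beta).max(axis=1) > 50)
    beta[bad] = 0.0
    return beta


def _batched_km_auc(lp, struct):
    """Cumulative/dynamic KM AUC for many markers over one test set.

    ``lp`` is (m, n); markers with tied values fall back to the scalar
    path (ties collapse cutpoints), the common all-distinct case is fully
    vectorized.
    """
    m, n = lp.shape
    orders = np.argsort(-lp, axis=1)
    C = np.cumsum(struct.both[orders], axis=1)
    k = struct.k
    R = C[:, :, :k]
    D = C[:, :, k:]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(R > 0, 1.0 - D / np.where(R > 0, R, 1.0), 1.0)
    S_prefix = np.prod(frac, axis=2)
    S_all = S_prefix[:, -1]
    P = (np.arange(1, n + 1) / n)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tpr = (1.0 - S_prefix) * P / (1.0 - S_all[:, None])
        fpr = S_prefix * P / S_all[:, None]
    tpr = np.clip(np.maximum.accumulate(tpr, axis=1), 0.0, 1.0)
    fpr = np.clip(np.maximum.accumulate(fpr, axis=1), 0.0, 1.0)
    zeros = np.zeros((m, 1))
    ones = np.ones((m, 1))
    fpr = np.concatenate([zeros, fpr, ones], axis=1)
    tpr = np.concatenate([zeros, tpr, ones], axis=1)
    auc = np.trapezoid(tpr, fpr, axis=1)

    # exact handling for degenerate / tied markers
    lp_sorted = np.take_along_axis(lp, orders, axis=1)
    has_ties = (np.diff(lp_sorted, axis=1) == 0).any(axis=1)
    for i in np.flatnonzero(has_ties):
        if np.ptp(lp[i]) == 0:
            auc[i] = 0.5
        else:
            time = struct.time
            event = struct.event
            auc[i] = km_auc(lp[i], time, event, struct.t_star, struct)
    return auc


def bag_subsets(
    subsets,
    expr: ExpressionMatrix,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    B: int = 100,
    train_frac: float = 0.6,
    eval_rule: str = "median_followup",
    seed: int = 0,
) -> list[BaggedSubsetResult]:
    """Bagged AUCs for many gene subsets on shared replicate splits.

    Vectorized equivalent of calling :func:`bagged_auc` with the same
    ``seed`` for every subset (common random numbers): all subsets are
    scored on identical train/test splits, so their comparison is
    paired.  Returns one :class:`BaggedSubsetResult` per subset, in
    input order.
    """
    subsets = [tuple(s) for s in subsets]
    if not subsets:
        return []
    ids = outcome.sample_ids
    treatment = pd.Series(treatment).reindex(ids)
    genes = sorted({g for s in subsets for g in s})
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"subset genes missing from matrix: {missing}")
    gidx = {g: i for i, g in enumerate(genes)}
    Xall = expr.values.loc[genes, ids].to_numpy(dtype=float).T

    ss = np.random.SeedSequence(seed)
    arm_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
    by_size: dict[int, list[int]] = {}
    for i, s in enumerate(subsets):
        by_size.setdefault(len(s), []).append(i)

    aucs = {name: np.full((len(subsets), B), np.nan)
            for name in ("treated", "control")}
    for (arm_val, arm_name), arm_seed in zip(((1, "treated"), (0, "control")),
                                             arm_seeds):
        sel = (treatment == arm_val).to_numpy()
        time = outcome.time.to_numpy(dtype=float)[sel]
        event = outcome.event.to_numpy()[sel]
        eval_time = choose_eval_time(
            SurvivalOutcome(time=pd.Series(time, index=ids[sel]),
                            event=pd.Series(event, index=ids[sel]),
                            endpoint=outcome.endpoint),
            rule=eval_rule)
        reps = _cached_plan(arm_seed, time, event, B, train_frac, eval_time,
                            "split")
        Xarm = Xall[sel]
        for p_size, members in by_size.items():
            cols = np.array([[gidx[g] for g in subsets[i]] for i in members])
            Xs = Xarm[:, cols].transpose(1, 0, 2)  # (m, n, p)
            for b, (tr, te, struct) in enumerate(reps):
                if struct is None:
                    continue
                beta = _batched_breslow(Xs[:, tr, :], time[tr], event[tr])
                lp = np.einsum("mnp,mp->mn", Xs[:, te, :], beta)
                aucs[arm_name][members, b] = _batched_km_auc(lp, struct)
    results = []
    for i, s in enumerate(subsets):
        for arm_name in ("treated", "control"):
            if np.isnan(aucs[arm_name][i]).sum() > 0.5 * B:
                raise RuntimeError(
                    f"more than half of the {arm_name}-arm replicates "
                    f"unscorable for subset {s}")
        results.append(BaggedSubsetResult(
            genes=s,
            replicate_aucs_treated=list(aucs["treated"][i]),
            replicate_aucs_control=list(aucs["control"][i]),
            seed=seed))
    return results


def select_best_signature(
    results: list[BaggedSubsetResult],
) -> tuple[BaggedSubsetResult, pd.DataFrame]:
    """Rank subsets by treated-minus-control median AUC; return the winner.

    Ties break by higher treated-arm median, then smaller subset, then
    lexicographic gene order.  The full ranking table is returned too.
    """
    if not results:
        raise ValueError("no subset results to rank")
    rows = []
    for r in results:
        if np.isnan(r.replicate_aucs_treated).all() and \
           np.isnan(r.replicate_aucs_control).all():
            continue
        rows.append({
            "genes": "+".join(r.genes),
            "size": len(r.genes),
            "median_auc_treated": r.median_auc_treated,
            "median_auc_control": r.median_auc_control,
            "differential": r.differential,
        })
    if not rows:
        raise ValueError("all bagged medians are missing")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["differential", "median_auc_treated", "size", "genes"],
        ascending=[False, False, True, True], kind="stable",
    ).reset_index(drop=True)
    table.index.name = "rank"
    best_key = table.iloc[0]["genes"]
    best = next(r for r in results if "+".join(r.genes) == best_key)
    return best, table


def fit_signature_weights(
    subset,
    expr: ExpressionMatrix,
    outcome: SurvivalOutcome,
    covariates: pd.DataFrame,
    name: str = "derived",
    ties: str = "breslow",
) -> SignatureDefinition:
    """Joint Cox fit of the winning genes on the merged cohort.

    The genes enter as simultaneous continuous log2-expression terms
    alongside the clinical covariates; their fitted coefficients become
    the signature weights.
    """
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ValueError("signature genes must be unique")
    ids = outcome.sample_ids
    design = pd.DataFrame(
        expr.values.loc[subset, ids].to_numpy(dtype=float).T,
        index=ids, columns=subset)
    for c in covariates.columns:
        design[c] = covariates[c].reindex(ids).astype(float)
    fit = fit_cox(design, outcome, ties=ties)
    if fit.flagged_terms:
        cond = np.linalg.cond(design.to_numpy(dtype=float))
        raise RuntimeError(
            f"signature model did not converge (flagged terms "
            f"{fit.flagged_terms}; design condition number {cond:.3g})")
    weights = [fit.coef(g) for g in subset]
    return SignatureDefinition(name=name, genes=subset, weights=weights)


# ---------------------------------------------------------------------------
# whole-pipeline convenience

@dataclass
class DerivationResult:
    clustering: GeneClustering
    screen: GeneScreenResult
    candidates: CandidateList
    ranking: pd.DataFrame
    best: BaggedSubsetResult
    signature: SignatureDefinition
    params: dict


def run_derivation(
    expr: ExpressionMatrix,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    covariates: pd.DataFrame,
    sizes=(2, 3, 4, 5),
    n_candidates: int = 21,
    B: int = 100,
    train_frac: float = 0.6,
    alpha_cmf: float = 0.05,
    eval_rule: str = "median_followup",
    target_k: int | None = None,
    damping: float = 0.9,
    seed: int = 0,
) -> DerivationResult:
    """Cluster -> screen -> select -> enumerate -> bag -> rank -> weight."""
    clustering = cluster_genes(expr, damping=damping, target_k=target_k)
    screen = screen_genes(expr, treatment, outcome, covariates)
    n_candidates = min(n_candidates, len(screen.table))
    if n_candidates < clustering.k:
        n_candidates = clustering.k
    candidates = select_candidates(clustering, screen, total=n_candidates,
                                   alpha_cmf=alpha_cmf)
    subsets = list(enumerate_subsets(candidates,
                                     [s for s in sizes
                                      if s <= len(candidates.genes)]))
    # every subset is scored on the same B splits (common random numbers),
    # so subset comparisons are paired and split noise cancels
    split_seed = int(np.random.SeedSequence(seed).generate_state(1)[0]
                     % (2 ** 31))
    results = bag_subsets(subsets, expr, treatment, outcome, B=B,
                          train_frac=train_frac, eval_rule=eval_rule,
                          seed=split_seed)
    best, ranking = select_best_signature(results)
    signature = fit_signature_weights(best.genes, expr, outcome, covariates,
                                      name="derived_signature")
    params = {
        "sizes": list(sizes), "n_candidates": n_candidates, "B": B,
        "train_frac": train_frac, "alpha_cmf": alpha_cmf,
        "eval_rule": eval_rule, "target_k": target_k, "damping": damping,
        "seed": seed, "n_subsets": len(subsets),
    }
    return DerivationResult(clustering=clustering, screen=screen,
                            candidates=candidates, ranking=ranking,
                            best=best, signature=signature, params=params)
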