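"""Cox proportional-hazards and Kaplan-Meier machinery.

Wraps the general-purpose fitters (statsmodels ``PHReg`` for Cox with
Breslow/Efron tie handling, lifelines for product-limit curves) behind
the result containers used throughout the package, and builds the
treatment-by-marker interaction analyses: a full Cox model containing
marker, treatment, covariates and the marker x treatment product, plus
unadjusted within-stratum treatment contrasts for Table-style reporting.
Within-stratum p-values are deliberately not produced by default (to
avoid multiple testing over subgroups); inference rests on the
interaction term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SurvivalOutcome:
    """Per-sample (time, event) pairs for a named endpoint."""

    time: pd.Series
    event: pd.Series
    endpoint: str = "DRFS"

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.event.index):
            raise ValueError("time and event must share the same sample index")
        if (self.time <= 0).any():
            raise ValueError("event/censoring times must be strictly positive")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.time.index

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, ids) -> "SurvivalOutcome":
        ids = pd.Index(ids)
        return replace(self, time=self.time.loc[ids], event=self.event.loc[ids])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event})
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, endpoint: str = "DRFS",
                   time_col: str = "time", event_col: str = "event") -> "SurvivalOutcome":
        return cls(time=df[time_col].astype(float), event=df[event_col].astype(int),
                   endpoint=endpoint)


@dataclass
class CoxFit:
    """A fitted Cox model: per-term coefficients, HRs, Wald CIs and p-values."""

    summary: pd.DataFrame  # index: term; columns: coef, se, hr, ci_low, ci_high, p
    loglik: float
    n: int
    n_events: int
    ties: str
    n_dropped: int = 0
    converged: bool = True
    flagged_terms: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    @property
    def terms(self) -> list[str]:
        return list(self.summary.index)


def fit_cox(design: pd.DataFrame, outcome: SurvivalOutcome,
            ties: str = "breslow") -> CoxFit:
    """Maximize the Cox partial likelihood for the given design matrix.

    Rows with missing covariate values are dropped (count reported on the
    result).  Monotone-likelihood terms (perfect separation) are flagged:
    their Wald statistics are unreliable and the fit is marked
    non-converged.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    design = design.reindex(outcome.sample_ids)
    keep = design.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    design = design.loc[keep]
    out = outcome.subset(design.index)
    if out.n_events == 0:
        raise ValueError("no events in the analysis set")

    # constant columns carry no information under proportional hazards:
    # coefficient 0 by convention, Wald statistics undefined
    variable = [c for c in design.columns if design[c].nunique() > 1]
    coef = np.zeros(design.shape[1])
    se = np.full(design.shape[1], np.nan)
    p = np.full(design.shape[1], np.nan)
    X = design[variable].to_numpy(dtype=float) if variable else \
        np.zeros((len(design), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PHReg(out.time.to_numpy(), X, status=out.event.to_numpy(),
                      ties=ties)
        if variable:
            res = model.fit(disp=False)
            pos = [design.columns.get_loc(c) for c in variable]
            coef[pos] = np.asarray(res.params, dtype=float)
            se[pos] = np.asarray(res.bse, dtype=float)
            p[pos] = np.asarray(res.pvalues, dtype=float)
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - Z95 * se),
            "ci_high": np.exp(coef + Z95 * se),
            "p": p,
        },
        index=pd.Index(design.columns, name="term"),
    )
    flagged = [t for t, c, s in zip(design.columns, coef, se)
               if t in variable and ((not np.isfinite(c)) or abs(c) > 50
                                     or (not np.isfinite(s)) or s > 100)]
    loglik = model.loglike(coef[[design.columns.get_loc(c)
                                 for c in variable]]) if variable \
        else model.loglike(np.zeros(1))
    return CoxFit(
        summary=summary,
        loglik=float(loglik),
        n=out.n,
        n_events=out.n_events,
        ties=ties,
        n_dropped=n_dropped,
        converged=not flagged,
        flagged_terms=flagged,
    )


def cox_score_test(design: pd.DataFrame, outcome: SurvivalOutcome,
                   ties: str = "breslow") -> float:
    """Score (Rao) chi-square at beta=0; equals the log-rank statistic for
    a single binary covariate without ties."""
    design = design.reindex(outcome.sample_ids)
    model = PHReg(outcome.time.to_numpy(), design.to_numpy(dtype=float),
                  status=outcome.event.to_numpy(), ties=ties)
    beta0 = np.zeros(design.shape[1])
    u = model.score(beta0)
    info = -model.hessian(beta0)
    return float(u @ np.linalg.solve(info, u))


def km_curve(outcome: SurvivalOutcome,
             groups: pd.Series | None = None) -> dict[str, pd.DataFrame]:
    """Product-limit estimate per group.

    Returns, per group label, a step-function frame with columns
    ``time``, ``survival``, ``at_risk``, ``events`` (time 0 row included,
    S(0)=1).  Empty groups are omitted with a warning.
    """
    if groups is None:
        groups = pd.Series("all", index=outcome.sample_ids)
    groups = groups.reindex(outcome.sample_ids)
    curves: dict[str, pd.DataFrame] = {}
    for label in pd.unique(groups.dropna()):
        ids = groups.index[groups == label]
        if len(ids) == 0:
            warnings.warn(f"group {label!r} is empty; omitted")
            continue
        sub = outcome.subset(ids)
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, sub.event)
        tbl = kmf.event_table
        df = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
                "events": tbl["observed"].to_numpy(),
            }
        )
        curves[str(label)] = df.reset_index(drop=True)
    return curves


@dataclass
class InteractionResult:
    """A treatment-by-marker analysis.

    ``base`` is the full adjusted Cox fit (marker, covariates, treatment,
    marker x treatment).  The interaction fields are copies of the
    corresponding entries of ``base``.  ``per_stratum_hr`` holds the
    unadjusted within-stratum treatment hazard ratios (Low / High), each
    a (hr, ci_low, ci_high) tuple or None when undefined (zero events).
    """

    marker_name: str
    base: CoxFit
    interaction_term: str
    interaction_hr: float
    interaction_ci: tuple[float, float]
    interaction_p: float
    per_stratum_hr: dict[str, tuple[float, float, float] | None]
    label: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        # consistency: interaction fields mirror the base fit
        assert np.isclose(self.interaction_hr, self.base.hr(self.interaction_term))


def _marker_series(marker) -> tuple[pd.Series, pd.Series | None, str]:
    """Accept a SignatureScore (binary if dichotomized) or numeric Series."""
    from .signatures import SignatureScore

    if isinstance(marker, SignatureScore):
        if marker.group is not None:
            values = (marker.group == "High").astype(float)
            return values.rename(marker.name), marker.group, marker.name
        return marker.scores.astype(float), None, marker.name
    s = pd.Series(marker).astype(float)
    return s, None, (s.name or "marker")


def treatment_by_marker(
    marker,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    covariates: pd.DataFrame | None = None,
    ties: str = "breslow",
    label: str = "",
) -> InteractionResult:
    """Fit the full interaction model plus Table-style stratum contrasts.

    ``marker`` may be a dichotomized :class:`SignatureScore` (binary
    High=1 term) or a continuous score.  ``treatment`` must be binary 0/1
    (1 = anthracycline-containing arm).  The per-stratum treatment HRs
    are computed from unadjusted treatment-only fits within the Low and
    High marker groups (for a continuous marker, strata come from a
    median split); no p-values are attached to them.
    """
    values, group, name = _marker_series(marker)
    treatment = pd.Series(treatment).astype(float)
    if not set(treatment.dropna().unique()) <= {0.0, 1.0}:
        raise ValueError("treatment must be binary 0/1")
    ids = outcome.sample_ids
    values = values.reindex(ids)
    treatment = treatment.reindex(ids)

    inter_name = f"{name}:treatment"
    design = pd.DataFrame({name: values})
    if covariates is not None:
        for c in covariates.columns:
            design[c] = covariates[c].reindex(ids).astype(float)
    design["treatment"] = treatment
    design[inter_name] = values * treatment
    base = fit_cox(design, outcome, ties=ties)

    if group is None:
        med = values.median()
        group = pd.Series(np.where(values > med, "High", "Low"), index=ids)
    group = group.reindex(ids)

    strata: dict[str, tuple[float, float, float] | None] = {}
    for lab in ("Low", "High"):
        sids = ids[group == lab]
        sub = outcome.subset(sids) if len(sids) else None
        if sub is None or sub.n_events == 0 or treatment.loc[sids].nunique() < 2:
            strata[lab] = None
            continue
        fit = fit_cox(pd.DataFrame({"treatment": treatment.loc[sids]}), sub,
                      ties=ties)
        if fit.flagged_terms:
            strata[lab] = None
        else:
            lo, hi = fit.ci("treatment")
            strata[lab] = (fit.hr("treatment"), lo, hi)

    return InteractionResult(
        marker_name=name,
        base=base,
        interaction_term=inter_name,
        interaction_hr=base.hr(inter_name),
        interaction_ci=base.ci(inter_name),
        interaction_p=base.p(inter_name),
        per_stratum_hr=strata,
        label=label or name,
        endpoint=outcome.endpoint,
    )


def subgroup_by_grade(
    marker,
    treatment: pd.Series,
    outcome: SurvivalOutcome,
    clinical: pd.DataFrame,
    grade_levels,
    covariates: pd.DataFrame | None = None,
    ties: str = "breslow",
) -> InteractionResult:
    """Interaction analysis restricted to tumours of the given grades."""
    grade_levels = set(grade_levels)
    if not grade_levels:
        raise ValueError("grade_levels must be non-empty")
    if "grade" not in clinical.columns:
        raise ValueError("clinical table has no 'grade' column")
    keep = clinical.index[clinical["grade"].isin(grade_levels)]
    keep = keep.intersection(outcome.sample_ids)
    if len(keep) == 0:
        raise ValueError(f"no samples with grade in {sorted(grade_levels)}")

    values, group, name = _marker_series(marker)
    if group is not None:
        from .signatures import SignatureScore
        marker = SignatureScore(name=name, scores=values.loc[keep],
                                group=group.loc[keep])
    else:
        marker = values.loc[keep]
    if grade_levels == {3}:
        label = f"{name} in grade III"
    elif grade_levels == {1, 2}:
        label = f"{name} in grade I & II"
    else:
        label = f"{name} in grade {sorted(grade_levels)}"
    cov = covariates.loc[covariates.index.intersection(keep)] if covariates is not None else None
    return treatment_by_marker(marker, treatment.loc[keep], outcome.subset(keep),
                               covariates=cov, ties=ties, label=label)
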