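"""Synthetic two-trial randomized cohorts with a planted predictive signature.

Emulates the merged design of two adjuvant chemotherapy trials: two
cohorts randomized 1:1 to an anthracycline-containing arm versus CMF
alone, a digital-counting expression panel (endogenous targets,
housekeeping genes, spike-in positive controls on a geometric ladder,
negative-control background), correlated clinical covariates, and
proportional-hazards survival with a treatment main effect and a
treatment x signature-score interaction of configurable size.

The planted signature works through a per-sample latent factor: the
designated signature genes load on it on the log-expression scale, and
the realized latent score (the standardized mean of those genes'
log-expression) enters the hazard multiplied by treatment, so the
signature is predictive (treatment-modifying) rather than prognostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .known import CANDIDATE_GENES, CIN4_GENES
from .matrix import (ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE,
                     ExpressionMatrix)
from .survival import SurvivalOutcome

#: Default log-hazards for the clinical covariates (per unit of coding).
DEFAULT_BETA_CLINICAL: dict[str, float] = {
    "grade": 0.50,   # ordinal 1-3
    "nodes": 0.80,   # node-positive vs negative
    "size": 0.55,    # >2 cm vs <=2 cm
    "her2": 0.28,
    "pgr": 0.14,
}

#: Baseline exponential DRFS hazard (per year), calibrated so the default
#: cohort realizes ~60% censoring under the default effect sizes.
DEFAULT_BASELINE_DRFS = 0.047
#: OS baseline: deaths accrue more slowly than distant relapses.
DEFAULT_BASELINE_OS = 0.038


def default_gene_names(n_genes: int) -> list[str]:
    """Panel gene names: the public 21-gene candidate list first, then
    generic identifiers up to ``n_genes``."""
    names = list(CANDIDATE_GENES[:n_genes])
    names += [f"G{i:03d}" for i in range(len(names) + 1, n_genes + 1)]
    return names


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study conditions."""

    n_trial1: int = 282
    n_trial2: int = 421
    n_genes: int = 70
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_housekeeping: int = 6
    signature_genes: tuple[str, ...] = CIN4_GENES
    beta_clinical: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_CLINICAL))
    gamma_treatment: float = math.log(0.60)
    delta_interaction: float = math.log(0.35)
    baseline_hazard: float | tuple[float, float] = DEFAULT_BASELINE_DRFS
    baseline_hazard_os: float | tuple[float, float] = DEFAULT_BASELINE_OS
    admin_censor_time: float | None = 10.0
    censor_rate: float = 0.02
    count_dispersion: float = 0.1
    signature_loading: float = 0.25
    signature_unique_sd: float = 1.0
    biological_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trial1", "n_trial2", "n_genes", "n_pos_controls",
                     "n_neg_controls", "n_housekeeping"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= len(self.signature_genes) <= self.n_genes:
            raise ValueError("need 1 <= |signature_genes| <= n_genes")
        genes = set(default_gene_names(self.n_genes))
        unknown = set(self.signature_genes) - genes
        if unknown:
            raise ValueError(f"signature genes not on the panel: {sorted(unknown)}")
        for hz in (self.baseline_hazard, self.baseline_hazard_os):
            params = hz if isinstance(hz, tuple) else (hz,)
            if any(v <= 0 for v in params):
                raise ValueError("baseline hazard parameters must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signature_genes"] = list(self.signature_genes)
        return d


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    survival_drfs: SurvivalOutcome
    survival_os: SurvivalOutcome
    truth: dict

    @property
    def sample_ids(self) -> pd.Index:
        return self.clinical.index

    @property
    def treatment(self) -> pd.Series:
        return self.clinical["arm"]

    @property
    def latent_score(self) -> pd.Series:
        return pd.Series(self.truth["latent_score"], index=self.sample_ids,
                         name="latent_score")


def _draw_survival_times(rng, lp: np.ndarray, baseline) -> np.ndarray:
    e = rng.exponential(1.0, size=lp.size)
    if isinstance(baseline, tuple):
        shape, scale = baseline
        t = scale * (e / np.exp(lp)) ** (1.0 / shape)
    else:
        t = e / (baseline * np.exp(lp))
    return np.maximum(t, 1e-9)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate expression, clinical and survival tables under ``spec``."""
    ss = np.random.SeedSequence(spec.seed)
    (s_clin, s_latent, s_expr, s_drfs, s_os, s_cens) = ss.spawn(6)
    rng_clin = np.random.default_rng(s_clin)
    rng_lat = np.random.default_rng(s_latent)
    rng_expr = np.random.default_rng(s_expr)

    n = spec.n_trial1 + spec.n_trial2
    sample_ids = pd.Index([f"S{i:04d}" for i in range(1, n + 1)],
                          name="sample_id")
    trial = np.array(["BR9601"] * spec.n_trial1 + ["MA.5"] * spec.n_trial2)

    # 1:1 randomization within each trial
    arm = np.zeros(n, dtype=int)
    off = 0
    for n_t in (spec.n_trial1, spec.n_trial2):
        a = np.zeros(n_t, dtype=int)
        a[: n_t // 2] = 1
        rng_clin.shuffle(a)
        arm[off:off + n_t] = a
        off += n_t

    # clinical covariates: grade enriched for III; ER/PgR correlated via a
    # shared latent normal (tetrachoric-style)
    age = np.clip(rng_clin.normal(52.0, 9.0, size=n), 25, 78).round(1)
    grade = rng_clin.choice([1, 2, 3], size=n, p=[0.1, 0.4, 0.5])
    z_hr = rng_clin.multivariate_normal([0.0, 0.0],
                                        [[1.0, 0.7], [0.7, 1.0]], size=n)
    from scipy.stats import norm
    er = (z_hr[:, 0] < norm.ppf(0.60)).astype(int)
    pgr = (z_hr[:, 1] < norm.ppf(0.55)).astype(int)
    her2 = rng_clin.binomial(1, 0.25, size=n)
    size = rng_clin.binomial(1, 0.50, size=n)
    nodes = rng_clin.binomial(1, 0.65, size=n)
    clinical = pd.DataFrame(
        {"trial": trial, "arm": arm, "age": age, "grade": grade, "size": size,
         "nodes": nodes, "er": er, "pgr": pgr, "her2": her2},
        index=sample_ids,
    )

    # expression model
    gene_names = default_gene_names(spec.n_genes)
    sig_idx = [gene_names.index(g) for g in spec.signature_genes]
    mu_gene = np.log(200.0) + rng_expr.normal(0.0, 0.7, size=spec.n_genes)
    # the signature genes share a latent co-regulation factor and carry
    # gene-specific components, so each contributes complementary signal
    z = rng_lat.normal(0.0, 1.0, size=n)  # latent instability factor
    uniq = rng_lat.normal(0.0, 1.0, size=(len(sig_idx), n))
    bio = rng_expr.normal(0.0, spec.biological_sd, size=(spec.n_genes, n))
    log_expr = mu_gene[:, None] + bio
    log_expr[sig_idx, :] += (spec.signature_loading * z[None, :]
                             + spec.signature_unique_sd * uniq)

    raw_score = log_expr[sig_idx, :].mean(axis=0)
    score = (raw_score - raw_score.mean()) / raw_score.std(ddof=0)

    lane = np.exp(rng_expr.normal(0.0, 0.2, size=n))

    def nb_draw(rng, mean, dispersion):
        if dispersion <= 0:
            return rng.poisson(mean)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        return rng.poisson(lam)

    endo_mean = np.exp(log_expr) * lane[None, :]
    endo = nb_draw(rng_expr, endo_mean, spec.count_dispersion)
    endo = endo + rng_expr.poisson(2.0, size=endo.shape)

    mu_hk = np.exp(np.log(600.0) + rng_expr.normal(0.0, 0.3,
                                                   size=spec.n_housekeeping))
    hk_mean = (mu_hk[:, None]
               * np.exp(rng_expr.normal(0.0, 0.05, size=(spec.n_housekeeping, n)))
               * lane[None, :])
    hk = nb_draw(rng_expr, hk_mean, spec.count_dispersion)
    hk = hk + rng_expr.poisson(2.0, size=hk.shape)

    # geometric 4-fold spike-in ladder, ~250 counts per fM
    ladder_fm = 128.0 / 4.0 ** np.arange(spec.n_pos_controls)
    pos_mean = 250.0 * ladder_fm[:, None] * lane[None, :]
    pos = np.maximum(nb_draw(rng_expr, pos_mean, 0.01), 1)
    neg = rng_expr.poisson(2.0, size=(spec.n_neg_controls, n))

    probe_ids = (gene_names
                 + [f"HK{i:02d}" for i in range(1, spec.n_housekeeping + 1)]
                 + [f"POS_{chr(65 + i)}" for i in range(spec.n_pos_controls)]
                 + [f"NEG_{chr(65 + i)}" for i in range(spec.n_neg_controls)])
    probe_class = pd.Series(
        [ENDOGENOUS] * spec.n_genes + [HOUSEKEEPING] * spec.n_housekeeping
        + [POSITIVE] * spec.n_pos_controls + [NEGATIVE] * spec.n_neg_controls,
        index=probe_ids, name="probe_class")
    values = pd.DataFrame(np.vstack([endo, hk, pos, neg]).astype(float),
                          index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    expression = ExpressionMatrix(values=values, probe_class=probe_class,
                                  scale="raw")

    # proportional-hazards survival with planted interaction
    lp = np.zeros(n)
    for cov, beta in spec.beta_clinical.items():
        lp += beta * clinical[cov].to_numpy(dtype=float)
    lp += spec.gamma_treatment * arm
    lp += spec.delta_interaction * arm * score
    lp -= lp.mean()  # baseline hazard refers to the average subject

    rng_cens = np.random.default_rng(s_cens)

    def make_outcome(seed_child, baseline, endpoint):
        rng_t = np.random.default_rng(seed_child)
        t_event = _draw_survival_times(rng_t, lp, baseline)
        c = np.full(n, np.inf)
        if spec.censor_rate > 0:
            c = rng_cens.exponential(1.0 / spec.censor_rate, size=n)
        if spec.admin_censor_time is not None:
            c = np.minimum(c, spec.admin_censor_time)
        event = (t_event <= c).astype(int)
        t_obs = np.minimum(t_event, c)
        t_obs = np.maximum(t_obs, 1e-9)
        return SurvivalOutcome(time=pd.Series(t_obs, index=sample_ids, name="time"),
                               event=pd.Series(event, index=sample_ids, name="event"),
                               endpoint=endpoint)

    survival_drfs = make_outcome(s_drfs, spec.baseline_hazard, "DRFS")
    survival_os = make_outcome(s_os, spec.baseline_hazard_os, "OS")

    truth = {
        "spec": spec.to_dict(),
        "latent_score": [round(float(v), 10) for v in score],
        "realized_censoring": {
            "DRFS": round(1.0 - survival_drfs.event.mean(), 6),
            "OS": round(1.0 - survival_os.event.mean(), 6),
        },
    }
    return SyntheticCohort(expression=expression, clinical=clinical,
                           survival_drfs=survival_drfs, survival_os=survival_os,
                           truth=truth)


def realized_censoring_fraction(cohort: SyntheticCohort, endpoint: str) -> float:
    """Fraction of samples censored (event indicator 0) for an endpoint."""
    if endpoint == "DRFS":
        out = cohort.survival_drfs
    elif endpoint == "OS":
        out = cohort.survival_os
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return float(1.0 - out.event.mean())


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write expression/clinical/survival tables plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.csv",
        "survival_drfs": outdir / "survival_drfs.csv",
        "survival_os": outdir / "survival_os.csv",
        "truth": outdir / "truth.json",
    }
    cohort.expression.to_tsv(paths["expression"])
    cohort.clinical.to_csv(paths["clinical"], float_format="%.10g")
    cohort.survival_drfs.to_frame().to_csv(paths["survival_drfs"],
                                           float_format="%.10g")
    cohort.survival_os.to_frame().to_csv(paths["survival_os"],
                                         float_format="%.10g")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def read_survival(path, endpoint: str = "DRFS") -> SurvivalOutcome:
    df = pd.read_csv(path, index_col="sample_id")
    return SurvivalOutcome.from_frame(df, endpoint=endpoint)
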