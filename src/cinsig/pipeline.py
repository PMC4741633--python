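"""Pipeline orchestration, configuration and table-style reporting.

A :class:`PipelineConfig` (loadable from YAML) drives the stages
simulate (optional) -> normalize -> score -> derive -> evaluate, writing
versioned delimited outputs plus a provenance JSON into a run
directory.  A run is fully reproducible: config + master seed determine
every output byte.

Reports mirror the two table layouts used for treatment-by-marker
results: a per-marker table (within-stratum treatment HRs and the
interaction test) and a per-term multivariate table.  Within-stratum
treatment contrasts carry no p-values in default reports, to avoid
multiple testing over subgroups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import known
from .cohort import (CohortSpec, SyntheticCohort, generate_cohort,
                     read_clinical, read_survival, write_cohort)
from .derivation import DerivationResult, run_derivation
from .matrix import ExpressionMatrix
from .nanostring import normalize_counts
from .signatures import (SignatureDefinition, SignatureScore,
                         dichotomize_at_median, score_signature)
from .survival import InteractionResult, subgroup_by_grade, treatment_by_marker

log = logging.getLogger("cinsig")

DEFAULT_COVARIATES = ["grade", "size", "nodes", "her2", "pgr"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable, reproducible with the seed."""

    # inputs: either a simulate block or paths to existing tables
    simulate: dict | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    survival_drfs_path: str | None = None
    survival_os_path: str | None = None
    # analysis options
    endpoint: str = "DRFS"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    ties: str = "breslow"
    # normalization
    k_sd: float = 2.0
    pseudocount: float = 1.0
    norm_method: str = "geomean"
    # signature files (name -> path); scored and dichotomized if present
    signatures: dict[str, str] = field(default_factory=dict)
    # derivation parameters
    derive: bool = True
    sizes: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_candidates: int = 21
    B: int = 100
    train_frac: float = 0.6
    alpha_cmf: float = 0.05
    eval_rule: str = "median_followup"
    target_k: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.endpoint not in ("DRFS", "OS"):
            raise ValueError("endpoint must be DRFS or OS")
        if self.simulate is None:
            for attr in ("expression_path", "clinical_path",
                         "survival_drfs_path"):
                p = getattr(self, attr)
                if p is None:
                    raise ValueError(f"config needs simulate: or {attr}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{attr}: {p} does not exist")
        for name, p in self.signatures.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"signature {name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def render_table1_style(results: list[InteractionResult]) -> pd.DataFrame:
    """Per-marker report: within-stratum treatment HRs plus interaction.

    One row per marker (including grade-restricted analyses); columns
    are the Low-stratum HR and CI, High-stratum HR and CI, interaction
    HR and interaction p.  Undefined strata render as empty cells.
    """
    rows = []
    for r in results:
        row = {"marker": r.label or r.marker_name, "endpoint": r.endpoint}
        for stratum in ("Low", "High"):
            v = r.per_stratum_hr.get(stratum)
            pre = stratum.lower()
            if v is None:
                row[f"{pre}_hr"] = ""
                row[f"{pre}_ci"] = ""
            else:
                hr, lo, hi = v
                row[f"{pre}_hr"] = f"{hr:.2f}"
                row[f"{pre}_ci"] = f"{lo:.2f}-{hi:.2f}"
        row["interaction_hr"] = f"{r.interaction_hr:.2f}"
        row["interaction_p"] = f"{r.interaction_p:.3g}"
        rows.append(row)
    cols = ["marker", "endpoint", "low_hr", "low_ci", "high_hr", "high_ci",
            "interaction_hr", "interaction_p"]
    return pd.DataFrame(rows, columns=cols)


def render_multivariate_table(result: InteractionResult) -> pd.DataFrame:
    """Per-term report of the full interaction model (HR, CI, p)."""
    s = result.base.summary
    return pd.DataFrame({
        "term": s.index,
        "hr": [f"{v:.2f}" for v in s["hr"]],
        "ci95": [f"{lo:.2f}-{hi:.2f}"
                 for lo, hi in zip(s["ci_low"], s["ci_high"])],
        "p": [f"{v:.3g}" for v in s["p"]],
    })


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- inputs -----------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            spec = CohortSpec(**{**config.simulate, "seed": config.seed})
            cohort = generate_cohort(spec)
            write_cohort(cohort, outdir / "cohort")
            expr_raw = cohort.expression
            clinical = cohort.clinical
            outcome = (cohort.survival_drfs if config.endpoint == "DRFS"
                       else cohort.survival_os)
        else:
            stage = "load"
            expr_raw = ExpressionMatrix.from_tsv(config.expression_path)
            clinical = read_clinical(config.clinical_path)
            path = (config.survival_drfs_path if config.endpoint == "DRFS"
                    else config.survival_os_path)
            outcome = read_survival(path, endpoint=config.endpoint)
        treatment = clinical["arm"].astype(int)
        log.info("inputs: %d probes x %d samples, %d events (%s)",
                 len(expr_raw.probe_ids), len(expr_raw.sample_ids),
                 outcome.n_events, config.endpoint)

        # ---- normalize --------------------------------------------------
        stage = "normalize"
        expr, norm_info = normalize_counts(
            expr_raw, k_sd=config.k_sd, pseudocount=config.pseudocount,
            method=config.norm_method)
        expr.to_tsv(outdir / "normalized.tsv")
        log.info("normalized; %d counts floored to background",
                 norm_info.n_flagged)

        covariates = clinical[config.covariates].astype(float)

        # ---- score configured signatures -------------------------------
        stage = "score"
        evaluations: list[InteractionResult] = []
        for name, path in config.signatures.items():
            sig = SignatureDefinition.read(path, name=name)
            sc = score_signature(expr, sig, standardize=not sig.weighted)
            sc = dichotomize_at_median(sc)
            sc.to_frame().to_csv(outdir / f"scores_{name}.csv",
                                 float_format="%.10g")
            evaluations.append(treatment_by_marker(
                sc, treatment, outcome, covariates=covariates,
                ties=config.ties, label=name))
            for levels in ({3}, {1, 2}):
                evaluations.append(subgroup_by_grade(
                    sc, treatment, outcome, clinical, levels,
                    covariates=None, ties=config.ties))

        # ---- derive a minimal signature ---------------------------------
        derived: DerivationResult | None = None
        if config.derive:
            stage = "derive"
            derived = run_derivation(
                expr, treatment, outcome, covariates,
                sizes=config.sizes, n_candidates=config.n_candidates,
                B=config.B, train_frac=config.train_frac,
                alpha_cmf=config.alpha_cmf, eval_rule=config.eval_rule,
                target_k=config.target_k, seed=config.seed)
            d = outdir / "derivation"
            d.mkdir(exist_ok=True)
            derived.clustering.labels.to_csv(d / "clustering.csv")
            derived.screen.table.to_csv(d / "screen.csv",
                                        float_format="%.10g")
            (d / "candidates.txt").write_text(
                "\n".join(derived.candidates.genes) + "\n")
            derived.ranking.to_csv(d / "ranking.csv", float_format="%.10g")
            derived.signature.write(d / "signature.txt")
            log.info("derivation: %d clusters, %d candidates, %d subsets; "
                     "winner %s", derived.clustering.k,
                     len(derived.candidates.genes),
                     derived.params["n_subsets"],
                     "+".join(derived.best.genes))

            stage = "evaluate"
            sc = score_signature(expr, derived.signature, standardize=False)
            sc = sc.standardized()
            sc.to_frame().to_csv(outdir / "scores_derived.csv",
                                 float_format="%.10g")
            evaluations.append(treatment_by_marker(
                sc.scores.rename("derived_signature"), treatment, outcome,
                covariates=covariates, ties=config.ties,
                label="derived_signature"))

        # ---- reports ----------------------------------------------------
        stage = "report"
        if evaluations:
            render_table1_style(evaluations).to_csv(
                outdir / "interaction_report.csv", index=False)
            render_multivariate_table(evaluations[-1]).to_csv(
                outdir / "multivariate_report.csv", index=False)
            results_json = {
                r.label: {
                    "endpoint": r.endpoint,
                    "n": r.base.n,
                    "n_events": r.base.n_events,
                    "interaction_hr": round(r.interaction_hr, 6),
                    "interaction_ci": [round(v, 6) for v in r.interaction_ci],
                    "interaction_p": round(r.interaction_p, 8),
                    "terms": {t: round(r.base.hr(t), 6)
                              for t in r.base.terms},
                } for r in evaluations
            }
            with open(outdir / "results.json", "w") as fh:
                json.dump(results_json, fh, indent=1, sort_keys=True)
                fh.write("\n")

        provenance = {
            "config": config.to_dict(),
            "seed": config.seed,
            "panel": {"n_probes": int(len(expr_raw.probe_ids)),
                      "n_samples": int(len(expr_raw.sample_ids)),
                      "n_assayed_genes": int(expr_raw.n_assayed_genes)},
            "stages": ["simulate" if config.simulate else "load", "normalize",
                       "score", "derive" if config.derive else None,
                       "report"],
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir
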