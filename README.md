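# cinsig

Chromosome instability (CIN) in breast tumours — karyotype-level genomic
instability producing numerical and structural chromosomal aberrations —
has been proposed both as a prognostic marker and as a *predictive*
marker of benefit from anthracycline-containing chemotherapy.  `cinsig`
is a Python library for the full analysis chain behind that question,
aimed at biostatisticians and translational researchers working with
digital-counting (NanoString nCounter-style) expression panels and
randomized-trial outcomes:

* **Normalization** of raw probe counts using spike-in positive controls
  (geometric-mean or standard-curve scaling), negative-control
  background thresholding, and housekeeping (reference-gene) scaling.
* **Signature scoring**: unweighted signatures such as CIN25/CIN70
  (mean of per-gene z-scores of log2 expression) and coefficient-weighted
  signatures such as CIN4 (Σ wᵍ·xᵍ), dichotomized at the cohort median
  (High ⇔ score strictly above the median).
* **Survival modelling**: Cox proportional-hazards fits (Breslow or
  Efron ties), Kaplan–Meier curves, and treatment-by-marker interaction
  analyses.  For marker M, treatment T (1 = anthracycline arm) and
  covariates **x**, the key model is

      h(t) = h₀(t) · exp(β'x + θM + γT + δ·M·T)

  where exp(δ) is the treatment-by-marker hazard ratio — the criterion
  for *predictive* (treatment-modifying) rather than merely prognostic
  value.  Within-stratum treatment contrasts are reported without
  p-values; inference rests on the interaction term.
* **Time-dependent ROC**: cumulative/dynamic survival AUC at horizon t
  (cases = events by t, controls = event-free beyond t) with censoring
  handled by nested Kaplan–Meier or nearest-neighbour conditional
  survival estimators.
* **Signature derivation**: affinity-propagation clustering of the gene
  panel, per-arm adjusted Cox screening (significant in the
  anthracycline arm, not in the comparator arm), cluster-size-weighted
  candidate selection, exhaustive enumeration of 2–5-gene subsets,
  bagged survival-AUC scoring (repeated event-stratified 60/40
  train/test splits; the median test-set AUC is the bagged statistic),
  ranking by the treated-minus-control AUC differential, and a final
  coefficient-weighted signature fit.
* **Synthetic cohorts**: a generator emulating a merged two-trial
  randomized design (two cohorts of 282 and 421 samples, 1:1
  randomization to anthracycline vs CMF-only arms, correlated clinical
  covariates, overdispersed counts with spike-in controls) with a
  *planted* treatment×signature interaction of configurable size, so
  every stage can be validated against ground truth.

## Worked example

Simulate a cohort with the default planted interaction (HR 0.35 per SD
of signature score), normalize, score the planted genes, and test the
interaction:

```python
from cinsig import (CohortSpec, generate_cohort, normalize_counts,
                    SignatureDefinition, score_signature,
                    treatment_by_marker)

cohort = generate_cohort(CohortSpec(n_trial1=1000, n_trial2=1000, seed=3))
expr, info = normalize_counts(cohort.expression)

sig = SignatureDefinition("planted", ["HDGF", "KIAA0286", "RFC4", "MSH6"])
score = score_signature(expr, sig, standardize=True).standardized()

cov = cohort.clinical[["grade", "size", "nodes", "her2", "pgr"]].astype(float)
res = treatment_by_marker(score.scores.rename("score"),
                          cohort.clinical["arm"], cohort.survival_drfs,
                          covariates=cov)
print(f"interaction HR {res.interaction_hr:.2f} "
      f"[{res.interaction_ci[0]:.2f}, {res.interaction_ci[1]:.2f}], "
      f"p = {res.interaction_p:.3g}")
```

This prints

```
interaction HR 0.37 [0.32, 0.43], p = 1e-35
```

i.e. the fitted treatment-by-score hazard ratio (0.37 per SD of score)
recovers the planted 0.35 up to sampling noise: each unit of signature
score multiplies the anthracycline-arm hazard by ≈0.37, while the score
carries no effect in the comparator arm.

The same stages are available from the shell:

```bash
cinsig simulate --seed 3 --out cohort/
cinsig normalize --in cohort/expression.tsv --out norm.tsv
cinsig score --expr norm.tsv --signature cin25.txt --out scores.csv
cinsig derive --expr norm.tsv --clinical cohort/clinical.csv \
              --survival cohort/survival_drfs.csv --seed 3 --out derived/
cinsig run --config pipeline.yaml --out run/     # all-in-one
```

## Layout

```
src/cinsig/
  matrix.py       probe x sample expression container + TSV/RCC I/O
  nanostring.py   positive-control / background / housekeeping normalization
  signatures.py   signature scoring and median dichotomization
  survival.py     Cox fits, KM curves, treatment-by-marker analyses
  tdroc.py        time-dependent (cumulative/dynamic) ROC and AUC
  derivation.py   clustering, screening, subset search, bagged AUC
  cohort.py       synthetic two-trial cohort generator
  pipeline.py     config-driven orchestration and table-style reports
  cli.py          command-line interface (`cinsig`)
docs/methods.md   model and design notes
```
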