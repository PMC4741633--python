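# Methods notes

This note documents the models, estimators and design choices behind
`cinsig`, including what the synthetic cohorts do and do not emulate.

## Normalization of digital counts

Raw probe counts are normalized in three steps, in this order:

1. **Positive-control scaling.** Each lane is multiplied by
   `G / g_s`, where `g_s` is the geometric mean of the lane's spike-in
   positive-control counts and `G` the grand geometric mean of the
   `g_s` over lanes.  Geometric-mean scaling is the dominant field
   convention and needs no nominal-concentration file; a standard-curve
   variant (per-lane regression through the origin of control counts on
   the nominal 4-fold ladder, slopes equalized) is available via
   `method="curve"`.
2. **Background thresholding.** Per lane, background = mean + k·SD
   (sample SD, k = 2 by default) of the negative-control counts.
   Endogenous counts at or below background are flagged and *floored*
   to the background value.  Flooring rather than subtraction is
   chosen so that no negative counts can arise and the subsequent
   log transform is always defined.
3. **Reference-gene scaling.** Lanes are rescaled so that each lane's
   housekeeping geometric mean equals the grand housekeeping geometric
   mean.

Whether background correction belongs before or after positive-control
scaling is a genuinely open ordering question; positive-control →
background → housekeeping is used here because the spike-in scaling is
a technical (lane-level) correction that should precede any
content-based decision.  Counts are then log2-transformed with
pseudocount 1 (counts are integers ≥ 0).

Two practical invariances hold and are tested: normalization is
equivariant under sample reordering, and multiplying one lane's raw
counts by c > 0 changes its normalized counts only by the cohort
calibration factor c^(1/n) (the grand geometric means include the
lane), which vanishes with cohort size.

## Signature scores

Unweighted signatures (CIN25/CIN70 style) default to the mean of
per-gene z-scores of log2 expression across the cohort; a raw-mean
variant is available (`standardize=False`).  The exact historical
scoring formula for these signatures is not fully specified in the
primary literature, so both variants are provided.  Weighted signatures
score Σ wᵍ·xᵍ.  A zero-variance gene under standardization contributes
0 with a warning.

Dichotomization uses the median over all scored samples of the merged
cohort; High means strictly above the median, so ties go Low.  This
makes the dichotomy invariant under strictly increasing transforms of
the score.  The sharp imbalance bound under this convention is
|#High − #Low| ≤ max(1, 2·t − 1) where t is the number of samples tied
at the median.

For continuous-marker models, `SignatureScore.standardized()` rescales
the score to unit variance so hazard ratios are per SD of score —
comparable across signatures and matching how the synthetic generator
defines its planted (standardized) score.

## Cox models and the treatment-by-marker criterion

Cox fits use the partial likelihood with Breslow tie handling by
default (the convention of the classical trial-analysis packages);
Efron is switchable and the two agree to 1e-6 on tie-free data.
Wald-based 95% CIs and p-values are reported per term.  Rows with
missing covariates are dropped and counted.  Monotone-likelihood
(perfect-separation) terms are flagged and the fit marked
non-converged; constant columns get coefficient 0 with undefined Wald
statistics.

The predictive analysis fits marker + covariates + treatment +
marker×treatment and, for Table-style reporting, unadjusted
treatment-only models within the Low and High marker strata.
Within-stratum contrasts are reported without p-values to avoid
multiple testing over subgroups; the interaction term carries the
inference.  Covariate codings: grade ordinal 1–3, tumour size binary
(>2 cm), nodal status binary, receptors binary.  Both the covariate
set with ER and the set with PgR are supported via configuration, since
published multivariate tables differ on this point.  A CEP17 column
participates only if supplied.

## Time-dependent (cumulative/dynamic) ROC

At horizon t, cases are subjects with events by t and controls those
event-free beyond t.  With S(t | X > c) the conditional survival in the
upper marker set,

    TP(c) = [1 − S(t|X>c)]·P(X>c) / [1 − S(t)]
    FP(c) =      S(t|X>c) ·P(X>c) /      S(t)

The default estimator plugs in nested Kaplan–Meier estimates (computed
for all cutpoints in one pass over prefixes of the descending-marker
ordering); the nearest-neighbour (NNE) estimator smooths the bivariate
survival over a percentile window of half-width 0.25·n^(−0.20).  The
raw KM curve can be locally non-monotone, so curves are rectified by a
running maximum over decreasing cutpoints before trapezoidal
integration.  Without censoring the estimator reduces exactly to the
empirical ROC (Mann–Whitney AUC); this, plus agreement with an
exhaustive per-cutpoint enumeration oracle, anchors the tests.  The
negation identity AUC(−m) = 1 − AUC(m) is exact only without censoring,
because the nested estimator conditions on upper marker sets.

The ROC horizon defaults to the median observed follow-up of the arm
being scored: the evaluation time used in the historical analyses is
unknown, and a data-driven horizon keeps case/control counts usable, so
all AUC-dependent checks are property- and simulation-based rather than
matches to printed AUC values.

## Derivation of a minimal predictive signature

1. **Clustering.** Affinity propagation on similarity = negative
   squared Euclidean distance between standardized gene profiles;
   preference defaults to the median similarity, damping 0.9.  The
   cluster count emerges from the preference; `target_k` adjusts the
   preference by bisection when a fixed count (e.g. 9) is wanted.
2. **Screening.** Per gene and per treatment arm, an adjusted Cox model
   (gene + clinical covariates); genes are ranked within clusters by
   anthracycline-arm p, qualifying only if the comparator-arm p ≥ 0.05
   — the arm-specific (predictive) pattern.
3. **Candidate list.** Cluster quotas by largest-remainder
   apportionment of the total over cluster sizes with a floor of one
   per cluster (every cluster must be represented); a cluster with no
   qualifying gene contributes its single best anthracycline-arm gene;
   unfilled quota is re-allocated to the best remaining qualifying
   genes elsewhere.
4. **Subset search.** Every 2–5-gene combination of the candidates is
   scored by bagged survival AUC.  "Bagged" here means B repeated
   event-stratified 60/40 train/test splits (B = 100 by default): a
   with-replacement bootstrap combined with a 60/40 split would be
   contradictory, so Monte-Carlo splitting is the default and a true
   bootstrap (out-of-bag test) is available via `mode="bootstrap"`.
   Per replicate, an unadjusted Cox model of the subset is fitted on
   the training part and its linear predictor scored on the test part
   at the arm's median follow-up; the median over replicates is the
   bagged statistic.  Every subset is scored on the *same* splits
   (common random numbers), so subset comparisons are paired and split
   noise cancels from the ranking.
5. **Ranking.** Subsets are ranked by the treated-minus-control
   median-AUC differential — a predictive signature should rank
   outcomes well only in the treated arm.  Ties break by higher
   treated AUC, then smaller subset, then lexicographic order.
6. **Weighting.** The winning genes are refitted jointly with the
   clinical covariates on the merged cohort; their coefficients become
   the signature weights.  The weighted score is therefore a
   merged-cohort *risk* linear predictor: higher score = higher
   predicted hazard.

**Orientation of the derived score.**  When the planted signal is
purely predictive (no prognostic main effect — the synthetic
generator's hazard contains the score only through the treatment
interaction), the merged-cohort gene coefficients are proportional to
δ·P(treated) and hence negative for a beneficial interaction: the risk
score is anti-correlated with the planted benefit score, and the
planted interaction surfaces on the risk-score orientation as
HR ≈ 1/0.35 > 1.  This is a pure reparameterization — negating the
score recovers HR ≈ 0.35 — and the end-to-end tests assert the
orientation-corrected property.  On real cohorts, where instability
signatures typically carry a strong adverse prognostic main effect, the
same weighting yields positively oriented scores.

### Computational engines

The bagged search needs ~10⁵–10⁶ small Cox fits and AUCs.  Two
interchangeable paths exist: a per-subset reference path
(`bagged_auc`, Newton–Raphson Breslow solver + single-marker AUC) and a
batched path (`bag_subsets`) that vectorizes the Newton iterations and
the prefix-cumsum ROC computation across all subsets of a size class.
The two agree to ~1e-9 (tested) and the lean solver agrees with the
general-purpose fitter to 1e-6.  Bagging-plan survival structures are
held in float32 (counts are exact in float32; AUC effects ~1e-7, far
below ranking noise); the general `survival_auc` path stays float64.

## Synthetic cohorts: what they emulate

Defaults are fixed once and mirror the merged two-trial design:

* 282 + 421 samples, 1:1 randomization within trial.
* Clinical covariates: grade ∈ {1,2,3} with probabilities
  (0.1, 0.4, 0.5) (high-grade enriched), ER/PgR positive with marginal
  rates 0.60/0.55 correlated 0.7 via a shared latent normal, HER2 0.25,
  size >2 cm 0.5, node-positive 0.65, age ~ N(52, 9²) — qualitative
  margins, not a claim to the real trials' joint distribution.
* Expression: gene baseline means log-normal (median 200 counts,
  log-sd 0.7); per-sample gene noise sd 0.25 (log scale); lane factors
  log-normal (sd 0.2); counts negative-binomial with dispersion 0.1
  plus Poisson(2) background; positive controls on a 4-fold geometric
  ladder (~250 counts/fM); negatives Poisson(2).
* Planted signature: the designated genes carry a shared
  co-regulation factor (loading 0.25) *and* gene-specific components
  (sd 1.0).  The latent score — the standardized mean of the planted
  genes' log-expression — then correlates >0.93 with the score
  recomputed from normalized counts, while each gene contributes
  complementary information, which is what makes a 4-gene signature
  genuinely minimal rather than redundant.
* Survival: h(t) = h₀·exp(β'x + γT + δ·T·score) with the linear
  predictor centred; exponential baseline by default (closed-form
  inverse sampling; Weibull (shape, scale) optional).  Default effects
  echo the magnitudes of published multivariate tables: grade 0.50,
  nodes 0.80, size 0.55, HER2 0.28, PgR 0.14 (log-hazard per coding
  unit), treatment log(0.60), interaction log(0.35) per SD of score.
  Censoring = independent exponential (rate 0.02/yr) plus a 10-year
  administrative cutoff; the baseline DRFS hazard (0.047/yr) is
  calibrated so the default cohort realizes ≈60% censoring, the stated
  study condition.  OS uses a lower baseline (0.038/yr) on the same
  linear predictor.

Not emulated: FFPE degradation, batch effects between the trials,
probe-level QC failures, exact event counts or follow-up of the real
trials, or any real patient-level association structure.  Passing tests
therefore demonstrate that the estimators and the search recover known
planted structure under a realistic randomized design — not that the
historical hazard ratios (which depend on undeposited patient-level
data) are reproduced.

## Determinism

All randomness flows from a single master seed through
`numpy.random.SeedSequence` stream-splitting (cohort: separate streams
for clinical, latent, expression, each endpoint, censoring; derivation:
one split-plan seed shared by all subsets, spawned per arm).  The
pipeline writes floats with fixed formats and sorted JSON keys, so a
re-run with the same config and seed is byte-identical — this is tested
at the output-file level.

## Problem sizes used in the checks

The automated checks run at deliberately reduced scale: interaction
recovery on n = 2000 cohorts (20 seeds), the planted-subset ranking on
n = 1200 cohorts with a 10-gene candidate list, C(10,4) = 210 subsets
and B = 50 splits (25 seeds), the end-to-end derivation on n = 600
with B = 25, and determinism on n = 240 with a reduced subset grid.
These sizes keep the full validation suite in the minutes range on a
single CPU while leaving every statistical property at tested
resolution.
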