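"""Signature-derivation engine: clustering, screening, candidate
selection, subset enumeration, bagged AUC scoring, ranking, weighting."""

import math

import numpy as np
import pandas as pd
import pytest

from cinsig._coxfast import breslow_fit, breslow_loglik
from cinsig.cohort import CohortSpec, generate_cohort
from cinsig.derivation import (BaggedSubsetResult, CandidateList, GeneClustering,
                               GeneScreenResult, bag_subsets, bagged_auc,
                               cluster_genes, cluster_quotas,
                               enumerate_subsets, fit_signature_weights,
                               run_derivation, screen_genes,
                               select_best_signature, select_candidates)
from cinsig.known import CIN4_GENES
from cinsig.matrix import ENDOGENOUS, ExpressionMatrix
from cinsig.nanostring import normalize_counts
from cinsig.signatures import score_signature
from cinsig.survival import SurvivalOutcome, fit_cox, treatment_by_marker

from conftest import toy_matrix
from oracles import reference_affinity_propagation


def log2_matrix(array, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    values = pd.DataFrame(array, index=genes, columns=samples)
    return ExpressionMatrix(values=values,
                            probe_class=pd.Series(ENDOGENOUS, index=genes),
                            scale="log2")


class TestClustering:
    def test_two_separated_blocks_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=100)
        prof = np.vstack([
            np.tile(base, (5, 1)) + rng.normal(0, 0.01, (5, 100)),
            np.tile(-base, (6, 1)) + rng.normal(0, 0.01, (6, 100)),
        ])
        cl = cluster_genes(log2_matrix(prof))
        assert cl.k == 2
        labels = cl.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_single_gene_is_its_own_exemplar(self):
        cl = cluster_genes(log2_matrix(np.random.default_rng(0)
                                       .normal(size=(1, 20))))
        assert cl.k == 1
        assert cl.exemplars[0] == "g0"

    def test_matches_reference_message_passing(self):
        rng = np.random.default_rng(42)
        prof = rng.normal(size=(40, 120))
        cl = cluster_genes(log2_matrix(prof), damping=0.9)
        z = (prof - prof.mean(1, keepdims=True)) / prof.std(1, keepdims=True)
        sq = (z * z).sum(1)
        S = -(sq[:, None] + sq[None, :] - 2 * z @ z.T)
        ref = reference_affinity_propagation(S, cl.preference, damping=0.9)
        assert ref is not None
        assert np.array_equal(cl.labels.to_numpy(), ref[0])

    def test_target_k_bisection(self):
        rng = np.random.default_rng(5)
        prof = rng.normal(size=(70, 100))
        cl = cluster_genes(log2_matrix(prof), target_k=9)
        assert cl.k == 9

    def test_exemplars_belong_to_their_clusters(self, normalized):
        endo = normalized.subset_probes(normalized.endogenous_probes)
        cl = cluster_genes(endo)
        for cid, gene in cl.exemplars.items():
            assert cl.labels[gene] == cid

    def test_damping_out_of_range_rejected(self):
        m = log2_matrix(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            cluster_genes(m, damping=0.3)


class TestScreening:
    def _screen_planted(self, seed, n=800):
        c = generate_cohort(CohortSpec(n_trial1=n // 2, n_trial2=n // 2,
                                       seed=seed))
        expr, _ = normalize_counts(c.expression)
        cov = c.clinical[["grade", "size", "nodes", "her2", "pgr"]]
        return screen_genes(expr, c.clinical["arm"], c.survival_drfs, cov,
                            genes=list(CIN4_GENES))

    def test_planted_gene_is_arm_specific(self):
        # predictive-only genes: significant in the anthracycline arm,
        # not in the CMF arm, for most seeds
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            screen = self._screen_planted(seed)
            gene = "HDGF"
            if screen.p_treated(gene) < 0.05 and screen.p_control(gene) > 0.05:
                hits += 1
        assert hits >= 0.75 * n_seeds

    def test_null_gene_pvalues_roughly_uniform(self):
        from scipy.stats import kstest
        pvals = []
        for seed in range(3):
            c = generate_cohort(CohortSpec(n_trial1=200, n_trial2=200,
                                           seed=300 + seed))
            expr, _ = normalize_counts(c.expression)
            cov = c.clinical[["grade", "size", "nodes", "her2", "pgr"]]
            nulls = [g for g in expr.endogenous_probes
                     if g not in CIN4_GENES]
            screen = screen_genes(expr, c.clinical["arm"], c.survival_drfs,
                                  cov, genes=nulls)
            pvals.extend(screen.table["p_cmf"].tolist())
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_gene_flagged(self, small_cohort):
        expr, _ = normalize_counts(small_cohort.expression)
        cov = small_cohort.clinical[["grade"]].astype(float)
        # make one gene an exact copy of the grade covariate
        vals = expr.values.copy()
        vals.loc["CDC2"] = cov["grade"].to_numpy()
        expr2 = expr.with_values(vals)
        screen = screen_genes(expr2, small_cohort.clinical["arm"],
                              small_cohort.survival_drfs, cov,
                              genes=["CDC2"])
        assert bool(screen.table.loc["CDC2", "flagged"])
        assert screen.table.loc["CDC2", "p_anthracycline"] == 1.0


class TestCandidateSelection:
    def test_quotas_weighted_by_cluster_size(self):
        assert cluster_quotas([1, 1, 1, 2, 4, 2, 2, 4, 4], 21) == \
            [1, 1, 1, 2, 4, 2, 2, 4, 4]

    def test_quotas_enforce_cluster_representation(self):
        # a tiny cluster still gets one slot
        q = cluster_quotas([1, 50, 49], 10)
        assert q[0] >= 1 and sum(q) == 10

    def test_total_below_cluster_count_rejected(self):
        with pytest.raises(ValueError):
            cluster_quotas([3, 3, 3], 2)

    def _toy_inputs(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        labels = pd.Series([0, 0, 0, 0, 1, 1], index=genes)
        clusters = GeneClustering(labels=labels, exemplars={0: "a", 1: "e"},
                                  k=2, preference=0.0, damping=0.9)
        table = pd.DataFrame({
            "p_anthracycline": [0.01, 0.30, 0.02, 0.04, 0.50, 0.90],
            "p_cmf":           [0.50, 0.80, 0.01, 0.60, 0.02, 0.03],
            "flagged": False}, index=genes)
        screen = GeneScreenResult(table=table, covariates_used=[])
        return clusters, screen

    def test_membership_matches_hand_enumeration(self):
        clusters, screen = self._toy_inputs()
        # quotas for sizes (4,2), total 3: ideal (2, 1) -> (2, 1)
        # cluster 0 qualifying (p_cmf>=0.05): a(0.01), d(0.04), b(0.30) -> a,d
        # cluster 1 qualifying: none -> best p_anthracycline: e
        out = select_candidates(clusters, screen, total=3, alpha_cmf=0.05)
        assert out.genes == ["a", "d", "e"]
        assert out.per_cluster_allocation == {0: 2, 1: 1}

    def test_single_cluster_takes_best_qualifying(self):
        genes = [f"g{i}" for i in range(8)]
        labels = pd.Series(0, index=genes)
        clusters = GeneClustering(labels=labels, exemplars={0: "g0"}, k=1,
                                  preference=0.0, damping=0.9)
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "p_anthracycline": rng.uniform(size=8),
            "p_cmf": 0.5, "flagged": False}, index=genes)
        screen = GeneScreenResult(table=table, covariates_used=[])
        out = select_candidates(clusters, screen, total=5)
        expected = list(table["p_anthracycline"].sort_values().index[:5])
        assert out.genes == expected


class TestEnumeration:
    @pytest.mark.parametrize("n,k", [(4, 4), (10, 3), (21, 2), (21, 5),
                                     (25, 5)])
    def test_counts_are_binomial_coefficients(self, n, k):
        genes = [f"g{i}" for i in range(n)]
        subsets = list(enumerate_subsets(genes, [k]))
        assert len(subsets) == math.comb(n, k)
        assert len(set(subsets)) == len(subsets)

    def test_lexicographic_in_candidate_order(self):
        subsets = list(enumerate_subsets(["w", "x", "y"], [2]))
        assert subsets == [("w", "x"), ("w", "y"), ("x", "y")]

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_subsets(["a", "b"], [3]))


class TestFastCox:
    def test_matches_general_fitter(self):
        rng = np.random.default_rng(10)
        n = 150
        X = rng.normal(size=(n, 3))
        t = rng.exponential(1.0 / (0.2 * np.exp(X @ [0.5, -0.4, 0.0])))
        c = rng.exponential(6.0, size=n)
        ev = (t <= c).astype(int)
        tobs = np.minimum(t, c)
        beta, conv = breslow_fit(X, tobs, ev)
        idx = pd.Index([f"s{i}" for i in range(n)])
        out = SurvivalOutcome(time=pd.Series(tobs, index=idx),
                              event=pd.Series(ev, index=idx))
        fit = fit_cox(pd.DataFrame(X, index=idx, columns=list("abc")), out,
                      ties="breslow")
        assert conv
        assert np.allclose(beta, fit.summary["coef"], atol=1e-6)

    def test_maximizes_reference_partial_likelihood(self):
        rng = np.random.default_rng(3)
        n = 40
        X = rng.normal(size=(n, 2))
        t = rng.exponential(1.0, size=n)
        ev = rng.binomial(1, 0.7, size=n)
        if ev.sum() == 0:
            ev[0] = 1
        beta, _ = breslow_fit(X, t, ev)
        ll_hat = breslow_loglik(beta, X, t, ev)
        for _ in range(20):
            other = beta + rng.normal(0, 0.3, size=2)
            assert breslow_loglik(other, X, t, ev) <= ll_hat + 1e-8

    def test_no_events_returns_zero(self):
        beta, conv = breslow_fit(np.ones((4, 1)), np.arange(1.0, 5.0),
                                 np.zeros(4))
        assert not conv and beta[0] == 0.0


class TestBaggedAuc:
    @pytest.fixture(scope="class")
    def cohort(self):
        c = generate_cohort(CohortSpec(n_trial1=150, n_trial2=150, seed=31))
        expr, _ = normalize_counts(c.expression)
        return c, expr

    def test_same_seed_reproduces_replicates(self, cohort):
        c, expr = cohort
        a = bagged_auc(CIN4_GENES, expr, c.clinical["arm"], c.survival_drfs,
                       B=8, seed=5)
        b = bagged_auc(CIN4_GENES, expr, c.clinical["arm"], c.survival_drfs,
                       B=8, seed=5)
        assert a.replicate_aucs_treated == b.replicate_aucs_treated
        assert a.replicate_aucs_control == b.replicate_aucs_control

    def test_constant_subset_scores_half(self, cohort):
        c, expr = cohort
        vals = expr.values.copy()
        vals.loc["CDC2"] = 3.0
        flat = expr.with_values(vals)
        res = bagged_auc(("CDC2",), flat, c.clinical["arm"],
                         c.survival_drfs, B=6, seed=2)
        assert res.median_auc_treated == 0.5
        assert res.median_auc_control == 0.5

    def test_batched_path_equals_reference_path(self, cohort):
        c, expr = cohort
        subsets = [("HDGF", "RFC4"), ("CDC2", "KIF20A", "MSH6"),
                   ("HDGF", "KIAA0286", "RFC4", "MSH6")]
        batch = bag_subsets(subsets, expr, c.clinical["arm"],
                            c.survival_drfs, B=10, seed=17)
        for sub, got in zip(subsets, batch):
            ref = bagged_auc(sub, expr, c.clinical["arm"], c.survival_drfs,
                             B=10, seed=17)
            assert np.allclose(ref.replicate_aucs_treated,
                               got.replicate_aucs_treated, atol=1e-9,
                               equal_nan=True)
            assert np.allclose(ref.replicate_aucs_control,
                               got.replicate_aucs_control, atol=1e-9,
                               equal_nan=True)

    def test_bootstrap_mode_runs(self, cohort):
        c, expr = cohort
        res = bagged_auc(CIN4_GENES, expr, c.clinical["arm"],
                         c.survival_drfs, B=6, seed=3, mode="bootstrap")
        assert np.isfinite(res.median_auc_treated)

    def test_median_fields_equal_replicate_medians(self, cohort):
        c, expr = cohort
        res = bagged_auc(CIN4_GENES, expr, c.clinical["arm"],
                         c.survival_drfs, B=9, seed=4)
        assert res.median_auc_treated == np.nanmedian(
            res.replicate_aucs_treated)

    def test_invalid_parameters_rejected(self, cohort):
        c, expr = cohort
        with pytest.raises(ValueError):
            bagged_auc(CIN4_GENES, expr, c.clinical["arm"],
                       c.survival_drfs, B=0)
        with pytest.raises(ValueError):
            bagged_auc(CIN4_GENES, expr, c.clinical["arm"],
                       c.survival_drfs, train_frac=1.5)
        with pytest.raises(KeyError):
            bagged_auc(("NOPE",), expr, c.clinical["arm"], c.survival_drfs)


class TestSelection:
    def _result(self, genes, treated, control, seed=0):
        return BaggedSubsetResult(genes=tuple(genes),
                                  replicate_aucs_treated=list(treated),
                                  replicate_aucs_control=list(control),
                                  seed=seed)

    def test_single_candidate_returned(self):
        r = self._result("ab", [0.7], [0.5])
        best, table = select_best_signature([r])
        assert best.genes == ("a", "b")
        assert len(table) == 1

    def test_tie_broken_by_treated_auc(self):
        r1 = self._result("ab", [0.75], [0.5])     # differential 0.25
        r2 = self._result("cd", [0.625], [0.375])  # differential 0.25
        best, _ = select_best_signature([r2, r1])
        assert best.genes == ("a", "b")

    def test_higher_differential_wins(self):
        r1 = self._result("ab", [0.60], [0.50])
        r2 = self._result("cd", [0.70], [0.40])
        best, table = select_best_signature([r1, r2])
        assert best.genes == ("c", "d")
        assert table.iloc[0]["differential"] == pytest.approx(0.30)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_best_signature([])


class TestSignatureWeights:
    def test_duplicate_gene_rejected(self, normalized, small_cohort):
        with pytest.raises(ValueError, match="unique"):
            fit_signature_weights(["CDC2", "CDC2"], normalized,
                                  small_cohort.survival_drfs,
                                  small_cohort.clinical[["grade"]])

    def test_planted_coefficients_recovered(self):
        rng = np.random.default_rng(6)
        n = 2000
        truth = np.array([-0.8, -0.5, 0.4, 0.6])
        X = rng.normal(size=(4, n))
        t = rng.exponential(1.0 / (0.1 * np.exp(truth @ X)))
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        expr = log2_matrix(X, genes=["w", "x", "y", "z"], samples=list(idx))
        out = SurvivalOutcome(time=pd.Series(t, index=idx),
                              event=pd.Series(1, index=idx, dtype=int))
        sig = fit_signature_weights(["w", "x", "y", "z"], expr, out,
                                    pd.DataFrame(index=idx))
        assert np.allclose(sig.weights, truth, atol=0.2)

    def test_outcome_orthogonal_genes_get_near_zero_weights(self):
        rng = np.random.default_rng(9)
        n = 2000
        X = rng.normal(size=(3, n))
        t = rng.exponential(5.0, size=n)  # independent of the genes
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        expr = log2_matrix(X, genes=["a", "b", "c"], samples=list(idx))
        out = SurvivalOutcome(time=pd.Series(t, index=idx),
                              event=pd.Series(1, index=idx, dtype=int))
        sig = fit_signature_weights(["a", "b", "c"], expr, out,
                                    pd.DataFrame(index=idx))
        assert np.all(np.abs(sig.weights) < 0.12)


class TestEndToEnd:
    def test_pipeline_detects_planted_predictive_signature(self):
        """With a planted interaction of HR 0.35 per unit score, the
        derived coefficient-weighted score (a merged-cohort risk score)
        carries the interaction: the benefit-oriented score has HR < 1,
        i.e. the raw risk-score interaction log-HR is positive."""
        n_seeds = 5
        hits = 0
        for seed in range(n_seeds):
            c = generate_cohort(CohortSpec(n_trial1=300, n_trial2=300,
                                           seed=50 + seed))
            expr, _ = normalize_counts(c.expression)
            cov = c.clinical[["grade", "size", "nodes", "her2", "pgr"]]
            d = run_derivation(expr, c.clinical["arm"], c.survival_drfs,
                               cov, sizes=[4], n_candidates=10, B=25,
                               seed=seed)
            sc = score_signature(expr, d.signature,
                                 standardize=False).standardized()
            res = treatment_by_marker(sc.scores.rename("derived"),
                                      c.clinical["arm"], c.survival_drfs,
                                      covariates=cov)
            if np.log(res.interaction_hr) > 0:  # benefit-oriented HR < 1
                hits += 1
        assert hits >= n_seeds - 1

    def test_derivation_deterministic_under_master_seed(self):
        c = generate_cohort(CohortSpec(n_trial1=120, n_trial2=120, seed=77))
        expr, _ = normalize_counts(c.expression)
        cov = c.clinical[["grade", "size", "nodes", "her2", "pgr"]]
        kwargs = dict(sizes=[2], n_candidates=6, B=6, seed=3)
        a = run_derivation(expr, c.clinical["arm"], c.survival_drfs, cov,
                           **kwargs)
        b = run_derivation(expr, c.clinical["arm"], c.survival_drfs, cov,
                           **kwargs)
        pd.testing.assert_frame_equal(a.ranking, b.ranking)
        assert a.signature.genes == b.signature.genes
        assert a.signature.weights == b.signature.weights
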