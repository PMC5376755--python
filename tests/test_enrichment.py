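"""GSEA: enrichment statistic, set filtering, permutation significance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycstratify.containers import ExpressionMatrix
from mycstratify.enrichment import (
    GeneSetCollection,
    enrichment_score,
    filter_gene_sets,
    gsea_significance,
    tstat_metric,
)

HIGH, LOW = "MYC-high", "MYC-low"


def brute_force_es(ranked_genes, metric, gene_set, weight=1.0):
    """Plain-Python running-sum oracle for the weighted enrichment statistic."""
    members = set(gene_set)
    n = len(ranked_genes)
    n_hits = sum(g in members for g in ranked_genes)
    denom = sum(abs(m) ** weight for g, m in zip(ranked_genes, metric) if g in members)
    running, best = 0.0, 0.0
    for g, m in zip(ranked_genes, metric):
        if g in members:
            running += abs(m) ** weight / denom
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


class TestFilterGeneSets:
    def test_size_bounds_inclusive(self):
        genes = [f"g{i}" for i in range(600)]
        coll = GeneSetCollection(sets={
            "tiny": genes[:10],
            "edge": genes[:15],
            "big_partial": genes,          # 600 members, 400 present
        })
        present = genes[:400] + ["other"]
        kept = filter_gene_sets(coll, present, min_size=15, max_size=500)
        assert "tiny" not in kept.sets
        assert len(kept.sets["edge"]) == 15
        assert len(kept.sets["big_partial"]) == 400  # intersect THEN filter

    def test_empty_result_warns(self):
        coll = GeneSetCollection(sets={"s": ["a", "b"]})
        with pytest.warns(UserWarning):
            kept = filter_gene_sets(coll, ["a"], min_size=15)
        assert len(kept) == 0


class TestEnrichmentScore:
    def test_top_gene_set_scores_plus_one(self):
        genes = list("abcde")
        es, _ = enrichment_score(genes, [5.0, 4.0, 3.0, 2.0, 1.0], {"a"})
        assert es == pytest.approx(1.0)

    def test_bottom_gene_equal_metric_scores_minus_one(self):
        genes = list("abcde")
        es, _ = enrichment_score(genes, [1.0, 1.0, 1.0, 1.0, 1.0], {"e"})
        assert es == pytest.approx(-1.0)

    def test_reversed_ranking_flips_single_gene_es(self):
        genes = list("abcde")
        metric = [2.0, 1.0, 0.0, -1.0, -2.0]
        es_fwd, _ = enrichment_score(genes, metric, {"a"})
        es_rev, _ = enrichment_score(genes[::-1], metric[::-1], {"a"})
        assert es_fwd == pytest.approx(-es_rev)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        genes = [f"g{i}" for i in range(n)]
        metric = np.sort(rng.normal(size=n))[::-1]
        members = set(rng.choice(genes, size=8, replace=False))
        es, running = enrichment_score(genes, metric, members)
        assert es == pytest.approx(brute_force_es(genes, metric, members))
        assert len(running) == n

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_uniform_metric_rescaling(self, c):
        genes = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(7)
        metric = np.sort(rng.normal(size=12))[::-1]
        members = {"g1", "g4", "g9"}
        es_a, _ = enrichment_score(genes, metric, members)
        es_b, _ = enrichment_score(genes, metric * c, members)
        assert es_a == pytest.approx(es_b)

    def test_degenerate_sets_rejected(self):
        genes = list("abc")
        with pytest.raises(ValueError):
            enrichment_score(genes, [3.0, 2.0, 1.0], set(genes))
        with pytest.raises(ValueError):
            enrichment_score(genes, [0.0, 2.0, 1.0], {"a"})


class TestSignificance:
    def test_planted_set_positive_and_significant(self, small_cohort):
        coll = GeneSetCollection(sets={
            "PLANTED": list(small_cohort.myc_target_genes),
            "RANDOM": [f"BG{i + 1:04d}" for i in range(60, 110)],
        })
        report = gsea_significance(small_cohort.expression, small_cohort.true_labels,
                                   coll, n_perm=200, seed=3)
        planted = report.loc["PLANTED"]
        assert planted["es"] > 0 and planted["nes"] > 0
        assert planted["qvalue"] < 0.05
        assert set(report.columns) >= {"es", "nes", "pvalue", "qvalue", "size"}

    def test_pvalues_respect_add_one_floor(self, small_cohort):
        coll = GeneSetCollection(sets={"PLANTED": list(small_cohort.myc_target_genes)})
        report = gsea_significance(small_cohort.expression, small_cohort.true_labels,
                                   coll, n_perm=50, seed=3)
        assert (report["pvalue"] >= 1.0 / 51.0).all()
        assert (report["pvalue"] <= 1.0).all()
        assert np.sign(report["nes"]).equals(np.sign(report["es"]))

    def test_permutation_estimate_matches_exhaustive_enumeration(self):
        """On 4+4 samples the permutation null converges to the exhaustive
        label-assignment null."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(8)]
        samples = [f"s{i}" for i in range(8)]
        X = rng.normal(7, 1, size=(8, 8))
        X[:3, :4] += 1.5  # mild planted signal for the first three genes
        expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples),
                                scale="log2")
        members = {"g0", "g1", "g2"}
        labels = pd.Series([HIGH] * 4 + [LOW] * 4, index=samples)

        def es_for_mask(mask):
            metric = tstat_metric(X, np.asarray(mask))
            order = np.argsort(-metric, kind="stable")
            ranked = [genes[i] for i in order]
            return enrichment_score(ranked, metric[order], members)[0]

        obs = es_for_mask([True] * 4 + [False] * 4)
        null = [es_for_mask([i in combo for i in range(8)])
                for combo in itertools.combinations(range(8), 4)]
        null = np.array(null)
        same = null[null >= 0] if obs >= 0 else null[null < 0]
        exact_p = (np.sum(same >= obs) if obs >= 0 else np.sum(same <= obs)) / same.size

        report = gsea_significance(expr, labels,
                                   GeneSetCollection(sets={"S": sorted(members)}),
                                   n_perm=4000, seed=1, min_size=1)
        assert report.loc["S", "pvalue"] == pytest.approx(exact_p, abs=0.05)

    def test_null_sets_nominally_calibrated(self, null_cohort_frame):
        """About 5% of random sets reach nominal p <= 0.05 on a null cohort."""
        rng = np.random.default_rng(17)
        genes = list(null_cohort_frame.genes)
        fracs = []
        for rep in range(3):
            sets = {f"S{rep}_{k}": list(rng.choice(genes, size=20, replace=False))
                    for k in range(60)}
            lab = np.array([HIGH] * 15 + [LOW] * 15)
            rng.shuffle(lab)
            labels = pd.Series(lab, index=null_cohort_frame.samples)
            report = gsea_significance(null_cohort_frame, labels,
                                       GeneSetCollection(sets=sets),
                                       n_perm=200, seed=100 + rep, min_size=15)
            fracs.append((report["pvalue"] <= 0.05).mean())
        assert 0.005 <= np.mean(fracs) <= 0.15

    def test_requires_permutable_groups(self, small_cohort):
        labels = small_cohort.true_labels.copy()
        labels.iloc[:] = LOW
        labels.iloc[0] = HIGH
        coll = GeneSetCollection(sets={"S": list(small_cohort.myc_target_genes)})
        with pytest.raises(ValueError):
            gsea_significance(small_cohort.expression, labels, coll, n_perm=10)
        with pytest.raises(ValueError):
            gsea_significance(small_cohort.expression, small_cohort.true_labels,
                              coll, n_perm=0)
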