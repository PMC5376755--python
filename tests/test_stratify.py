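"""Stratification: clustering vs a brute-force oracle, ranking, BH, panel selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycstratify.containers import DEFAULT_PANEL, ExpressionMatrix
from mycstratify.stratify import (
    bh_fdr,
    count_increased,
    hclust_two_groups,
    select_marker_panel,
    ttest_rank,
)

HIGH, LOW = "MYC-high", "MYC-low"


def brute_force_complete_linkage_two_cut(points):
    """Independent agglomerative oracle: repeatedly merge the cluster pair with
    the smallest complete-linkage (max pairwise) distance until two remain."""
    clusters = [frozenset([i]) for i in range(len(points))]

    def linkdist(c1, c2):
        return max(np.linalg.norm(points[i] - points[j]) for i in c1 for j in c2)

    while len(clusters) > 2:
        best = min(itertools.combinations(clusters, 2), key=lambda p: linkdist(*p))
        clusters.remove(best[0])
        clusters.remove(best[1])
        clusters.append(best[0] | best[1])
    return set(map(frozenset, clusters))


def _expr_from_points(points, n_genes=None):
    points = np.asarray(points, dtype=float)
    samples = [f"s{i}" for i in range(points.shape[0])]
    genes = [f"g{i}" for i in range(points.shape[1])]
    return ExpressionMatrix(pd.DataFrame(points.T, index=genes, columns=samples),
                            scale="log2")


class TestClustering:
    def test_separable_blobs_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.2, size=(6, 4))
        b = rng.normal(5.0, 0.2, size=(5, 4))
        expr = _expr_from_points(np.vstack([a, b]))
        labels = hclust_two_groups(expr, list(expr.genes))
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert (labels.iloc[6:] == HIGH).all()  # blob b has the greater mean

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_cut_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 7)
        points = rng.normal(size=(n, 3))
        expr = _expr_from_points(points)
        labels = hclust_two_groups(expr, list(expr.genes))
        ours = {
            frozenset(i for i, s in enumerate(expr.samples) if labels[s] == grp)
            for grp in (HIGH, LOW)
        }
        assert ours == brute_force_complete_linkage_two_cut(points)

    def test_default_cohort_recovers_17_high(self, default_cohort):
        labels = hclust_two_groups(default_cohort.expression,
                                   default_cohort.myc_target_genes)
        assert (labels == HIGH).sum() == 17
        assert (labels == default_cohort.true_labels).all()

    def test_invariant_to_sample_and_gene_order(self, small_cohort):
        expr = small_cohort.expression
        panel = list(small_cohort.myc_target_genes)
        base = hclust_two_groups(expr, panel)
        rng = np.random.default_rng(0)
        shuffled = ExpressionMatrix(
            expr.values.iloc[rng.permutation(expr.n_genes),
                             rng.permutation(expr.n_samples)],
            scale="linear",
        )
        perm = hclust_two_groups(shuffled, list(rng.permutation(panel)))
        assert (perm.loc[base.index] == base).all()

    def test_identical_samples_rejected(self):
        expr = _expr_from_points(np.ones((4, 3)))
        with pytest.raises(ValueError, match="identical"):
            hclust_two_groups(expr, list(expr.genes))


class TestTtestRank:
    def test_welch_matches_textbook_computation(self):
        # oracle: t = (m1-m2)/sqrt(v1/n1+v2/n2) for {1,2,3} vs {4,5,6}
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"],
                         columns=list("abcdef")),
            scale="log2",
        )
        labels = pd.Series([HIGH] * 3 + [LOW] * 3, index=list("abcdef"))
        table = ttest_rank(expr, labels)
        expected_t = (2.0 - 5.0) / np.sqrt(1.0 / 3 + 1.0 / 3)
        assert table.loc["g", "stat"] == pytest.approx(expected_t)
        assert table.loc["g", "mean_diff"] == pytest.approx(-3.0)

    def test_null_pvalues_uniform(self, null_cohort_frame):
        from scipy import stats

        rng = np.random.default_rng(5)
        lab = np.array([HIGH] * 15 + [LOW] * 15)
        rng.shuffle(lab)
        labels = pd.Series(lab, index=null_cohort_frame.samples)
        table = ttest_rank(null_cohort_frame, labels)
        ks = stats.kstest(table["pvalue"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_up_markers_rank_in_positive_tail(self, small_cohort):
        table = ttest_rank(small_cohort.expression, small_cohort.true_labels)
        targets = table[table.index.isin(set(small_cohort.myc_target_genes))]
        assert (targets["stat"] > 0).all()
        up_rows = table.loc[list(DEFAULT_PANEL.up_genes)]
        assert (up_rows["stat"] > 0).all() and (up_rows["qvalue"] < 0.05).all()

    def test_degenerate_gene_flagged_and_ranked_last(self):
        values = np.vstack([np.ones(6), [1, 2, 3, 6, 7, 9.0]])
        expr = ExpressionMatrix(pd.DataFrame(values, index=["flat", "ok"],
                                             columns=list("abcdef")), scale="log2")
        labels = pd.Series([HIGH] * 3 + [LOW] * 3, index=list("abcdef"))
        table = ttest_rank(expr, labels)
        assert table.loc["flat", "degenerate"]
        assert table.index[-1] == "flat"

    def test_wilcoxon_alternative_available(self, small_cohort):
        table = ttest_rank(small_cohort.expression, small_cohort.true_labels,
                           rank_metric="wilcoxon")
        up_rows = table.loc[list(DEFAULT_PANEL.up_genes)]
        assert (up_rows["stat"] > 0).all()


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals, expected",
        [([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
         ([0.005, 0.1], [0.01, 0.1]),
         ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])],
    )
    def test_step_up_closed_form(self, pvals, expected):
        assert np.allclose(bh_fdr(pvals), expected)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_step_up_oracle(self, pvals):
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPanelSelection:
    def test_recovers_planted_structure(self, small_cohort):
        table = ttest_rank(small_cohort.expression, small_cohort.true_labels)
        panel = select_marker_panel(table, small_cohort.myc_target_genes)
        assert panel.n_up == 10 and panel.n_down == 6
        # down-markers are the only genes elevated in MYC-low: exact recovery
        assert sorted(panel.down_genes) == sorted(DEFAULT_PANEL.down_genes)
        # all 239 targets share one effect size, so the top 10 is any target subset
        assert set(panel.up_genes) <= set(small_cohort.myc_target_genes)

    def test_insufficient_candidates_error_reports_counts(self, small_cohort):
        table = ttest_rank(small_cohort.expression, small_cohort.true_labels)
        with pytest.raises(ValueError, match="400"):
            select_marker_panel(table, small_cohort.myc_target_genes, n_up=400)

    def test_count_increased_targets(self, small_cohort):
        table = ttest_rank(small_cohort.expression, small_cohort.true_labels)
        n = count_increased(table, small_cohort.myc_target_genes)
        assert n == len(small_cohort.myc_target_genes)
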