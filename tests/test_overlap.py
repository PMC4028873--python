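"""Overlap tables, Fisher log-tail, sign concordance, pruning, clustering."""

import math

import numpy as np
import pytest

from meqtl.datatypes import GenotypeMatrix
from meqtl.overlap import (
    cluster_tstats,
    expected_same_sign,
    fisher_exact_log10,
    ld_prune,
    overlap_table,
    overlap_table_from_counts,
    pairwise_sign_concordance,
    partition_overlap,
    poisson_binomial_pmf,
    round_half_up,
    sign_concordance,
)
from meqtl.pipeline import render_overlap_report
from meqtl.scan import CisPair, MeqtlResult

from _oracles import hypergeom_upper_tail, same_sign_enumeration


def _res(snp, cpg, significant, t=2.0):
    return MeqtlResult(pair=CisPair(snp, cpg, 10), beta_hat=0.1, t=t, df=50,
                       p=0.01, p_holm=0.04 if significant else 0.9,
                       significant=significant, n_used=52)


class TestFisherLogTail:
    def test_small_table_matches_enumeration(self):
        for table in [(3, 1, 1, 3), (0, 5, 5, 0), (10, 0, 0, 10), (4, 6, 2, 8)]:
            expected = math.log10(float(hypergeom_upper_tail(*table)))
            assert fisher_exact_log10(*table) == pytest.approx(expected, abs=1e-9)

    def test_expectation_gives_unsurprising_tail(self):
        # margins 10/10 out of 20, E[a] = 5
        assert fisher_exact_log10(5, 5, 5, 5) >= math.log10(0.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_log10(-1, 2, 3, 4)

    def test_extreme_table_far_below_float_floor(self):
        lp = fisher_exact_log10(319, 405, 310, 528190)
        assert lp < -308
        assert np.isfinite(lp)


class TestOverlapTable:
    def _two_cohorts(self):
        pairs = [(f"rs{i}", f"cg{i}") for i in range(20)]
        a = [_res(s, c, significant=(i < 8)) for i, (s, c) in enumerate(pairs)]
        b = [_res(s, c, significant=(4 <= i < 14)) for i, (s, c) in enumerate(pairs)]
        return {"A": a, "B": b}

    def test_counts_shared_percent(self):
        table = overlap_table(self._two_cohorts(), universe_size=20)
        assert list(table.meqtl_counts) == [8, 10]
        assert table.shared[0, 1] == 4
        assert table.percent[0, 1] == pytest.approx(100 * 4 / 10)
        assert table.percent[1, 0] == pytest.approx(100 * 4 / 8)

    def test_identical_sets_full_overlap(self):
        pairs = [(f"rs{i}", f"cg{i}") for i in range(10)]
        res = {n: [_res(s, c, significant=(i < 5))
                   for i, (s, c) in enumerate(pairs)] for n in ("X", "Y")}
        table = overlap_table(res, universe_size=10)
        assert table.shared[0, 1] == 5
        assert table.percent[0, 1] == 100.0 and table.percent[1, 0] == 100.0

    def test_mismatched_universe_rejected(self):
        res = self._two_cohorts()
        res["B"] = res["B"][:-1]
        with pytest.raises(ValueError, match="universe"):
            overlap_table(res, universe_size=20)

    def test_report_cell_format(self):
        table = overlap_table_from_counts(
            ["PB", "CBA"], [724, 629], [[724, 319], [319, 629]],
            universe_size=529_224)
        text = render_overlap_report(table)
        assert "319 (50.7)" in text       # shared/629 column convention
        assert "319 (44.1)" in text       # shared/724 in the other direction
        assert text.splitlines()[1].split("\t")[2] == "-"


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (50.65, 50.7), (44.05, 44.1), (67.55, 67.6), (7.74, 7.7), (0.0, 0.0),
        (-2.25, -2.3),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_up(x, 1) == expected


class TestSignConcordance:
    def test_all_half_closed_form(self):
        assert expected_same_sign([0.5] * 7) == pytest.approx(2 * 0.5**7)

    def test_atleast_m_closed_form(self):
        # k=7, p=1/2, m=6: (2 + 14)/128
        assert expected_same_sign([0.5] * 7, m=6) == pytest.approx(16 / 128)

    def test_certain_sign(self):
        assert expected_same_sign([1.0] * 5) == pytest.approx(1.0)

    def test_matches_sign_vector_enumeration(self, rng):
        for k in range(2, 11):
            p = rng.uniform(0.2, 0.8, size=k)
            for m in (k, k - 1, max(2, k // 2)):
                assert expected_same_sign(p, m) == pytest.approx(
                    same_sign_enumeration(p, m), abs=1e-12)

    def test_equal_p_closed_form(self, rng):
        for _ in range(20):
            p = float(rng.uniform(0.05, 0.95))
            k = int(rng.integers(2, 9))
            assert expected_same_sign([p] * k) == pytest.approx(
                p**k + (1 - p) ** k)

    def test_pmf_sums_to_one(self, rng):
        pmf = poisson_binomial_pmf(rng.uniform(size=9))
        assert pmf.sum() == pytest.approx(1.0)

    def test_summary_on_constructed_matrix(self, rng):
        # 200 perfectly concordant rows + 200 independent-sign rows
        n, k = 200, 4
        concordant = np.abs(rng.normal(3, 1, size=(n, k)))
        signs = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
        concordant *= signs[:, None]
        independent = rng.normal(0, 3, size=(n, k))
        independent[independent == 0] = 1.0
        T = np.vstack([concordant, independent])
        s = sign_concordance(T, m=k)
        assert s.k == k and s.n_pairs == 2 * n
        assert s.observed_all_same > 0.5
        assert s.expected_all_same < 0.3
        assert s.binomial_log10p_all < -10

    def test_zero_t_rows_dropped(self):
        T = np.array([[1.0, 2.0], [0.0, 1.0], [-1.0, -3.0]])
        s = sign_concordance(T, m=2)
        assert s.n_dropped_zero == 1 and s.n_pairs == 2
        assert s.observed_all_same == 1.0

    def test_m_exceeding_k_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            sign_concordance(np.ones((5, 3)), m=4)

    def test_pairwise_concordance(self, rng):
        T = rng.normal(0, 2, size=(500, 3))
        T[T == 0] = 1.0
        obs, exp, lp = pairwise_sign_concordance(T, 0, 1)
        assert 0.3 < obs < 0.7 and 0.4 < exp < 0.6
        assert lp <= 0.0


class TestLdPrune:
    def _matrix(self, cols):
        values = np.column_stack(cols).astype(float)
        return GenotypeMatrix(samples=[f"s{i}" for i in range(values.shape[0])],
                              snps=[f"rs{j}" for j in range(values.shape[1])],
                              values=values)

    def test_independent_snps_all_retained(self, rng):
        cols = [rng.integers(0, 3, size=200).astype(float) for _ in range(20)]
        g = self._matrix(cols)
        # independence: with n=200 the sample r^2 stays below 0.05 w.h.p.
        retained = ld_prune(g, r2_max=0.05)
        assert len(retained) >= 18

    def test_duplicate_column_keeps_exactly_one(self, rng):
        col = rng.integers(0, 3, size=100).astype(float)
        g = self._matrix([col, col.copy()])
        assert ld_prune(g) == ["rs0"]

    def test_retained_set_passes_posthoc_check(self, rng):
        # blocks of correlated SNPs: copies with sparse flips
        base_cols = []
        for _ in range(20):
            col = rng.integers(0, 3, size=150).astype(float)
            for _ in range(5):
                c = col.copy()
                flip = rng.uniform(size=150) < 0.05
                c[flip] = rng.integers(0, 3, size=int(flip.sum()))
                base_cols.append(c)
        g = self._matrix(base_cols[:100])
        retained = ld_prune(g, window=50, step=5, r2_max=0.05)
        idx = [g.snps.index(s) for s in retained]
        for wstart in range(0, len(idx), 5):
            wi = [j for j in idx if wstart <= j < wstart + 50]
            for a in range(len(wi)):
                for b in range(a + 1, len(wi)):
                    r = np.corrcoef(g.values[:, wi[a]], g.values[:, wi[b]])[0, 1]
                    assert r * r <= 0.05 + 1e-12


class TestClusterTstats:
    def test_identical_columns_merge_first(self, rng):
        base = rng.normal(size=(50, 1))
        T = np.hstack([base, base, rng.normal(size=(50, 1)) * 5])
        clust = cluster_tstats(T, cluster_rows=False)
        first_merge = clust.cohort_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0)

    def test_row_permutation_invariance_of_cohort_tree(self, rng):
        T = rng.normal(size=(40, 4))
        perm = rng.permutation(40)
        a = cluster_tstats(T, cluster_rows=False)
        b = cluster_tstats(T[perm], cluster_rows=False)
        np.testing.assert_allclose(a.cohort_linkage[:, 2],
                                   b.cohort_linkage[:, 2], rtol=1e-12)

    def test_single_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_tstats(rng.normal(size=(10, 1)))

    def test_cohorts_cluster_by_ancestry_group(self):
        """With two allele-frequency/LD regimes, the same-regime cohorts
        merge before any cross-regime merge in nearly every replicate."""
        from meqtl.pipeline import qc_cohort, restrict_to_common_universe, tstat_matrix
        from meqtl.scan import scan_cohort
        from meqtl.simulate import SimConfig, simulate_study

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(n_cohorts=4, n_samples=90, n_snps=400, n_cpgs=100,
                            chrom_length=1_500_000, n_planted=30,
                            ancestry=[0, 0, 1, 1], ld_block_len=[3, 3, 10, 10],
                            n_batches=1, outlier_fraction=0.0,
                            effect_sharing=np.ones((30, 4), dtype=int),
                            seed=100 + seed)
            cohorts, _ = simulate_study(cfg)
            results = {ds.name: scan_cohort(qc_cohort(ds), min_df=20)
                       for ds in cohorts}
            common, _ = restrict_to_common_universe(results)
            T, _, names = tstat_matrix(common)
            clust = cluster_tstats(np.where(np.isnan(T), 0.0, T),
                                   cluster_rows=False)
            a, b = int(clust.cohort_linkage[0, 0]), int(clust.cohort_linkage[0, 1])
            if {a, b} in ({0, 1}, {2, 3}):
                wins += 1
        assert wins >= 0.9 * n_seeds


class TestPartitionOverlap:
    def test_same_tissue_same_half_full_overlap(self, small_study):
        cohorts, _ = small_study
        from meqtl.pipeline import qc_cohort

        ds = qc_cohort(cohorts[1])
        po = partition_overlap(ds, ds, seed=5, min_df=10)
        n1, n2, shared, _ = po.comparisons["A-vs-A"]
        assert n1 == n2 == shared

    def test_shared_effects_overlap_across_disjoint_halves(self, small_study):
        cohorts, _ = small_study
        from meqtl.pipeline import qc_cohort

        ds = qc_cohort(cohorts[1])
        po = partition_overlap(ds, ds, seed=5, min_df=10)
        n1, n2, shared, lp = po.comparisons["A-vs-B"]
        assert shared >= 1
        assert lp < np.log10(0.05)

    def test_too_few_subjects_rejected(self, small_study):
        cohorts, _ = small_study
        from meqtl.pipeline import subset_cohort

        tiny = subset_cohort(cohorts[0], cohorts[0].samples[:6])
        with pytest.raises(ValueError, match="8"):
            partition_overlap(tiny, tiny, seed=1)
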