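"""Statistical contracts of the synthetic multi-cohort generator."""

import numpy as np
import pytest
from scipy import stats

from meqtl.qc import hwe_exact_test, pca_outlier_removal
from meqtl.scan import build_cis_pairs, fit_pair, holm_adjust
from meqtl.simulate import (
    SimConfig,
    simulate_annotations,
    simulate_genotypes,
    simulate_methylation,
    simulate_study,
    simulate_truth,
)


class TestDeterminism:
    def test_identical_config_identical_study(self):
        cfg = SimConfig(n_cohorts=2, n_samples=30, n_snps=100, n_cpgs=30,
                        chrom_length=500_000, n_planted=5, seed=42)
        a_cohorts, a_truth = simulate_study(cfg)
        b_cohorts, b_truth = simulate_study(SimConfig(
            n_cohorts=2, n_samples=30, n_snps=100, n_cpgs=30,
            chrom_length=500_000, n_planted=5, seed=42))
        assert a_truth.planted == b_truth.planted
        for a, b in zip(a_cohorts, b_cohorts):
            np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
            np.testing.assert_array_equal(a.methylation.beta, b.methylation.beta)

    def test_seed_changes_output(self):
        cfg1 = SimConfig(n_cohorts=1, n_samples=20, n_snps=50, n_cpgs=10,
                         chrom_length=200_000, n_planted=0, seed=1)
        cfg2 = SimConfig(n_cohorts=1, n_samples=20, n_snps=50, n_cpgs=10,
                         chrom_length=200_000, n_planted=0, seed=2)
        g1, _ = simulate_genotypes(cfg1, 0)
        g2, _ = simulate_genotypes(cfg2, 0)
        assert not np.array_equal(g1.values, g2.values)


class TestGenotypes:
    def test_empirical_maf_near_target(self):
        cfg = SimConfig(n_cohorts=1, n_samples=10_000, n_snps=30, n_cpgs=5,
                        chrom_length=300_000, maf_range=(0.3, 0.3),
                        ld_block_len=1, n_planted=0, seed=5)
        g, _ = simulate_genotypes(cfg, 0)
        freq_alt = 1.0 - g.values.mean(axis=0) / 2.0
        assert (np.abs(freq_alt - 0.3) < 0.02).all()

    def test_blocksize_one_gives_independent_snps(self):
        cfg = SimConfig(n_cohorts=1, n_samples=400, n_snps=100, n_cpgs=5,
                        chrom_length=1_000_000, ld_block_len=1,
                        maf_range=(0.2, 0.4), n_planted=0, seed=6)
        g, _ = simulate_genotypes(cfg, 0)
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(100):
            i, j = rng.choice(100, size=2, replace=False)
            rs.append(abs(np.corrcoef(g.values[:, i], g.values[:, j])[0, 1]))
        assert np.mean(rs) < 3 / np.sqrt(400)

    def test_ld_blocks_give_adjacent_correlation(self):
        cfg = SimConfig(n_cohorts=1, n_samples=500, n_snps=100, n_cpgs=5,
                        chrom_length=1_000_000, ld_block_len=10,
                        maf_range=(0.2, 0.4), n_planted=0, seed=6)
        g, _ = simulate_genotypes(cfg, 0)
        within = []
        for j in range(0, 90, 10):
            within.append(np.corrcoef(g.values[:, j], g.values[:, j + 1])[0, 1] ** 2)
        assert np.mean(within) > 0.3

    def test_marginal_hwe_holds(self):
        cfg = SimConfig(n_cohorts=1, n_samples=200, n_snps=300, n_cpgs=5,
                        chrom_length=1_500_000, ld_block_len=6,
                        n_planted=0, seed=8)
        g, _ = simulate_genotypes(cfg, 0)
        fails = 0
        for j in range(300):
            col = g.values[:, j]
            p = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                               int((col == 0).sum()))
            fails += p <= 0.00001
        assert fails / 300 <= 0.01

    def test_block_longer_than_panel_rejected(self):
        with pytest.raises(ValueError, match="ld_block_len"):
            SimConfig(n_cohorts=1, n_snps=5, ld_block_len=10)


class TestMethylation:
    def test_null_type_one_error_calibrated(self):
        # effect 0: per-pair regression p-values are uniform
        cfg = SimConfig(n_cohorts=1, n_samples=90, n_snps=500, n_cpgs=120,
                        chrom_length=1_200_000, n_planted=0,
                        outlier_fraction=0.0, n_batches=1,
                        detection_fail_rate=0.0, seed=9)
        cohorts, truth = simulate_study(cfg)
        ds = cohorts[0]
        pairs = build_cis_pairs(ds.snp_ann, ds.cpg_ann)
        assert len(pairs) >= 2000
        snp_col = {s: j for j, s in enumerate(ds.genotypes.snps)}
        cpg_col = {c: j for j, c in enumerate(ds.methylation.cpgs)}
        hits = 0
        n = 0
        for pair in pairs[:2500]:
            res = fit_pair(ds.methylation.beta[:, cpg_col[pair.cpg_id]],
                           ds.genotypes.values[:, snp_col[pair.snp_id]])
            n += 1
            hits += res.p < 0.05
        frac = hits / n
        lo, hi = stats.binom.interval(0.999, n, 0.05)
        # LD makes pairs dependent; the CI is indicative, widened slightly
        assert lo / n - 0.02 < frac < hi / n + 0.02

    def test_outlier_free_config_flags_nothing(self):
        cfg = SimConfig(n_cohorts=1, n_samples=60, n_snps=100, n_cpgs=60,
                        chrom_length=500_000, n_planted=0,
                        outlier_fraction=0.0, seed=10)
        cohorts, _ = simulate_study(cfg)
        _, flagged = pca_outlier_removal(cohorts[0].methylation)
        assert flagged == []

    def test_planted_outliers_flagged(self):
        cfg = SimConfig(n_cohorts=1, n_samples=60, n_snps=100, n_cpgs=60,
                        chrom_length=500_000, n_planted=0,
                        outlier_fraction=0.05, seed=10)
        cohorts, _ = simulate_study(cfg)
        _, flagged = pca_outlier_removal(cohorts[0].methylation)
        assert len(flagged) == 3

    def test_planted_snp_must_exist(self):
        cfg = SimConfig(n_cohorts=1, n_samples=20, n_snps=50, n_cpgs=10,
                        chrom_length=200_000, n_planted=2, seed=11)
        snp_ann, cpg_ann = simulate_annotations(cfg)
        g, _ = simulate_genotypes(cfg, 0, snp_ann)
        truth = simulate_truth(cfg, snp_ann, cpg_ann)
        bad = type(truth)(planted=[
            type(truth.planted[0])(snp_id="rs_missing", cpg_id="cg000001",
                                   sharing=(1,), sign=1)])
        with pytest.raises(ValueError, match="rs_missing"):
            simulate_methylation(cfg, g, bad, 0, cpg_ann)


class TestStudyStructure:
    def test_planted_pairs_within_cis_window(self):
        cfg = SimConfig(n_cohorts=2, n_samples=30, n_snps=200, n_cpgs=60,
                        chrom_length=1_000_000, n_planted=20, seed=12)
        snp_ann, cpg_ann = simulate_annotations(cfg)
        truth = simulate_truth(cfg, snp_ann, cpg_ann)
        spos = {a.snp_id: a.pos for a in snp_ann}
        cpos = {a.cpg_id: a.pos for a in cpg_ann}
        for e in truth.planted:
            assert abs(spos[e.snp_id] - cpos[e.cpg_id]) <= 50_000

    def test_effect_sharing_shape_validated(self):
        with pytest.raises(ValueError, match="effect_sharing"):
            SimConfig(n_cohorts=2, n_planted=5,
                      effect_sharing=np.ones((4, 2)))

    def test_cohorts_share_annotations(self, small_study):
        cohorts, _ = small_study
        assert cohorts[0].snp_ann == cohorts[1].snp_ann == cohorts[2].snp_ann
        assert cohorts[0].cpg_ann == cohorts[2].cpg_ann

    def test_identity_sharing_confines_effects(self):
        """Private effects are detected in their own cohort, not in others."""
        n_planted = 12
        sharing = np.zeros((n_planted, 2), dtype=int)
        sharing[:6, 0] = 1
        sharing[6:, 1] = 1
        cfg = SimConfig(n_cohorts=2, n_samples=100, n_snps=400, n_cpgs=120,
                        chrom_length=1_500_000, n_planted=n_planted,
                        effect_sharing=sharing, ld_block_len=1,
                        outlier_fraction=0.0, n_batches=1, seed=13)
        cohorts, truth = simulate_study(cfg)
        for c_idx in (0, 1):
            ds = cohorts[c_idx]
            snp_col = {s: j for j, s in enumerate(ds.genotypes.snps)}
            cpg_col = {c: j for j, c in enumerate(ds.methylation.cpgs)}
            pvals, owned = [], []
            for e in truth.planted:
                res = fit_pair(ds.methylation.beta[:, cpg_col[e.cpg_id]],
                               ds.genotypes.values[:, snp_col[e.snp_id]])
                pvals.append(res.p)
                owned.append(bool(e.sharing[c_idx]))
            pvals = np.array(pvals)
            owned = np.array(owned)
            # own effects: overwhelming evidence; foreign effects: null
            assert (pvals[owned] < 1e-4).mean() > 0.5
            assert (pvals[~owned] < 1e-4).sum() == 0

    def test_ancestry_groups_share_allele_frequencies(self):
        cfg = SimConfig(n_cohorts=3, n_samples=2000, n_snps=60, n_cpgs=10,
                        chrom_length=400_000, ancestry=[0, 0, 1],
                        ld_block_len=1, n_planted=0, seed=14)
        gs = [simulate_genotypes(cfg, i)[0] for i in range(3)]
        f = [1.0 - g.values.mean(axis=0) / 2.0 for g in gs]
        same = np.abs(f[0] - f[1]).mean()
        diff = np.abs(f[0] - f[2]).mean()
        assert same < 0.02 < diff


def test_holm_on_null_study_rarely_fires():
    """Family-wise error of the scan on a fully null cohort stays near 5%."""
    cfg = SimConfig(n_cohorts=1, n_samples=90, n_snps=300, n_cpgs=80,
                    chrom_length=900_000, n_planted=0, outlier_fraction=0.0,
                    n_batches=1, detection_fail_rate=0.0, seed=15)
    cohorts, _ = simulate_study(cfg)
    ds = cohorts[0]
    pairs = build_cis_pairs(ds.snp_ann, ds.cpg_ann)
    snp_col = {s: j for j, s in enumerate(ds.genotypes.snps)}
    cpg_col = {c: j for j, c in enumerate(ds.methylation.cpgs)}
    ps = [fit_pair(ds.methylation.beta[:, cpg_col[p.cpg_id]],
                   ds.genotypes.values[:, snp_col[p.snp_id]]).p
          for p in pairs]
    assert (holm_adjust(ps) < 0.05).sum() == 0
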