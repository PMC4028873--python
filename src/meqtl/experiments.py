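"""Simulation studies exercising the pipeline's statistical guarantees.

Each function runs one self-contained computer experiment on synthetic
data — family-wise error under the complete null, recovery of planted
cis effects, β- vs M-scale agreement, calibration of the empirical
enrichment p-value — and returns plain numbers. The analysis drivers,
the test suite and the results-reproduction script all call these, so
the numbers they report are always recomputed, never stored.

Problem sizes default to desk scale: one synthetic chromosome, a few
hundred SNPs/CpGs and cohort sizes matching the seven-cohort study
design (87–125 subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import enrichment_test
from .pipeline import qc_cohort
from .scan import FilteredPair, build_cis_pairs, fit_pair, holm_adjust, scan_cohort
from .simulate import SimConfig, simulate_study


def _null_cfg(seed: int, n_samples: int) -> SimConfig:
    return SimConfig(
        n_cohorts=1, n_samples=n_samples, n_snps=400, n_cpgs=120,
        chrom_length=1_200_000, n_planted=0, outlier_fraction=0.0,
        n_batches=1, detection_fail_rate=0.0, seed=seed,
    )


def null_scan_significant_count(seed: int, n_pairs: int = 2000,
                                n_samples: int = 90) -> int:
    """Holm-significant pair count in a fully null cohort.

    Simulates a cohort with no planted effects, tests the first
    ``n_pairs`` cis pairs and Holm-adjusts over exactly that family.
    Holm guarantees the probability of any return value > 0 is at most
    the nominal 5% (less under the positive dependence LD induces).
    """
    cohorts, _ = simulate_study(_null_cfg(seed, n_samples))
    ds = cohorts[0]
    pairs = build_cis_pairs(ds.snp_ann, ds.cpg_ann)
    if len(pairs) < n_pairs:
        raise ValueError(f"only {len(pairs)} cis pairs available, need {n_pairs}")
    snp_col = {s: j for j, s in enumerate(ds.genotypes.snps)}
    cpg_col = {c: j for j, c in enumerate(ds.methylation.cpgs)}
    ps = []
    for pair in pairs[:n_pairs]:
        res = fit_pair(ds.methylation.beta[:, cpg_col[pair.cpg_id]],
                       ds.genotypes.values[:, snp_col[pair.snp_id]],
                       min_df=30)
        if isinstance(res, FilteredPair):   # e.g. a monomorphic draw
            continue
        ps.append(res.p)
    return int((holm_adjust(ps) < 0.05).sum())


def fwer_over_seeds(base_seed: int, n_seeds: int = 100,
                    n_pairs: int = 2000, n_samples: int = 90) -> float:
    """Fraction of independent null studies with zero Holm discoveries."""
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s) for s in
             ss.generate_state(n_seeds, dtype=np.uint32) % (2**31)]
    clean = sum(
        null_scan_significant_count(s, n_pairs, n_samples) == 0
        for s in seeds)
    return clean / n_seeds


@dataclass
class RecoveryResult:
    n_planted: int
    n_tested: int
    mean_slope: float        # sign-aligned, so truth is +effect_size
    effect_size: float
    holm_power: float        # fraction of tested planted pairs significant


def _planted_cfg(seed: int, n_samples: int, n_planted: int,
                 effect_size: float, noise_sd: float) -> SimConfig:
    return SimConfig(
        n_cohorts=1, n_samples=n_samples, n_snps=1500, n_cpgs=2 * n_planted,
        chrom_length=5_000_000, n_planted=n_planted, effect_size=effect_size,
        noise_sd=noise_sd, outlier_fraction=0.0, n_batches=1, seed=seed,
    )


def planted_recovery(seed: int, n_planted: int = 200, n_samples: int = 100,
                     effect_size: float = 0.1, noise_sd: float = 0.3,
                     ) -> RecoveryResult:
    """Slope recovery and Holm power for planted Δβ-per-allele effects.

    One cohort passes the full QC cascade and scan; planted pairs that
    survive QC are compared against the known effect size (slopes are
    sign-aligned before averaging).
    """
    cfg = _planted_cfg(seed, n_samples, n_planted, effect_size, noise_sd)
    cohorts, truth = simulate_study(cfg)
    ds = qc_cohort(cohorts[0])
    results = scan_cohort(ds, min_df=30)
    by_key = {(r.pair.snp_id, r.pair.cpg_id): r for r in results}
    slopes, sig = [], 0
    for e in truth.planted:
        r = by_key.get((e.snp_id, e.cpg_id))
        if r is None:
            continue
        slopes.append(r.beta_hat * e.sign)
        sig += r.significant
    if not slopes:
        raise ValueError("no planted pairs survived QC")
    return RecoveryResult(
        n_planted=n_planted, n_tested=len(slopes),
        mean_slope=float(np.mean(slopes)), effect_size=effect_size,
        holm_power=sig / len(slopes))


def mvalue_tstat_correlation(seed: int, n_planted: int = 120,
                             n_samples: int = 100) -> tuple[float, int]:
    """Pearson r between β-scale and M-scale t-statistics.

    Computed over the pairs Holm-significant on the β scale, mirroring
    the check that the two response scales identify the same signals.
    Returns (correlation, number of pairs correlated).
    """
    cfg = _planted_cfg(seed, n_samples, n_planted, 0.1, 0.3)
    cohorts, _ = simulate_study(cfg)
    ds = qc_cohort(cohorts[0])
    res_beta = scan_cohort(ds, min_df=30, scale="beta")
    res_m = scan_cohort(ds, min_df=30, scale="mvalue")
    t_beta = {(r.pair.snp_id, r.pair.cpg_id): r.t
              for r in res_beta if r.significant}
    t_m = {(r.pair.snp_id, r.pair.cpg_id): r.t for r in res_m}
    keys = sorted(t_beta.keys() & t_m.keys())
    if len(keys) < 3:
        raise ValueError("too few Holm-significant pairs to correlate")
    r = float(np.corrcoef([t_beta[k] for k in keys],
                          [t_m[k] for k in keys])[0, 1])
    return r, len(keys)


def enrichment_null_pvalues(seed: int, n_replicates: int = 200,
                            n_resamples: int = 1000, universe_size: int = 2000,
                            set_size: int = 100, target_size: int = 400,
                            ) -> np.ndarray:
    """Empirical enrichment p-values when the meQTL set is itself random.

    Each replicate draws a uniformly random "meQTL" set from the universe
    (so its MAF profile is exchangeable with the matched resamples) and a
    fixed random target set; under this null the empirical p-value should
    be uniform on {0, 1/N, ..., 1} up to resampling noise.
    """
    rng = np.random.default_rng(seed)
    snps = [f"rs{i:05d}" for i in range(universe_size)]
    universe = dict(zip(snps, rng.uniform(0.05, 0.5, size=universe_size)))
    target = set(rng.choice(snps, size=target_size, replace=False))
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        meqtls = set(rng.choice(snps, size=set_size, replace=False))
        res = enrichment_test(meqtls, target, universe, n_resamples, rng)
        ps[i] = res.empirical_p
    return ps
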