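"""Synthetic multi-cohort genotype + methylation study generator.

The generator emulates the statistical structure of a seven-cohort
meQTL study varying by ancestry, developmental stage and tissue:

* cohorts share SNP and CpG positions (one synthetic chromosome) but
  have ancestry-group-specific allele frequencies and LD block lengths —
  shorter blocks for the African-American-like cohorts, which is what
  drives their lower power to tag causal variants;
* LD is produced by a copy-with-refresh haplotype chain within blocks:
  each haplotype carries a latent uniform that is refreshed with a fixed
  probability per SNP, so adjacent-SNP r² decays with distance while
  marginal allele frequencies and Hardy–Weinberg proportions are exact
  (the two haplotypes are independent);
* methylation β-values are logit-normal per CpG with cohort-specific
  baselines; planted cis effects (within 50 kb) add Δβ per reference
  allele on the β scale before clamping to [0.01, 0.99]; effects can be
  shared by all cohorts, by a subset, or private to one cohort;
* hybridization batch offsets, PCA-detectable global-shift outlier
  samples, and detection-p failures complete the nuisance structure.

Everything is a pure function of the :class:`SimConfig`, including its
seed: identical configs give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datatypes import (
    CohortDataset,
    CovariateTable,
    CpgAnnotation,
    GenotypeMatrix,
    MethylationMatrix,
    SnpAnnotation,
)

CIS_WINDOW_BP = 50_000
BETA_CLAMP = (0.01, 0.99)
_PLANTED_BASELINE_SD = 0.5   # keeps planted CpGs mid-range; see docs
_BACKGROUND_BASELINE_SD = 0.8
_COHORT_BASELINE_SD = 0.3
_OUTLIER_SHIFT = 0.25        # global beta-scale shift, >> 10 SD on PC1
_PROBE_HALF_LEN = 25


def _per_cohort(value, n: int, name: str) -> list:
    """Broadcast a scalar setting to all cohorts, or validate a list."""
    if isinstance(value, (list, tuple)) and not (
            name == "maf_range" and len(value) == 2
            and all(isinstance(v, (int, float)) for v in value)):
        if len(value) != n:
            raise ValueError(f"{name}: expected {n} per-cohort values, got {len(value)}")
        return list(value)
    return [value] * n


# the default seven-cohort study: two African-American-like cohorts (adult
# peripheral blood, neonate cord blood) with short LD blocks, one Caucasian
# cord-blood cohort, and four Caucasian adult brain-region cohorts scanned
# in hybridization batches with PCA-detectable outliers
_DEFAULT_N = [90, 87, 87, 111, 125, 105, 106]
_DEFAULT_BLOCKS = [4, 4, 10, 10, 10, 10, 10]
_DEFAULT_BATCHES = [1, 1, 1, 3, 3, 3, 3]
# one-pass detection with a 2.5-SD cut needs the outlier block to stay a
# modest minority (the cutoff scales with the outliers' own spread), so the
# default fractions stay at or below ~10% of a cohort
_DEFAULT_OUTLIERS = [0.0, 0.0, 0.0, 0.10, 0.04, 0.05, 0.08]
_DEFAULT_NAMES = ["PB", "CBA", "CBB", "FCTX", "TCTX", "CRBLM", "PONS"]


def _default_per_cohort(defaults: list, k: int, fallback) -> list:
    if k <= len(defaults):
        return defaults[:k]
    return defaults + [fallback] * (k - len(defaults))


@dataclass
class SimConfig:
    n_cohorts: int = 7
    n_samples: int | list | None = None
    n_snps: int = 1000
    n_cpgs: int = 250
    chrom_length: int = 5_000_000
    maf_range: tuple | list = (0.05, 0.5)
    ld_block_len: int | list | None = None
    ld_refresh_prob: float = 0.1
    n_planted: int = 60
    effect_size: float = 0.1
    effect_sharing: np.ndarray | None = None  # (n_planted, n_cohorts) of 0/1
    noise_sd: float = 0.3
    batch_effect_sd: float = 0.02
    n_batches: int | list | None = None
    outlier_fraction: float | list | None = None
    detection_fail_rate: float = 0.005
    ancestry: list | None = None   # group index per cohort; same group =>
    # same per-SNP allele frequencies
    cohort_names: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_cohorts
        if self.n_samples is None:
            self.n_samples = _default_per_cohort(_DEFAULT_N, k, 100)
        if self.ld_block_len is None:
            self.ld_block_len = _default_per_cohort(_DEFAULT_BLOCKS, k, 10)
        if self.n_batches is None:
            self.n_batches = _default_per_cohort(_DEFAULT_BATCHES, k, 1)
        if self.outlier_fraction is None:
            self.outlier_fraction = _default_per_cohort(_DEFAULT_OUTLIERS, k, 0.0)
        self.n_samples = [int(v) for v in _per_cohort(self.n_samples, k, "n_samples")]
        self.ld_block_len = [int(v) for v in
                             _per_cohort(self.ld_block_len, k, "ld_block_len")]
        self.n_batches = [int(v) for v in _per_cohort(self.n_batches, k, "n_batches")]
        self.outlier_fraction = [float(v) for v in
                                 _per_cohort(self.outlier_fraction, k, "outlier_fraction")]
        self.maf_range = [tuple(v) for v in _per_cohort(self.maf_range, k, "maf_range")]
        for lo, hi in self.maf_range:
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError(f"maf_range ({lo}, {hi}) must satisfy 0 < lo <= hi <= 0.5")
        for b in self.ld_block_len:
            if self.n_snps < b:
                raise ValueError(f"n_snps {self.n_snps} < ld_block_len {b}")
        if self.ancestry is None:
            # default study: cohorts 0-1 one ancestral group, the rest another
            self.ancestry = ([0, 0] + [1] * (k - 2)) if k >= 3 else [0] * k
        if len(self.ancestry) != k:
            raise ValueError("ancestry must list one group per cohort")
        if self.cohort_names is None:
            self.cohort_names = (_DEFAULT_NAMES[:k] if k <= 7
                                 else [f"cohort{i}" for i in range(k)])
        if len(self.cohort_names) != k:
            raise ValueError("cohort_names must list one name per cohort")
        if self.effect_sharing is not None:
            self.effect_sharing = np.asarray(self.effect_sharing, dtype=int)
            if self.effect_sharing.shape != (self.n_planted, k):
                raise ValueError(
                    f"effect_sharing must be ({self.n_planted}, {k}), "
                    f"got {self.effect_sharing.shape}")


@dataclass(frozen=True)
class PlantedEffect:
    snp_id: str
    cpg_id: str
    sharing: tuple          # 0/1 per cohort
    sign: int               # effect direction, same in every carrying cohort


@dataclass
class SimTruth:
    planted: list[PlantedEffect]

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.snp_id, e.cpg_id) for e in self.planted}


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


# ---------------------------------------------------------------------------
# shared annotations
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig) -> tuple[list[SnpAnnotation], list[CpgAnnotation]]:
    """SNP and CpG positions shared by every cohort (one chromosome)."""
    rng = _rng(cfg, 0)
    lo = _PROBE_HALF_LEN + 1
    snp_pos = np.sort(rng.choice(
        np.arange(lo, cfg.chrom_length - lo), size=cfg.n_snps, replace=False))
    cpg_pos = np.sort(rng.choice(
        np.arange(lo, cfg.chrom_length - lo), size=cfg.n_cpgs, replace=False))
    bases = np.array(list("ACGT"))
    snp_ann = []
    for i, pos in enumerate(snp_pos):
        ref, alt = rng.choice(bases, size=2, replace=False)
        snp_ann.append(SnpAnnotation(snp_id=f"rs{i:06d}", chrom="chr1",
                                     pos=int(pos), ref_allele=str(ref),
                                     alt_allele=str(alt)))
    cpg_ann = [
        CpgAnnotation(cpg_id=f"cg{i:06d}", chrom="chr1", pos=int(pos),
                      probe_start=int(pos) - _PROBE_HALF_LEN,
                      probe_end=int(pos) + _PROBE_HALF_LEN - 1)
        for i, pos in enumerate(cpg_pos)
    ]
    return snp_ann, cpg_ann


def simulate_truth(cfg: SimConfig,
                   snp_ann: list[SnpAnnotation] | None = None,
                   cpg_ann: list[CpgAnnotation] | None = None) -> SimTruth:
    """Plant cis effects: distinct SNP–CpG pairs within the cis window.

    Sharing defaults to a three-way mixture: one third of effects carried
    by every cohort, one third by a contiguous subset (the brain-like
    cohorts in the default study), one third private to a single cohort.
    """
    if snp_ann is None or cpg_ann is None:
        snp_ann, cpg_ann = simulate_annotations(cfg)
    rng = _rng(cfg, 2)
    snp_pos = np.array([s.pos for s in snp_ann])
    k = cfg.n_cohorts
    if cfg.effect_sharing is not None:
        sharing_rows = [tuple(row) for row in cfg.effect_sharing]
    else:
        sharing_rows = []
        subset = tuple(1 if i >= max(0, k - 4) else 0 for i in range(k))
        for i in range(cfg.n_planted):
            kind = i % 3
            if kind == 0 or k == 1:
                sharing_rows.append(tuple([1] * k))
            elif kind == 1:
                sharing_rows.append(subset if any(subset) else tuple([1] * k))
            else:
                owner = int(rng.integers(k))
                sharing_rows.append(tuple(1 if j == owner else 0 for j in range(k)))
    planted: list[PlantedEffect] = []
    used_pairs: set[tuple[str, str]] = set()
    used_cpgs: set[str] = set()
    attempts = 0
    while len(planted) < cfg.n_planted:
        attempts += 1
        if attempts > 100 * cfg.n_planted:
            raise ValueError("could not place planted effects within the cis window; "
                             "increase SNP density or chromosome length")
        cpg = cpg_ann[int(rng.integers(len(cpg_ann)))]
        if cpg.cpg_id in used_cpgs:   # one planted effect per CpG keeps
            continue                  # per-pair power interpretable
        lo = np.searchsorted(snp_pos, cpg.pos - CIS_WINDOW_BP, side="left")
        hi = np.searchsorted(snp_pos, cpg.pos + CIS_WINDOW_BP, side="right")
        if hi == lo:
            continue
        snp = snp_ann[int(rng.integers(lo, hi))]
        if (snp.snp_id, cpg.cpg_id) in used_pairs:
            continue
        used_pairs.add((snp.snp_id, cpg.cpg_id))
        used_cpgs.add(cpg.cpg_id)
        planted.append(PlantedEffect(
            snp_id=snp.snp_id, cpg_id=cpg.cpg_id,
            sharing=sharing_rows[len(planted)],
            sign=int(rng.choice([-1, 1]))))
    return SimTruth(planted=planted)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig, cohort: int,
                       snp_ann: list[SnpAnnotation] | None = None
                       ) -> tuple[GenotypeMatrix, list[SnpAnnotation]]:
    """One cohort's genotypes: block-structured LD, exact marginal HWE.

    Per-SNP minor allele frequencies are drawn once per *ancestry group*
    (uniform over the cohort's ``maf_range``), so cohorts in the same
    group share allele frequencies. Each haplotype carries a latent
    uniform that restarts at block boundaries and is refreshed with
    probability ``ld_refresh_prob`` per SNP inside a block; the allele is
    the indicator that the latent falls below the alt-allele frequency.
    """
    if snp_ann is None:
        snp_ann, _ = simulate_annotations(cfg)
    n = cfg.n_samples[cohort]
    block = cfg.ld_block_len[cohort]
    lo, hi = cfg.maf_range[cohort]
    group = cfg.ancestry[cohort]
    maf = _rng(cfg, 50, group).uniform(lo, hi, size=cfg.n_snps)

    rng = _rng(cfg, 100, cohort)
    n_hap = 2 * n
    fresh = rng.uniform(size=(n_hap, cfg.n_snps))
    refresh = rng.uniform(size=(n_hap, cfg.n_snps)) < cfg.ld_refresh_prob
    u = np.empty_like(fresh)
    u[:, 0] = fresh[:, 0]
    for j in range(1, cfg.n_snps):
        if j % block == 0:   # block boundary: chain restarts
            u[:, j] = fresh[:, j]
        else:
            u[:, j] = np.where(refresh[:, j], fresh[:, j], u[:, j - 1])
    alt = (u < maf[None, :]).astype(np.int8)     # alt allele indicator
    dosage = 2.0 - (alt[0::2] + alt[1::2])       # count of reference alleles
    g = GenotypeMatrix(
        samples=[f"{cfg.cohort_names[cohort]}_s{i:03d}" for i in range(n)],
        snps=[a.snp_id for a in snp_ann],
        values=dosage.astype(float),
    )
    return g, snp_ann


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_batches(cfg: SimConfig, cohort: int) -> np.ndarray:
    """Hybridization batch assignment (0..n_batches-1) per sample."""
    n = cfg.n_samples[cohort]
    n_batches = cfg.n_batches[cohort]
    return _rng(cfg, 300, cohort).integers(n_batches, size=n)


def simulate_methylation(cfg: SimConfig, genotypes: GenotypeMatrix,
                         truth: SimTruth, cohort: int,
                         cpg_ann: list[CpgAnnotation] | None = None
                         ) -> MethylationMatrix:
    """One cohort's β-values with planted effects and nuisance structure."""
    if cpg_ann is None:
        _, cpg_ann = simulate_annotations(cfg)
    n = cfg.n_samples[cohort]
    cpg_ids = [a.cpg_id for a in cpg_ann]
    cpg_col = {c: j for j, c in enumerate(cpg_ids)}
    snp_col = {s: j for j, s in enumerate(genotypes.snps)}
    for e in truth.planted:
        if e.snp_id not in snp_col:
            raise ValueError(f"planted SNP {e.snp_id} not in the genotype matrix")

    planted_cpgs = {e.cpg_id for e in truth.planted}
    rng = _rng(cfg, 200, cohort)
    mu0 = rng.normal(0.0, _COHORT_BASELINE_SD)
    baseline_sd = np.array([
        _PLANTED_BASELINE_SD if c in planted_cpgs else _BACKGROUND_BASELINE_SD
        for c in cpg_ids])
    mu = mu0 + rng.normal(0.0, 1.0, size=len(cpg_ids)) * baseline_sd
    latent = mu[None, :] + rng.normal(0.0, cfg.noise_sd, size=(n, len(cpg_ids)))
    beta = expit(latent)

    for e in truth.planted:
        if not e.sharing[cohort]:
            continue
        dosage = genotypes.values[:, snp_col[e.snp_id]]
        beta[:, cpg_col[e.cpg_id]] += e.sign * cfg.effect_size * dosage

    batches = simulate_batches(cfg, cohort)
    n_batches = cfg.n_batches[cohort]
    if n_batches > 1 and cfg.batch_effect_sd > 0:
        offsets = rng.normal(0.0, cfg.batch_effect_sd,
                             size=(n_batches, len(cpg_ids)))
        beta += offsets[batches]

    n_out = int(round(cfg.outlier_fraction[cohort] * n))
    if n_out:
        outliers = rng.choice(n, size=n_out, replace=False)
        # random direction per outlier: a coherent same-direction block
        # would form its own cluster and inflate the detection cutoff
        signs = rng.choice([-1.0, 1.0], size=n_out)
        beta[outliers] += signs[:, None] * _OUTLIER_SHIFT

    beta = np.clip(beta, *BETA_CLAMP)

    detp = rng.uniform(0.0, 1e-4, size=beta.shape)
    fails = rng.uniform(size=beta.shape) < cfg.detection_fail_rate
    detp[fails] = rng.uniform(0.0012, 0.05, size=int(fails.sum()))
    intensity = rng.normal(4000.0, 200.0, size=n)
    return MethylationMatrix(samples=list(genotypes.samples), cpgs=cpg_ids,
                             beta=beta, detection_p=detp, intensity=intensity)


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> tuple[list[CohortDataset], SimTruth]:
    """All cohorts over shared annotations, plus the planting ground truth."""
    snp_ann, cpg_ann = simulate_annotations(cfg)
    truth = simulate_truth(cfg, snp_ann, cpg_ann)
    cohorts: list[CohortDataset] = []
    for i in range(cfg.n_cohorts):
        g, _ = simulate_genotypes(cfg, i, snp_ann)
        m = simulate_methylation(cfg, g, truth, i, cpg_ann)
        batches = simulate_batches(cfg, i)
        columns = {
            f"batch{b}": (batches == b).astype(float)
            for b in range(1, cfg.n_batches[i])   # indicator coding, batch 0 ref
        }
        cov = CovariateTable(samples=list(g.samples), columns=columns)
        cohorts.append(CohortDataset(
            name=cfg.cohort_names[i], genotypes=g, methylation=m,
            snp_ann=list(snp_ann), cpg_ann=list(cpg_ann), covariates=cov))
    return cohorts, truth
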