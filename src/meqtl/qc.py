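"""Quality control for methylation arrays and genotype matrices.

The filters and their default thresholds follow the standard array-QC
recipe for 27k-style methylation data paired with PLINK-style genotype QC:

* samples dropped when the probe detection call rate falls below 90% or
  the mean total intensity is below 50% of the experiment-wide sample
  mean or below 2,000 arbitrary units;
* data points with detection p > 0.001 masked to missing (after the
  sample exclusions);
* PCA outlier samples removed when their distance from the origin in the
  (PC1, PC2) plane exceeds 2.5 SD of that distance, in a single pass;
* SNPs dropped for call rate < 95%, Hardy–Weinberg exact p < 1e-5, or
  MAF < 0.05, after dropping samples with > 5% missing genotypes;
* CpG probes dropped when any known variant falls inside the probe's
  genomic footprint (such probes produce artifactual SNP associations).

All exclusions are returned as :class:`~meqtl.datatypes.QcRecord` lists so
the cohort keeps a complete audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .datatypes import (
    CpgAnnotation,
    GenotypeMatrix,
    MethylationMatrix,
    QcRecord,
    SnpAnnotation,
)


@dataclass(frozen=True)
class QcThresholds:
    sample_detection_callrate_min: float = 0.90
    detection_p_max: float = 0.001
    intensity_rel_min: float = 0.50
    intensity_abs_min: float = 2000.0
    pca_sd_cut: float = 2.5
    snp_callrate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 0.00001
    sample_missing_max: float = 0.05


# ---------------------------------------------------------------------------
# methylation sample QC
# ---------------------------------------------------------------------------

def methylation_sample_qc(
    m: MethylationMatrix, thr: QcThresholds = QcThresholds()
) -> tuple[MethylationMatrix, list[QcRecord]]:
    """Drop failing samples, then mask detection failures to missing.

    A probe "detects" in a sample when its detection p-value is present and
    at most ``thr.detection_p_max``; the sample call rate is the fraction
    of probes that detect. Intensity rules use the experiment-wide mean of
    the per-sample mean intensities.
    """
    records: list[QcRecord] = []
    detected = ~np.isnan(m.detection_p) & (m.detection_p <= thr.detection_p_max)
    callrate = detected.mean(axis=1) if len(m.cpgs) else np.ones(len(m.samples))
    mean_intensity = np.nanmean(m.intensity)
    keep = np.ones(len(m.samples), dtype=bool)
    for i, s in enumerate(m.samples):
        if callrate[i] < thr.sample_detection_callrate_min:
            keep[i] = False
            records.append(QcRecord("methylation_sample_qc", "sample", s,
                                    f"detection call rate {callrate[i]:.3f} < "
                                    f"{thr.sample_detection_callrate_min}"))
        elif m.intensity[i] < thr.intensity_rel_min * mean_intensity:
            keep[i] = False
            records.append(QcRecord("methylation_sample_qc", "sample", s,
                                    f"intensity {m.intensity[i]:.1f} < "
                                    f"{thr.intensity_rel_min:.0%} of sample mean"))
        elif m.intensity[i] < thr.intensity_abs_min:
            keep[i] = False
            records.append(QcRecord("methylation_sample_qc", "sample", s,
                                    f"intensity {m.intensity[i]:.1f} < "
                                    f"{thr.intensity_abs_min:.0f} units"))
    if not keep.any():
        raise ValueError("methylation sample QC excluded every sample")

    beta = m.beta[keep].copy()
    detp = m.detection_p[keep].copy()
    mask = np.isnan(detp) | (detp > thr.detection_p_max)
    n_masked = int((mask & ~np.isnan(beta)).sum())
    beta[mask] = np.nan
    if n_masked:
        records.append(QcRecord("methylation_sample_qc", "datapoint", str(n_masked),
                                f"detection p > {thr.detection_p_max} set to missing"))
    out = MethylationMatrix(
        samples=[s for s, k in zip(m.samples, keep) if k],
        cpgs=list(m.cpgs), beta=beta, detection_p=detp,
        intensity=m.intensity[keep],
    )
    return out, records


def pca_outlier_removal(
    m: MethylationMatrix, thr: QcThresholds = QcThresholds()
) -> tuple[MethylationMatrix, list[str]]:
    """Single-pass removal of samples far from the origin in PC1–PC2.

    Missing β-values are mean-imputed per CpG for the decomposition only.
    A sample is an outlier when its Euclidean distance from the origin in
    the first-two-PC plane exceeds ``pca_sd_cut`` standard deviations of
    the centered PC1–PC2 scores — i.e. ``pca_sd_cut`` times the
    root-mean-square distance, the spread of the point cloud around the
    origin. (Scaling by the SD of the *distances* would flag a quarter of
    perfectly typical samples, because distances concentrate tightly
    around their mean in two dimensions.)
    """
    n = len(m.samples)
    if n < 3:
        raise ValueError("PCA outlier removal needs at least 3 samples")
    X = m.beta.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    X = X - X.mean(axis=0)

    # scores in the PC1-PC2 plane via SVD of the centered matrix
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(2, len(S))
    scores = U[:, :k] * S[:k]
    dist = np.sqrt((scores**2).sum(axis=1))
    sd = float(np.sqrt(np.mean(dist**2)))  # RMS distance = SD of PC scores
    outliers = [s for s, d in zip(m.samples, dist) if sd > 0 and d > thr.pca_sd_cut * sd]
    if not outliers:
        return m, []
    keep = [s not in set(outliers) for s in m.samples]
    out = MethylationMatrix(
        samples=[s for s, k_ in zip(m.samples, keep) if k_],
        cpgs=list(m.cpgs),
        beta=m.beta[keep], detection_p=m.detection_p[keep],
        intensity=m.intensity[keep],
    )
    return out, outliers


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _hwe_het_probs(n: int, n_minor: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """P(#heterozygotes = h | n diploids, n_minor minor alleles), exactly.

    The conditional distribution of the heterozygote count given the allele
    margin under random mating; computed with log-gamma arithmetic and
    normalized.
    """
    from scipy.special import gammaln

    h_min = n_minor % 2
    h_max = min(n_minor, 2 * n - n_minor)
    hs = np.arange(h_min, h_max + 1, 2)
    n_aa = (n_minor - hs) // 2
    n_AA = n - n_aa - hs
    logp = (hs * np.log(2)
            + gammaln(n + 1)
            - gammaln(n_AA + 1) - gammaln(hs + 1) - gammaln(n_aa + 1)
            + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return tuple(int(h) for h in hs), tuple(float(x) for x in p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy–Weinberg proportions.

    Two-sided by probability ordering: the p-value is the total probability
    of heterozygote counts (given the allele counts) no more likely than
    the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hs, probs = _hwe_het_probs(n, n_minor)
    p_obs = probs[hs.index(n_Aa)]
    # tolerance absorbs round-off when comparing equal-probability outcomes
    return float(min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-12))))


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

def snp_qc(
    g: GenotypeMatrix, thr: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, list[QcRecord]]:
    """Sample-missingness, call-rate, HWE and MAF filters, in that order.

    The order matters because MAF and HWE are recomputed on the retained
    sample set. All inequalities are strict, so a SNP at MAF exactly 0.05
    or call rate exactly 95% is kept.
    """
    if not g.snps or not g.samples:
        raise ValueError("empty genotype matrix")
    records: list[QcRecord] = []
    values = g.values

    missing_frac = np.isnan(values).mean(axis=1)
    keep_samples = missing_frac <= thr.sample_missing_max
    for s, f, k in zip(g.samples, missing_frac, keep_samples):
        if not k:
            records.append(QcRecord("snp_qc", "sample", s,
                                    f"genotype missingness {f:.3f} > {thr.sample_missing_max}"))
    values = values[keep_samples]
    samples = [s for s, k in zip(g.samples, keep_samples) if k]
    if not samples:
        raise ValueError("all samples removed by genotype missingness filter")

    keep = np.ones(len(g.snps), dtype=bool)
    callrate = 1.0 - np.isnan(values).mean(axis=0)
    for j, snp in enumerate(g.snps):
        if callrate[j] < thr.snp_callrate_min:
            keep[j] = False
            records.append(QcRecord("snp_qc", "snp", snp,
                                    f"call rate {callrate[j]:.3f} < {thr.snp_callrate_min}"))
    for j, snp in enumerate(g.snps):
        if not keep[j]:
            continue
        col = values[:, j]
        col = col[~np.isnan(col)]
        n_AA = int((col == 2).sum())  # homozygous reference
        n_Aa = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if n_AA + n_Aa + n_aa == 0:
            keep[j] = False
            records.append(QcRecord("snp_qc", "snp", snp, "no called genotypes"))
            continue
        p_hwe = hwe_exact_test(n_AA, n_Aa, n_aa)
        if p_hwe < thr.hwe_p_min:
            keep[j] = False
            records.append(QcRecord("snp_qc", "snp", snp,
                                    f"HWE exact p {p_hwe:.3g} < {thr.hwe_p_min}"))
            continue
        freq_ref = (2 * n_AA + n_Aa) / (2 * (n_AA + n_Aa + n_aa))
        maf = min(freq_ref, 1 - freq_ref)
        if maf < thr.maf_min:
            keep[j] = False
            records.append(QcRecord("snp_qc", "snp", snp,
                                    f"MAF {maf:.4f} < {thr.maf_min}"))
    if not keep.any():
        raise ValueError("SNP QC excluded every SNP")
    out = GenotypeMatrix(
        samples=samples,
        snps=[s for s, k in zip(g.snps, keep) if k],
        values=values[:, keep],
    )
    return out, records


# ---------------------------------------------------------------------------
# probe-SNP exclusion
# ---------------------------------------------------------------------------

def exclude_probes_with_snps(
    cpg_ann: list[CpgAnnotation], variants: list[SnpAnnotation]
) -> list[str]:
    """IDs of CpGs whose probe interval contains no known variant.

    Intervals are 1-based inclusive on both ends, so a variant exactly at
    either boundary excludes the probe.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {v.chrom for v in variants}:
        by_chrom[chrom] = np.sort([v.pos for v in variants if v.chrom == chrom])
    retained: list[str] = []
    for cpg in cpg_ann:
        pos = by_chrom.get(cpg.chrom)
        if pos is None:
            retained.append(cpg.cpg_id)
            continue
        lo = np.searchsorted(pos, cpg.probe_start, side="left")
        hi = np.searchsorted(pos, cpg.probe_end, side="right")
        if hi == lo:  # no variant inside [probe_start, probe_end]
            retained.append(cpg.cpg_id)
    return retained


def maf(genotype_column: np.ndarray) -> float:
    """Minor allele frequency of one reference-allele-count column."""
    col = genotype_column[~np.isnan(genotype_column)]
    if col.size == 0:
        return float("nan")
    f = float(col.sum()) / (2 * col.size)
    return min(f, 1.0 - f)
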