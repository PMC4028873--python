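"""Core domain containers for multi-cohort cis-meQTL analysis.

Conventions used throughout the package:

* Coordinates are 1-based and inclusive on both ends (the convention of VCF
  and of Illumina array manifests). BED input is converted on read.
* Genotypes are stored as the count of **reference** alleles per sample
  (0, 1 or 2), the additive coding used for the regression. Missing calls
  are ``NaN`` in a float matrix — a sentinel distinct from the valid code 0.
* Methylation is stored as β-values (methylated / total signal), a
  proportion in [0, 1]; ``NaN`` marks missing or detection-masked entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpAnnotation:
    """A SNP with forward-strand alleles at a 1-based position."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{self.snp_id}: invalid allele {allele!r}")


@dataclass(frozen=True)
class CpgAnnotation:
    """A CpG probe: the interrogated site plus the probe's genomic footprint."""

    cpg_id: str
    chrom: str
    pos: int
    probe_start: int
    probe_end: int

    def __post_init__(self) -> None:
        if self.probe_end < self.probe_start:
            raise ValueError(f"{self.cpg_id}: probe interval end < start")
        if not (self.probe_start <= self.pos <= self.probe_end):
            raise ValueError(f"{self.cpg_id}: site not inside probe interval")

    @property
    def probe_interval(self) -> tuple[int, int]:
        return (self.probe_start, self.probe_end)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of reference-allele counts (NaN = missing)."""

    samples: list[str]
    snps: list[str]
    values: np.ndarray  # float, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {bad[:5]}")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate snp_id in genotype matrix")

    def snp_index(self, snp_id: str) -> int:
        return self.snps.index(snp_id)

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_index(snp_id)]


@dataclass
class MethylationMatrix:
    """Samples x CpGs β-values with per-point detection p and per-sample intensity."""

    samples: list[str]
    cpgs: list[str]
    beta: np.ndarray          # float, (n_samples, n_cpgs), NaN = missing
    detection_p: np.ndarray   # float, (n_samples, n_cpgs), NaN = missing
    intensity: np.ndarray     # float, (n_samples,) mean total signal

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        shape = (len(self.samples), len(self.cpgs))
        if self.beta.shape != shape or self.detection_p.shape != shape:
            raise ValueError("methylation matrix shapes do not match ID lists")
        if self.intensity.shape != (len(self.samples),):
            raise ValueError("intensity must be one value per sample")
        for name, arr in (("beta", self.beta), ("detection_p", self.detection_p)):
            finite = arr[~np.isnan(arr)]
            if finite.size and ((finite < 0).any() or (finite > 1).any()):
                raise ValueError(f"{name} values outside [0, 1]")

    def cpg_index(self, cpg_id: str) -> int:
        return self.cpgs.index(cpg_id)

    def column(self, cpg_id: str) -> np.ndarray:
        return self.beta[:, self.cpg_index(cpg_id)]


@dataclass
class CovariateTable:
    """Numeric covariate columns (e.g. batch indicators) aligned to samples."""

    samples: list[str]
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (len(self.samples),):
                raise ValueError(f"covariate {name!r} length != n samples")
            self.columns[name] = col

    def design(self) -> np.ndarray:
        """Covariates as a (n_samples, n_covariates) array (no intercept)."""
        if not self.columns:
            return np.empty((len(self.samples), 0))
        return np.column_stack([self.columns[k] for k in sorted(self.columns)])

    def subset(self, keep: list[str]) -> "CovariateTable":
        idx = [self.samples.index(s) for s in keep]
        return CovariateTable(
            samples=list(keep),
            columns={k: v[idx] for k, v in self.columns.items()},
        )


@dataclass(frozen=True)
class QcRecord:
    """One applied exclusion or masking step, for the cohort's audit trail."""

    stage: str
    kind: str        # "sample" | "snp" | "cpg" | "datapoint"
    item: str        # excluded ID, or a count summary for datapoint masking
    reason: str


@dataclass
class CohortDataset:
    """One cohort's genotypes, methylation, annotations and covariates.

    Construction enforces ID consistency: genotype and methylation sample
    sets must agree with the covariate table, and annotation lists must
    cover exactly the matrix feature lists.
    """

    name: str
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    snp_ann: list[SnpAnnotation]
    cpg_ann: list[CpgAnnotation]
    covariates: CovariateTable
    qc_log: list[QcRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotypes.samples != self.methylation.samples:
            raise ValueError(f"{self.name}: genotype/methylation sample lists differ")
        if self.covariates.samples != self.genotypes.samples:
            raise ValueError(f"{self.name}: covariate sample list differs")
        if [a.snp_id for a in self.snp_ann] != self.genotypes.snps:
            raise ValueError(f"{self.name}: SNP annotation does not match matrix")
        if [a.cpg_id for a in self.cpg_ann] != self.methylation.cpgs:
            raise ValueError(f"{self.name}: CpG annotation does not match matrix")

    @property
    def samples(self) -> list[str]:
        return self.genotypes.samples

    def log(self, stage: str, kind: str, item: str, reason: str) -> None:
        self.qc_log.append(QcRecord(stage=stage, kind=kind, item=item, reason=reason))
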