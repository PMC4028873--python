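import numpy as np
import pytest
from hypothesis import settings

from meqtl import SimConfig, simulate_study
from meqtl.datatypes import CpgAnnotation, SnpAnnotation

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A three-cohort study small enough for fast unit tests."""
    return SimConfig(
        n_cohorts=3, n_samples=60, n_snps=300, n_cpgs=80,
        chrom_length=1_500_000, n_planted=15, ld_block_len=[3, 6, 6],
        n_batches=[1, 2, 2], outlier_fraction=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_snp(snp_id="rs1", chrom="chr1", pos=100, ref="A", alt="G"):
    return SnpAnnotation(snp_id=snp_id, chrom=chrom, pos=pos,
                         ref_allele=ref, alt_allele=alt)


def make_cpg(cpg_id="cg1", chrom="chr1", pos=100, start=None, end=None):
    return CpgAnnotation(cpg_id=cpg_id, chrom=chrom, pos=pos,
                         probe_start=start if start is not None else pos - 25,
                         probe_end=end if end is not None else pos + 24)
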