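"""cis-meQTL association scanning.

Every SNP within the cis window (default 50 kb, inclusive) of a CpG site
is tested by ordinary least squares: the methylation level (β-value, or
its base-2 logit, the M-value) is regressed on the reference-allele count
(0, 1, 2) plus any covariate columns, per pair on complete cases only.
Pairs with residual degrees of freedom below ``min_df`` (default 30) are
not tested at all, and the Holm step-down correction is applied over
exactly the set of tests performed, controlling the family-wise error
rate at 5% within the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import CohortDataset, CovariateTable

M_CLAMP = 1e-6


@dataclass(frozen=True)
class CisPair:
    snp_id: str
    cpg_id: str
    distance_bp: int

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance must be non-negative")


@dataclass
class MeqtlResult:
    pair: CisPair
    beta_hat: float
    t: float
    df: int
    p: float
    p_holm: float
    significant: bool
    n_used: int
    degenerate: bool = False  # constant response: t and p by the 0/0 -> 0 rule


@dataclass(frozen=True)
class FilteredPair:
    """A pair excluded from testing, with the reason (df or monomorphic)."""

    pair: CisPair
    reason: str
    n_used: int


def build_cis_pairs(snp_ann, cpg_ann, window_bp: int = 50_000) -> list[CisPair]:
    """All same-chromosome SNP–CpG pairs with |Δpos| ≤ window_bp.

    Deterministic order: CpGs in input order, SNPs by (position, id)
    within each CpG's window.
    """
    by_chrom: dict[str, list] = {}
    for s in snp_ann:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: (s.pos, s.snp_id))
    pairs: list[CisPair] = []
    for cpg in cpg_ann:
        snps = by_chrom.get(cpg.chrom, ())
        if not snps:
            continue
        positions = np.array([s.pos for s in snps])
        lo = np.searchsorted(positions, cpg.pos - window_bp, side="left")
        hi = np.searchsorted(positions, cpg.pos + window_bp, side="right")
        for s in snps[lo:hi]:
            pairs.append(CisPair(snp_id=s.snp_id, cpg_id=cpg.cpg_id,
                                 distance_bp=abs(s.pos - cpg.pos)))
    return pairs


def beta_to_m(beta):
    """M-value: log2(β / (1−β)) with β clamped to [1e-6, 1−1e-6]."""
    b = np.clip(np.asarray(beta, dtype=float), M_CLAMP, 1.0 - M_CLAMP)
    return np.log2(b / (1.0 - b))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending
    order statistics; ties keep their stable sorted order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    stepped = np.minimum(1.0, factors * p[order])
    adjusted_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _ols_t(y: np.ndarray, X: np.ndarray) -> tuple[float, float, int]:
    """Slope, t and residual df for the second column of X (the genotype).

    Degenerate covariate columns (zero variance on the complete cases) are
    dropped before solving so they cost no degrees of freedom.
    """
    keep = [0, 1] + [j for j in range(2, X.shape[1])
                     if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise ValueError("exactly collinear design (covariates vs genotype)")
    resid = y - X @ coef
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(rss / df * XtX_inv[1, 1])
    slope = float(coef[1])
    if se == 0.0:
        # rss == 0: constant response gives 0/0 -> t = 0; an exact nonzero
        # fit gives t = +-inf (p underflows to 0 downstream)
        return slope, (0.0 if slope == 0.0 else float(np.sign(slope)) * np.inf), df
    return slope, slope / se, df


def fit_pair(
    beta_values: np.ndarray,
    alleles: np.ndarray,
    covariates: CovariateTable | np.ndarray | None = None,
    min_df: int = 30,
    scale: str = "beta",
) -> MeqtlResult | FilteredPair:
    """Test one SNP–CpG pair by OLS on complete cases.

    Returns a :class:`MeqtlResult` with ``p_holm`` unset (NaN) — the
    caller adjusts over its full family — or a :class:`FilteredPair` when
    the pair yields no valid test (insufficient residual df, or a
    monomorphic SNP among the complete cases).
    """
    if scale not in ("beta", "mvalue"):
        raise ValueError(f"unknown scale {scale!r}")
    y = np.asarray(beta_values, dtype=float)
    x = np.asarray(alleles, dtype=float)
    if covariates is None:
        C = np.empty((y.size, 0))
    elif isinstance(covariates, CovariateTable):
        C = covariates.design()
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if y.shape[0] != x.shape[0] or C.shape[0] != y.shape[0]:
        raise ValueError("response, genotype and covariates must align on samples")

    ok = ~np.isnan(y) & ~np.isnan(x)
    if C.shape[1]:
        ok &= ~np.isnan(C).any(axis=1)
    n_used = int(ok.sum())
    pair_stub = CisPair("", "", 0)

    y, x, C = y[ok], x[ok], C[ok]
    if n_used == 0 or np.ptp(x) == 0:
        return FilteredPair(pair=pair_stub, reason="monomorphic", n_used=n_used)
    n_cov = sum(np.ptp(C[:, j]) > 0 for j in range(C.shape[1]))
    df = n_used - (2 + n_cov)
    if df < min_df:
        return FilteredPair(pair=pair_stub, reason=f"df {df} < {min_df}", n_used=n_used)

    if scale == "mvalue":
        y = beta_to_m(y)
    if np.ptp(y) == 0:
        # constant response: slope is exactly 0 and the 0/0 t-ratio is
        # defined as 0 (p = 1) rather than left to floating-point noise
        return MeqtlResult(pair=pair_stub, beta_hat=0.0, t=0.0, df=df,
                           p=1.0, p_holm=float("nan"), significant=False,
                           n_used=n_used, degenerate=True)
    X = np.column_stack([np.ones(n_used), x, C])
    slope, t, df = _ols_t(y, X)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    degenerate = False
    return MeqtlResult(pair=pair_stub, beta_hat=slope, t=float(t), df=df,
                       p=p, p_holm=float("nan"), significant=False,
                       n_used=n_used, degenerate=degenerate)


def scan_cohort(
    ds: CohortDataset,
    window_bp: int = 50_000,
    min_df: int = 30,
    scale: str = "beta",
    alpha: float = 0.05,
) -> list[MeqtlResult]:
    """Scan all cis pairs in a cohort and Holm-adjust over performed tests.

    The Holm family is exactly the set of pairs that produced a test
    (those surviving the df filter), and a pair is called an meQTL when
    its adjusted p falls below ``alpha``.
    """
    pairs = build_cis_pairs(ds.snp_ann, ds.cpg_ann, window_bp=window_bp)
    if not pairs:
        raise ValueError(f"{ds.name}: no cis pairs within {window_bp} bp")
    snp_col = {s: j for j, s in enumerate(ds.genotypes.snps)}
    cpg_col = {c: j for j, c in enumerate(ds.methylation.cpgs)}
    C = ds.covariates.design()
    results: list[MeqtlResult] = []
    for pair in pairs:
        res = fit_pair(
            ds.methylation.beta[:, cpg_col[pair.cpg_id]],
            ds.genotypes.values[:, snp_col[pair.snp_id]],
            C, min_df=min_df, scale=scale,
        )
        if isinstance(res, FilteredPair):
            continue
        res.pair = pair
        results.append(res)
    if not results:
        raise ValueError(f"{ds.name}: no testable cis pairs after the df filter")
    adjusted = holm_adjust([r.p for r in results])
    for r, p_holm in zip(results, adjusted):
        r.p_holm = float(p_holm)
        r.significant = bool(p_holm < alpha)
    return results
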