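"""Cross-cohort agreement statistics for meQTL scans.

Given per-cohort Holm-significant SNP–CpG sets over a common tested
universe, this module computes:

* pairwise overlap tables — shared counts, percent overlap (with the
  column cohort's meQTL count as denominator), and one-sided Fisher
  exact log10 p-values computed in log space so that p-values far below
  the double-precision floor (1e-308) remain representable;
* subject-partitioned overlap, the check that cross-tissue overlap is
  not an artifact of shared subjects: subjects are split into disjoint
  halves and scans re-run per tissue per half;
* sign concordance of t-statistics across cohorts, with chance
  expectations from the Poisson-binomial law of the number of positive
  signs (the all-same-sign expectation is ∏ p_i + ∏ (1 − p_i));
* sliding-window LD pruning (r² > threshold removes the later SNP);
* hierarchical clustering of the t-statistic matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import GenotypeMatrix
from .scan import MeqtlResult, scan_cohort

LOG10_E = float(np.log10(np.e))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Fisher exact test, one-sided, in log space
# ---------------------------------------------------------------------------

def fisher_exact_log10(a: int, b: int, c: int, d: int) -> float:
    """log10 of the one-sided (enrichment) Fisher exact p-value.

    For the 2x2 table [[a, b], [c, d]], returns log10 P(X >= a) where X is
    hypergeometric with the table's margins. Computed with log-gamma
    summation, so extreme tables (p << 1e-308) give finite log10 values.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 0.0
    row1 = a + b
    col1 = a + c
    k_max = min(row1, col1)
    lg = math.lgamma
    # log hypergeometric pmf at k = a, then the tail via the pmf ratio
    # recurrence pmf(k+1)/pmf(k) = (row1-k)(col1-k) / ((k+1)(n-row1-col1+k+1))
    cur = (lg(row1 + 1) - lg(a + 1) - lg(row1 - a + 1)
           + lg(n - row1 + 1) - lg(col1 - a + 1) - lg(n - row1 - col1 + a + 1)
           - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1)))
    terms = [cur]
    for k in range(a, k_max):
        cur += (math.log((row1 - k) * (col1 - k))
                - math.log((k + 1) * (n - row1 - col1 + k + 1)))
        terms.append(cur)
    top = max(terms)
    log_p = top + math.log(sum(math.exp(t - top) for t in terms))
    return float(min(0.0, log_p * LOG10_E))


# ---------------------------------------------------------------------------
# overlap tables
# ---------------------------------------------------------------------------

@dataclass
class OverlapTable:
    cohorts: list[str]
    meqtl_counts: np.ndarray      # (k,)
    shared: np.ndarray            # (k, k) symmetric, diagonal = counts
    percent: np.ndarray           # percent[i, j] = 100 * shared / counts[j]
    fisher_log10p: np.ndarray     # (k, k), 0.0 on the diagonal
    universe_size: int


def overlap_table(results_by_cohort: dict[str, list[MeqtlResult]],
                  universe_size: int) -> OverlapTable:
    """Pairwise meQTL overlap over a common tested-pair universe.

    Every cohort's results must cover the identical (snp_id, cpg_id)
    universe of ``universe_size`` pairs. The percent convention puts the
    *column* cohort's meQTL count in the denominator, so the matrix is
    asymmetric while the shared counts are symmetric.
    """
    cohorts = list(results_by_cohort)
    keysets = {
        name: {(r.pair.snp_id, r.pair.cpg_id) for r in results}
        for name, results in results_by_cohort.items()
    }
    tested = next(iter(keysets.values())) if keysets else set()
    for name, keys in keysets.items():
        if keys != tested:
            raise ValueError(
                f"cohort {name!r} was tested on a different pair universe")
    if tested and len(tested) != universe_size:
        raise ValueError(
            f"universe_size {universe_size} != {len(tested)} tested pairs")
    sig = {
        name: {(r.pair.snp_id, r.pair.cpg_id)
               for r in results if r.significant}
        for name, results in results_by_cohort.items()
    }
    k = len(cohorts)
    counts = np.array([len(sig[c]) for c in cohorts])
    shared = np.zeros((k, k), dtype=int)
    percent = np.zeros((k, k))
    log10p = np.zeros((k, k))
    for i, ci in enumerate(cohorts):
        for j, cj in enumerate(cohorts):
            if i == j:
                shared[i, j] = counts[i]
                percent[i, j] = 100.0
                continue
            s = len(sig[ci] & sig[cj])
            shared[i, j] = s
            percent[i, j] = 100.0 * s / counts[j] if counts[j] else 0.0
            a = s
            b = counts[i] - s
            c = counts[j] - s
            d = universe_size - a - b - c
            log10p[i, j] = fisher_exact_log10(a, b, c, d)
    return OverlapTable(cohorts=cohorts, meqtl_counts=counts, shared=shared,
                        percent=percent, fisher_log10p=log10p,
                        universe_size=universe_size)


def overlap_table_from_counts(cohorts: list[str], counts, shared,
                              universe_size: int) -> OverlapTable:
    """Overlap table arithmetic from already-tabulated counts.

    Used to recompute a printed report table (percent cells and Fisher
    tests) without the underlying per-pair results.
    """
    counts = np.asarray(counts, dtype=int)
    shared = np.asarray(shared, dtype=int)
    k = len(cohorts)
    percent = np.zeros((k, k))
    log10p = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                percent[i, j] = 100.0
                continue
            s = int(shared[i, j])
            percent[i, j] = 100.0 * s / counts[j] if counts[j] else 0.0
            log10p[i, j] = fisher_exact_log10(
                s, int(counts[i]) - s, int(counts[j]) - s,
                universe_size - counts[i] - counts[j] + s)
    return OverlapTable(cohorts=list(cohorts), meqtl_counts=counts,
                        shared=shared, percent=percent, fisher_log10p=log10p,
                        universe_size=universe_size)


# ---------------------------------------------------------------------------
# subject-partitioned overlap
# ---------------------------------------------------------------------------

@dataclass
class PartitionOverlap:
    """Overlap between meQTL sets from disjoint subject halves."""

    comparisons: dict[str, tuple[int, int, int, float]] = field(default_factory=dict)
    # name -> (n_sig_first, n_sig_second, shared, fisher_log10p)


def partition_overlap(ds_x, ds_y, seed: int, window_bp: int = 50_000,
                      min_df: int = 10, scale: str = "beta") -> PartitionOverlap:
    """Split common subjects in half; compare scans within and across halves.

    ``A-vs-B`` compares tissue X scanned on half A against tissue Y on the
    disjoint half B (no shared subjects); ``A-vs-A`` and ``B-vs-B`` compare
    the tissues on the same half. ``min_df`` defaults lower than a full
    scan because each half has half the subjects.
    """
    from .pipeline import subset_cohort  # deferred: avoids a module cycle

    subjects = [s for s in ds_x.samples if s in set(ds_y.samples)]
    if len(subjects) < 8:
        raise ValueError("need at least 8 common subjects to partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    half = len(subjects) // 2
    group_a = sorted(subjects[i] for i in perm[:half])
    group_b = sorted(subjects[i] for i in perm[half:])

    def sig_set(ds, keep):
        sub = subset_cohort(ds, keep)
        results = scan_cohort(sub, window_bp=window_bp, min_df=min_df, scale=scale)
        keys = {(r.pair.snp_id, r.pair.cpg_id) for r in results}
        sig = {(r.pair.snp_id, r.pair.cpg_id) for r in results if r.significant}
        return sig, keys

    xa, keys_xa = sig_set(ds_x, group_a)
    xb, keys_xb = sig_set(ds_x, group_b)
    ya, keys_ya = sig_set(ds_y, group_a)
    yb, keys_yb = sig_set(ds_y, group_b)

    out = PartitionOverlap()
    for name, (s1, s2, universe) in {
        "A-vs-B": (xa, yb, keys_xa & keys_yb),
        "B-vs-A": (xb, ya, keys_xb & keys_ya),
        "A-vs-A": (xa, ya, keys_xa & keys_ya),
        "B-vs-B": (xb, yb, keys_xb & keys_yb),
    }.items():
        u1, u2 = s1 & universe, s2 & universe
        a = len(u1 & u2)
        lp = fisher_exact_log10(a, len(u1) - a, len(u2) - a,
                                len(universe) - len(u1) - len(u2) + a)
        out.comparisons[name] = (len(u1), len(u2), a, lp)
    return out


# ---------------------------------------------------------------------------
# sign concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceSummary:
    k: int
    n_pairs: int
    p_positive: np.ndarray          # per-cohort fraction of positive t
    observed_all_same: float
    expected_all_same: float
    m: int
    observed_atleast_m: float
    expected_atleast_m: float
    binomial_log10p_all: float      # observed all-same count vs chance
    binomial_log10p_atleast_m: float
    n_dropped_zero: int


def poisson_binomial_pmf(probs) -> np.ndarray:
    """PMF of the number of successes among independent Bernoulli(p_i)."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def expected_same_sign(probs, m: int | None = None) -> float:
    """Chance probability that at least m of k signs agree.

    With S ~ Poisson-binomial(p_1..p_k) counting positive signs, "at least
    m same" is the event S >= m or S <= k − m; for m = k this is the
    all-same probability ∏ p_i + ∏ (1 − p_i).
    """
    probs = np.asarray(probs, dtype=float)
    k = probs.size
    if m is None:
        m = k
    if m > k:
        raise ValueError(f"m = {m} exceeds the number of cohorts {k}")
    pmf = poisson_binomial_pmf(probs)
    s = np.arange(k + 1)
    return float(pmf[(s >= m) | (s <= k - m)].sum())


def sign_concordance(tstats: np.ndarray, m: int) -> ConcordanceSummary:
    """Observed vs chance sign agreement across cohorts.

    ``tstats`` is (pairs x cohorts), already restricted by the caller to
    pairs significant in at least one cohort. Rows containing a zero
    t-statistic are signless and dropped (counted in ``n_dropped_zero``).
    """
    T = np.asarray(tstats, dtype=float)
    if T.ndim != 2 or T.shape[1] < 2:
        raise ValueError("need a pairs x cohorts matrix with >= 2 cohorts")
    k = T.shape[1]
    if m > k:
        raise ValueError(f"m = {m} exceeds the number of cohorts {k}")
    nonzero = (T != 0).all(axis=1) & ~np.isnan(T).any(axis=1)
    n_dropped = int(T.shape[0] - nonzero.sum())
    T = T[nonzero]
    if T.shape[0] == 0:
        raise ValueError("no pairs with a sign in every cohort")
    pos = T > 0
    p_i = pos.mean(axis=0)
    n_pos = pos.sum(axis=1)
    obs_all = float(((n_pos == k) | (n_pos == 0)).mean())
    obs_m = float(((n_pos >= m) | (n_pos <= k - m)).mean())
    exp_all = expected_same_sign(p_i, k)
    exp_m = expected_same_sign(p_i, m)
    n = T.shape[0]

    def log10p(observed_frac, expected):
        count = int(round(observed_frac * n))
        # one-sided: observed agreement above the chance expectation
        lp = stats.binom.logsf(count - 1, n, expected) * LOG10_E
        return float(lp)

    return ConcordanceSummary(
        k=k, n_pairs=n, p_positive=p_i,
        observed_all_same=obs_all, expected_all_same=exp_all,
        m=m, observed_atleast_m=obs_m, expected_atleast_m=exp_m,
        binomial_log10p_all=log10p(obs_all, exp_all),
        binomial_log10p_atleast_m=log10p(obs_m, exp_m),
        n_dropped_zero=n_dropped,
    )


def pairwise_sign_concordance(tstats: np.ndarray, i: int, j: int
                              ) -> tuple[float, float, float]:
    """Same-direction agreement between two cohorts' t-statistics.

    Returns (observed fraction, chance expectation p_i p_j + q_i q_j,
    one-sided binomial log10 p for observed agreement above chance).
    Rows with a zero or missing t in either cohort are dropped.
    """
    T = np.asarray(tstats, dtype=float)[:, [i, j]]
    ok = (T != 0).all(axis=1) & ~np.isnan(T).any(axis=1)
    T = T[ok]
    if T.shape[0] == 0:
        raise ValueError("no pairs with a sign in both cohorts")
    pos = T > 0
    pi, pj = pos.mean(axis=0)
    expected = pi * pj + (1 - pi) * (1 - pj)
    same = pos[:, 0] == pos[:, 1]
    observed = float(same.mean())
    n = T.shape[0]
    lp = float(stats.binom.logsf(int(same.sum()) - 1, n, expected) * LOG10_E)
    return observed, float(expected), lp


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(g: GenotypeMatrix, positions=None, window: int = 50,
             step: int = 5, r2_max: float = 0.05,
             window_unit: str = "snp") -> list[str]:
    """Greedy sliding-window pairwise pruning on genotype r².

    Within each window (``window`` consecutive SNPs, or a span in bp when
    ``window_unit="bp"``), every retained pair with squared genotype
    correlation above ``r2_max`` loses its later member (by position,
    then ID). The window slides by ``step`` SNPs. SNPs must be
    position-sorted; pass ``positions`` or they are taken as 0..n-1.
    """
    n = len(g.snps)
    if positions is None:
        positions = np.arange(n)
    positions = np.asarray(positions)
    if (np.diff(positions) < 0).any():
        raise ValueError("SNPs must be position-sorted for pruning")
    removed = np.zeros(n, dtype=bool)
    values = g.values
    for start in range(0, max(n - 1, 1), step):
        if window_unit == "snp":
            stop = min(start + window, n)
        elif window_unit == "bp":
            stop = int(np.searchsorted(positions, positions[start] + window,
                                       side="right"))
        else:
            raise ValueError(f"unknown window_unit {window_unit!r}")
        idx = [j for j in range(start, stop) if not removed[j]]
        for ai in range(len(idx)):
            if removed[idx[ai]]:
                continue
            for bi in range(ai + 1, len(idx)):
                i, j = idx[ai], idx[bi]
                if removed[j]:
                    continue
                xi, xj = values[:, i], values[:, j]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() < 3:
                    continue
                a, b = xi[ok], xj[ok]
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                if r * r > r2_max:
                    removed[j] = True
        if stop >= n:
            break
    return [s for s, gone in zip(g.snps, removed) if not gone]


# ---------------------------------------------------------------------------
# t-statistic clustering
# ---------------------------------------------------------------------------

@dataclass
class TstatClustering:
    cohort_linkage: np.ndarray
    cohort_order: list[int]
    row_linkage: np.ndarray | None
    row_order: list[int]


def cluster_tstats(tstats: np.ndarray, cluster_rows: bool = True) -> TstatClustering:
    """Average-linkage Euclidean clustering of cohorts (and pairs).

    Missing t-statistics are set to 0 (no evidence either way). SciPy's
    agglomerative implementation breaks ties by input index, so the result
    is deterministic for a fixed row order.
    """
    T = np.asarray(tstats, dtype=float)
    if T.ndim != 2 or T.shape[1] < 2:
        raise ValueError("need a pairs x cohorts matrix with >= 2 cohorts")
    T = np.where(np.isnan(T), 0.0, T)
    col_link = linkage(T.T, method="average", metric="euclidean")
    col_order = [int(i) for i in leaves_list(col_link)]
    row_link = None
    row_order = list(range(T.shape[0]))
    if cluster_rows and T.shape[0] > 1:
        row_link = linkage(T, method="average", metric="euclidean")
        row_order = [int(i) for i in leaves_list(row_link)]
    return TstatClustering(cohort_linkage=col_link, cohort_order=col_order,
                           row_linkage=row_link, row_order=row_order)
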