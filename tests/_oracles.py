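"""Independent reference implementations used only by the tests.

Everything here is brute force or exact rational arithmetic, kept
deliberately separate from the package's own (log-space / vectorized)
code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

import numpy as np


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for the 2x2 table's margins, as an exact rational."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0:
        return Fraction(1)
    denom = math.comb(n, col1)
    total = sum(
        math.comb(row1, k) * math.comb(n - row1, col1 - k)
        for k in range(a, min(row1, col1) + 1)
    )
    return Fraction(total, denom)


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact-conditional HWE p-value by full rational enumeration.

    Conditional on the allele counts, P(h heterozygotes) is proportional
    to 2^h * n! / (n_AA! h! n_aa!); the p-value sums outcomes no more
    likely than the observed heterozygote count.
    """
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    weights: dict[int, int] = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        n_hom_minor = (n_minor - h) // 2
        n_hom_major = n - n_hom_minor - h
        weights[h] = (2**h * math.factorial(n)
                      // (math.factorial(n_hom_major) * math.factorial(h)
                          * math.factorial(n_hom_minor)))
    total = sum(weights.values())
    observed = weights[n_Aa]
    tail = sum(w for w in weights.values() if w <= observed)
    return Fraction(tail, total)


def ols_slope_t(y, x, covariates=None):
    """Slope, t, df for x in an OLS fit, via statsmodels."""
    import statsmodels.api as sm

    X = np.column_stack([np.asarray(x, dtype=float)]
                        + ([np.asarray(covariates, dtype=float)]
                           if covariates is not None else []))
    X = sm.add_constant(X, prepend=True)
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.tvalues[1]), int(fit.df_resid)


def holm_statsmodels(pvalues):
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def same_sign_enumeration(probs, m: int) -> float:
    """P(at least m of k independent signs agree) by 2^k enumeration."""
    probs = list(probs)
    k = len(probs)
    total = 0.0
    for signs in product((0, 1), repeat=k):
        p = 1.0
        for s, pi in zip(signs, probs):
            p *= pi if s else (1.0 - pi)
        n_pos = sum(signs)
        if n_pos >= m or (k - n_pos) >= m:
            total += p
    return total


def brute_force_cis_pairs(snp_ann, cpg_ann, window_bp):
    out = set()
    for s in snp_ann:
        for c in cpg_ann:
            if s.chrom == c.chrom and abs(s.pos - c.pos) <= window_bp:
                out.add((s.snp_id, c.cpg_id, abs(s.pos - c.pos)))
    return out


def brute_force_probe_exclusion(cpg_ann, variants):
    retained = []
    for c in cpg_ann:
        hit = any(v.chrom == c.chrom and c.probe_start <= v.pos <= c.probe_end
                  for v in variants)
        if not hit:
            retained.append(c.cpg_id)
    return retained
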