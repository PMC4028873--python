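#!/usr/bin/env python
"""Cross-cohort agreement: overlap table, sign concordance, clustering.

Writes results/overlap_report.txt (the "n (pct)" matrix with Fisher
log10 p-values), results/concordance.tsv (observed vs chance sign
agreement) and results/cohort_clustering.tsv (dendrogram leaf order of
the cohorts on their t-statistic profiles). With the default study the
cohorts cluster by ancestry group and observed sign agreement far
exceeds the Poisson-binomial chance expectation.
"""

import numpy as np

from _common import RESULTS, announce, scanned_study
from meqtl.overlap import cluster_tstats, sign_concordance
from meqtl.pipeline import (
    render_overlap_report,
    restrict_to_common_universe,
    tstat_matrix,
)
from meqtl.overlap import overlap_table


def main() -> None:
    _, _, results = scanned_study()
    RESULTS.mkdir(exist_ok=True)
    common, universe = restrict_to_common_universe(results)
    table = overlap_table(common, universe)
    report = render_overlap_report(table)
    (RESULTS / "overlap_report.txt").write_text(
        report + f"\nuniverse\t{universe} SNP-CpG pairs tested in all cohorts\n")
    worst = float(table.fisher_log10p[table.fisher_log10p < 0].max())
    announce(f"overlap: universe {universe} pairs; all pairwise Fisher "
             f"log10 p <= {worst:.1f}")

    T, keys, names = tstat_matrix(common)
    filled = np.where(np.isnan(T), 0.0, T)
    usable = (filled != 0).all(axis=1)
    summary = sign_concordance(filled[usable], m=len(names) - 1)
    with open(RESULTS / "concordance.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"pairs_significant_in_any_cohort\t{T.shape[0]}\n")
        fh.write(f"pairs_with_sign_in_every_cohort\t{summary.n_pairs}\n")
        fh.write(f"observed_all_same_pct\t{100 * summary.observed_all_same:.2f}\n")
        fh.write(f"expected_all_same_pct\t{100 * summary.expected_all_same:.3f}\n")
        fh.write(f"observed_atleast_{summary.m}_pct\t"
                 f"{100 * summary.observed_atleast_m:.2f}\n")
        fh.write(f"expected_atleast_{summary.m}_pct\t"
                 f"{100 * summary.expected_atleast_m:.3f}\n")
        fh.write(f"binomial_log10p_all_same\t{summary.binomial_log10p_all:.2f}\n")
    announce(f"sign concordance: observed all-same "
             f"{100 * summary.observed_all_same:.1f}% vs chance "
             f"{100 * summary.expected_all_same:.2f}%")

    clustering = cluster_tstats(filled, cluster_rows=False)
    with open(RESULTS / "cohort_clustering.tsv", "w") as fh:
        fh.write("leaf_order\t" + "\t".join(
            names[i] for i in clustering.cohort_order) + "\n")
        fh.write("merge_height\t" + "\t".join(
            f"{h:.3f}" for h in clustering.cohort_linkage[:, 2]) + "\n")
    announce("cohort dendrogram order: "
             + " ".join(names[i] for i in clustering.cohort_order))


if __name__ == "__main__":
    main()
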