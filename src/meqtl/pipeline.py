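"""End-to-end orchestration: simulate -> QC -> scan -> overlap ->
concordance -> enrichment, from one configuration.

Each stage draws its randomness from a seed derived deterministically
from the run's global seed (``SeedSequence(seed, spawn_key=(stage,))``),
so a stage can be re-run in isolation and the whole run is reproducible
byte for byte. Every output is TSV/JSON text; a manifest records stage
seeds, record counts and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .datatypes import CohortDataset, CovariateTable, MethylationMatrix
from .enrichment import enrichment_test
from .overlap import (
    OverlapTable,
    cluster_tstats,
    overlap_table,
    round_half_up,
    sign_concordance,
)
from .qc import (
    QcThresholds,
    exclude_probes_with_snps,
    maf,
    methylation_sample_qc,
    pca_outlier_removal,
    snp_qc,
)
from .scan import MeqtlResult, scan_cohort
from .simulate import SimConfig, simulate_study

log = logging.getLogger("meqtl")

_STAGES = ["simulate", "qc", "scan", "overlap", "concordance", "enrichment"]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    window_bp: int = 50_000
    min_df: int = 30
    scale: str = "beta"
    alpha: float = 0.05
    concordance_min_cohorts: int | None = None  # default: k - 1
    enrichment_n_resamples: int = 1000
    enrichment_target: str | None = None  # path to an rsID list; default:
    # the simulation's planted SNPs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "mvalue"):
            raise ValueError(f"scale must be beta or mvalue, got {self.scale!r}")
        if self.min_df < 1 or self.window_bp < 0:
            raise ValueError("min_df must be >= 1 and window_bp >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QcThresholds(**raw.pop("qc", {}))
        return cls(sim=sim, qc=qc, **raw)

    def to_yaml(self, path: str | Path) -> None:
        sim = dataclasses.asdict(self.sim)
        if sim.get("effect_sharing") is not None:
            sim["effect_sharing"] = np.asarray(sim["effect_sharing"]).tolist()
        raw = {k: v for k, v in dataclasses.asdict(self).items()
               if k not in ("sim", "qc")}
        raw["sim"] = sim
        raw["qc"] = dataclasses.asdict(self.qc)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the global run seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# dataset surgery
# ---------------------------------------------------------------------------

def subset_cohort(ds: CohortDataset, samples: list[str]) -> CohortDataset:
    """Restrict a cohort to a sample subset (order as given)."""
    gi = [ds.genotypes.samples.index(s) for s in samples]
    mi = [ds.methylation.samples.index(s) for s in samples]
    g = dataclasses.replace(ds.genotypes, samples=list(samples),
                            values=ds.genotypes.values[gi])
    m = MethylationMatrix(samples=list(samples), cpgs=list(ds.methylation.cpgs),
                          beta=ds.methylation.beta[mi],
                          detection_p=ds.methylation.detection_p[mi],
                          intensity=ds.methylation.intensity[mi])
    return CohortDataset(name=ds.name, genotypes=g, methylation=m,
                         snp_ann=list(ds.snp_ann), cpg_ann=list(ds.cpg_ann),
                         covariates=ds.covariates.subset(list(samples)),
                         qc_log=list(ds.qc_log))


def qc_cohort(ds: CohortDataset, thr: QcThresholds = QcThresholds()) -> CohortDataset:
    """Apply the full QC cascade to one cohort, logging every exclusion.

    Order: methylation sample QC (call rate, intensity, detection-p
    masking) -> PCA outlier removal -> genotype QC (sample missingness,
    call rate, HWE, MAF) -> probe-SNP exclusion -> alignment of the two
    matrices on the surviving sample set.
    """
    from .datatypes import QcRecord

    meth, records = methylation_sample_qc(ds.methylation, thr)
    meth, pca_out = pca_outlier_removal(meth, thr)
    qc_log = list(ds.qc_log) + records
    for s in pca_out:
        qc_log.append(QcRecord("pca_outlier_removal", "sample", s,
                               f"PC1-PC2 distance > {thr.pca_sd_cut} SD"))

    geno, geno_records = snp_qc(ds.genotypes, thr)
    qc_log += geno_records

    keep_samples = [s for s in geno.samples if s in set(meth.samples)]
    gi = [geno.samples.index(s) for s in keep_samples]
    geno = dataclasses.replace(geno, samples=keep_samples, values=geno.values[gi])
    mi = [meth.samples.index(s) for s in keep_samples]
    meth = MethylationMatrix(samples=keep_samples, cpgs=list(meth.cpgs),
                             beta=meth.beta[mi], detection_p=meth.detection_p[mi],
                             intensity=meth.intensity[mi])

    snp_ann = [a for a in ds.snp_ann if a.snp_id in set(geno.snps)]
    retained_cpgs = set(exclude_probes_with_snps(ds.cpg_ann, snp_ann))
    for a in ds.cpg_ann:
        if a.cpg_id not in retained_cpgs:
            qc_log.append(QcRecord("exclude_probes_with_snps", "cpg", a.cpg_id,
                                   "variant within probe interval"))
    cpg_keep = [j for j, c in enumerate(meth.cpgs) if c in retained_cpgs]
    meth = MethylationMatrix(samples=keep_samples,
                             cpgs=[meth.cpgs[j] for j in cpg_keep],
                             beta=meth.beta[:, cpg_keep],
                             detection_p=meth.detection_p[:, cpg_keep],
                             intensity=meth.intensity)
    cpg_ann = [a for a in ds.cpg_ann if a.cpg_id in retained_cpgs]
    cov = ds.covariates.subset(keep_samples)
    return CohortDataset(name=ds.name, genotypes=geno, methylation=meth,
                         snp_ann=snp_ann, cpg_ann=cpg_ann,
                         covariates=cov, qc_log=qc_log)


def restrict_to_common_universe(
    results_by_cohort: dict[str, list[MeqtlResult]]
) -> tuple[dict[str, list[MeqtlResult]], int]:
    """Keep only SNP–CpG pairs tested in every cohort.

    Holm adjustment is *not* redone: each cohort's correction was over the
    tests it performed, and the restriction only harmonizes the universe
    for between-cohort comparison.
    """
    common: set | None = None
    for results in results_by_cohort.values():
        keys = {(r.pair.snp_id, r.pair.cpg_id) for r in results}
        common = keys if common is None else common & keys
    common = common or set()
    out = {
        name: [r for r in results
               if (r.pair.snp_id, r.pair.cpg_id) in common]
        for name, results in results_by_cohort.items()
    }
    return out, len(common)


def tstat_matrix(results_by_cohort: dict[str, list[MeqtlResult]]
                 ) -> tuple[np.ndarray, list[tuple[str, str]], list[str]]:
    """(pairs x cohorts) t-matrix over pairs significant in >= 1 cohort."""
    cohorts = list(results_by_cohort)
    sig_keys: set[tuple[str, str]] = set()
    by_key: dict[str, dict[tuple[str, str], MeqtlResult]] = {}
    for name, results in results_by_cohort.items():
        by_key[name] = {(r.pair.snp_id, r.pair.cpg_id): r for r in results}
        sig_keys |= {k for k, r in by_key[name].items() if r.significant}
    keys = sorted(sig_keys)
    T = np.full((len(keys), len(cohorts)), np.nan)
    for j, name in enumerate(cohorts):
        for i, k in enumerate(keys):
            r = by_key[name].get(k)
            if r is not None:
                T[i, j] = r.t
    return T, keys, cohorts


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_overlap_report(table: OverlapTable) -> str:
    """Text table with ``SHARED (PCT)`` cells, percent to one decimal.

    Percent denominators are the column cohort's meQTL count; rounding is
    half away from zero; the diagonal is '-'.
    """
    header = ["Cohort", "# of meQTLs"] + list(table.cohorts)
    lines = ["\t".join(header)]
    for i, ci in enumerate(table.cohorts):
        row = [ci, str(int(table.meqtl_counts[i]))]
        for j in range(len(table.cohorts)):
            if i == j:
                row.append("-")
            else:
                pct = round_half_up(table.percent[i, j], 1)
                row.append(f"{int(table.shared[i, j])} ({pct:.1f})")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def overlap_cell(shared: int, column_count: int) -> str:
    """One report cell, ``"319 (50.7)"`` style."""
    pct = round_half_up(100.0 * shared / column_count, 1) if column_count else 0.0
    return f"{shared} ({pct:.1f})"


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Writes per-cohort result TSVs, the overlap report, concordance and
    enrichment summaries, the QC log and a manifest. Raises with the
    stage name on any stage failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(
            cfg.sim, seed=stage_seed(cfg.seed, "simulate"))
        cohorts, truth = simulate_study(sim_cfg)
        log.info("simulate: %d cohorts, %d SNPs, %d CpGs, %d planted effects",
                 len(cohorts), sim_cfg.n_snps, sim_cfg.n_cpgs,
                 len(truth.planted))
        mio.write_snp_set({e.snp_id for e in truth.planted}, out / "truth_snps.txt")
        with open(out / "truth_pairs.tsv", "w") as fh:
            fh.write("snp_id\tcpg_id\tsign\t"
                     + "\t".join(c.name for c in cohorts) + "\n")
            for e in truth.planted:
                fh.write(f"{e.snp_id}\t{e.cpg_id}\t{e.sign}\t"
                         + "\t".join(str(s) for s in e.sharing) + "\n")
        manifest["stages"][stage] = {
            "seed": sim_cfg.seed, "n_cohorts": len(cohorts),
            "n_planted": len(truth.planted)}

        stage = "qc"
        clean = [qc_cohort(ds, cfg.qc) for ds in cohorts]
        with open(out / "qc_log.tsv", "w") as fh:
            fh.write("cohort\tstage\tkind\titem\treason\n")
            for ds in clean:
                for r in ds.qc_log:
                    fh.write(f"{ds.name}\t{r.stage}\t{r.kind}\t{r.item}\t{r.reason}\n")
        for ds, raw in zip(clean, cohorts):
            log.info("qc[%s]: samples %d -> %d, SNPs %d -> %d, CpGs %d -> %d",
                     ds.name, len(raw.samples), len(ds.samples),
                     len(raw.genotypes.snps), len(ds.genotypes.snps),
                     len(raw.methylation.cpgs), len(ds.methylation.cpgs))
        manifest["stages"][stage] = {
            "exclusions": sum(len(ds.qc_log) for ds in clean)}

        stage = "scan"
        results_by_cohort: dict[str, list[MeqtlResult]] = {}
        for ds in clean:
            results = scan_cohort(ds, window_bp=cfg.window_bp,
                                  min_df=cfg.min_df, scale=cfg.scale,
                                  alpha=cfg.alpha)
            results_by_cohort[ds.name] = results
            mio.write_results(results, out / f"results_{ds.name}.tsv")
            n_sig = sum(r.significant for r in results)
            log.info("scan[%s]: %d tests, %d Holm-significant", ds.name,
                     len(results), n_sig)
        manifest["stages"][stage] = {
            name: {"tests": len(res), "meqtls": sum(r.significant for r in res)}
            for name, res in results_by_cohort.items()}

        stage = "overlap"
        common, universe = restrict_to_common_universe(results_by_cohort)
        table = overlap_table(common, universe)
        (out / "overlap_report.txt").write_text(render_overlap_report(table))
        with open(out / "overlap.tsv", "w") as fh:
            fh.write("cohort_i\tcohort_j\tmeqtls_i\tmeqtls_j\tshared\t"
                     "percent_of_j\tfisher_log10p\n")
            for i, ci in enumerate(table.cohorts):
                for j, cj in enumerate(table.cohorts):
                    if i == j:
                        continue
                    fh.write(f"{ci}\t{cj}\t{table.meqtl_counts[i]}\t"
                             f"{table.meqtl_counts[j]}\t{table.shared[i, j]}\t"
                             f"{mio.FLOAT_FMT % table.percent[i, j]}\t"
                             f"{mio.FLOAT_FMT % table.fisher_log10p[i, j]}\n")
        log.info("overlap: universe of %d pairs common to all cohorts", universe)
        manifest["stages"][stage] = {"universe": universe}

        stage = "concordance"
        T, keys, cohort_names = tstat_matrix(common)
        k = len(cohort_names)
        m = cfg.concordance_min_cohorts or max(2, k - 1)
        summary = None
        if T.shape[0] >= 2 and k >= 2:
            filled = np.where(np.isnan(T), 0.0, T)
            usable = (filled != 0).all(axis=1)
            if usable.sum() >= 2:
                summary = sign_concordance(filled[usable], m=min(m, k))
            clustering = cluster_tstats(filled)
            with open(out / "clustering.tsv", "w") as fh:
                fh.write("cohort_order\t" + "\t".join(
                    cohort_names[i] for i in clustering.cohort_order) + "\n")
                fh.write("row_order\t" + "\t".join(
                    f"{keys[i][0]}|{keys[i][1]}" for i in clustering.row_order)
                    + "\n")
        with open(out / "concordance.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            if summary is not None:
                fh.write(f"n_pairs\t{summary.n_pairs}\n")
                fh.write(f"observed_all_same\t{mio.FLOAT_FMT % summary.observed_all_same}\n")
                fh.write(f"expected_all_same\t{mio.FLOAT_FMT % summary.expected_all_same}\n")
                fh.write(f"observed_atleast_{summary.m}\t"
                         f"{mio.FLOAT_FMT % summary.observed_atleast_m}\n")
                fh.write(f"expected_atleast_{summary.m}\t"
                         f"{mio.FLOAT_FMT % summary.expected_atleast_m}\n")
                log.info("concordance: observed all-same %.3f vs chance %.4f",
                         summary.observed_all_same, summary.expected_all_same)
        manifest["stages"][stage] = {
            "pairs_significant_anywhere": int(T.shape[0])}

        stage = "enrichment"
        if cfg.enrichment_target:
            target = mio.read_snp_set(cfg.enrichment_target)
        else:
            target = {e.snp_id for e in truth.planted}
        rng = np.random.default_rng(stage_seed(cfg.seed, "enrichment"))
        with open(out / "enrichment.tsv", "w") as fh:
            fh.write("cohort\tobserved\tnull_mean\tnull_sd\tempirical_p\t"
                     "empirical_p_corrected\treported_as\n")
            enr_stage: dict = {}
            for ds in clean:
                results = results_by_cohort[ds.name]
                meqtl_snps = {r.pair.snp_id for r in results if r.significant}
                universe_mafs = {
                    snp: maf(ds.genotypes.values[:, j])
                    for j, snp in enumerate(ds.genotypes.snps)}
                universe_mafs = {s: v for s, v in universe_mafs.items()
                                 if 0.0 < v <= 0.5}
                meqtl_snps &= set(universe_mafs)
                if not meqtl_snps:
                    continue
                res = enrichment_test(meqtl_snps, target, universe_mafs,
                                      cfg.enrichment_n_resamples, rng)
                fh.write(f"{ds.name}\t{res.observed_overlap}\t"
                         f"{mio.FLOAT_FMT % res.null_mean}\t"
                         f"{mio.FLOAT_FMT % res.null_sd}\t"
                         f"{mio.FLOAT_FMT % res.empirical_p}\t"
                         f"{mio.FLOAT_FMT % res.empirical_p_corrected}\t"
                         f"{res.reported_as}\n")
                enr_stage[ds.name] = {"observed": res.observed_overlap,
                                      "empirical_p": res.empirical_p}
                log.info("enrichment[%s]: observed %d, %s", ds.name,
                         res.observed_overlap, res.reported_as)
        manifest["stages"][stage] = enr_stage
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
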