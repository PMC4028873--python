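"""Readers and writers for the tabular formats the pipeline exchanges.

Formats:

* genotypes — VCF 4.x (GT field; read via :mod:`cyvcf2`) or a dosage TSV
  with rows = SNPs and columns = samples;
* methylation — a TSV with annotation columns followed by paired
  ``beta:<sample>`` / ``detp:<sample>`` columns, with per-sample mean
  intensities in ``##intensity`` header lines;
* association results — a sorted TSV, floats at 10 significant digits;
* target SNP sets — plain text, one rsID per line.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CpgAnnotation,
    GenotypeMatrix,
    MethylationMatrix,
    SnpAnnotation,
)

FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if x != x:  # NaN
        return "NA"
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> tuple[GenotypeMatrix, list[SnpAnnotation]]:
    """Read genotypes as reference-allele counts.

    ``format="vcf"`` parses the GT field of a VCF 4.x file; ``0/0`` is two
    reference alleles (count 2), ``1/1`` is zero. ``format="dosage_tsv"``
    expects columns ``snp_id chrom pos ref alt <sample...>`` holding counts
    already on the same convention ('NA' or '.' = missing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> tuple[GenotypeMatrix, list[SnpAnnotation]]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ValueError(f"{path}: cannot parse VCF: {exc}") from exc
    samples = list(vcf.samples)
    ann: list[SnpAnnotation] = []
    cols: list[np.ndarray] = []
    seen: set[str] = set()
    for i, var in enumerate(vcf, start=1):
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ValueError(f"{path}: duplicate snp_id {snp_id!r} at record {i}")
        seen.add(snp_id)
        alt = var.ALT[0] if var.ALT else None
        if alt is None:
            raise ValueError(f"{path}: record {i} ({snp_id}) has no ALT allele")
        ann.append(
            SnpAnnotation(snp_id=snp_id, chrom=str(var.CHROM), pos=int(var.POS),
                          ref_allele=str(var.REF), alt_allele=str(alt))
        )
        counts = np.full(len(samples), np.nan)
        for s, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a != -1]
            if len(alleles) == 2:
                counts[s] = sum(a == 0 for a in alleles)
        cols.append(counts)
    matrix = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=[a.snp_id for a in ann], values=matrix), ann


def _read_dosage_tsv(path: Path) -> tuple[GenotypeMatrix, list[SnpAnnotation]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chrom", "pos", "ref", "alt"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    samples = [c for c in df.columns if c not in required]
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"{path}: duplicate snp_id {dup!r}")
    ann = [
        SnpAnnotation(snp_id=r.snp_id, chrom=r.chrom, pos=int(r.pos),
                      ref_allele=r.ref, alt_allele=r.alt)
        for r in df.itertuples()
    ]
    vals = df[samples].replace({"NA": np.nan, ".": np.nan}).to_numpy(dtype=float)
    return GenotypeMatrix(samples=samples, snps=list(df["snp_id"]), values=vals.T), ann


def write_genotypes_vcf(g: GenotypeMatrix, ann: list[SnpAnnotation], path: str | Path) -> None:
    """Write hard GT calls; reference-allele count 2 -> 0/0, 1 -> 0/1, 0 -> 1/1."""
    gt_for = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}
    contigs = sorted({a.chrom for a in ann})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, a in enumerate(ann):
            calls = [gt_for.get(v, "./.") for v in g.values[:, j]]
            fh.write(f"{a.chrom}\t{a.pos}\t{a.snp_id}\t{a.ref_allele}\t{a.alt_allele}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def write_genotypes_dosage_tsv(g: GenotypeMatrix, ann: list[SnpAnnotation], path: str | Path) -> None:
    rows = []
    for j, a in enumerate(ann):
        row = {"snp_id": a.snp_id, "chrom": a.chrom, "pos": a.pos,
               "ref": a.ref_allele, "alt": a.alt_allele}
        for i, s in enumerate(g.samples):
            v = g.values[i, j]
            row[s] = "NA" if math.isnan(v) else str(int(v))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

_METH_ANN_COLS = ["cpg_id", "chrom", "pos", "probe_start", "probe_end"]


def read_methylation(path: str | Path) -> tuple[MethylationMatrix, list[CpgAnnotation]]:
    """Read a methylation TSV (β-values, detection p, per-sample intensity)."""
    path = Path(path)
    intensities: dict[str, float] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            skip += 1
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "##intensity" and len(parts) == 3:
                intensities[parts[1]] = float(parts[2])
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    for col in _METH_ANN_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    samples: list[str] = []
    for col in df.columns:
        if col in _METH_ANN_COLS:
            continue
        kind, _, sample = col.partition(":")
        if kind not in ("beta", "detp") or not sample:
            raise ValueError(f"{path}: unknown column {col!r}")
        if kind == "beta":
            samples.append(sample)
    for s in samples:
        if f"detp:{s}" not in df.columns:
            raise ValueError(f"{path}: sample {s!r} has beta but no detp column")
    ann = [
        CpgAnnotation(cpg_id=r.cpg_id, chrom=str(r.chrom), pos=int(r.pos),
                      probe_start=int(r.probe_start), probe_end=int(r.probe_end))
        for r in df.itertuples()
    ]
    beta = df[[f"beta:{s}" for s in samples]].to_numpy(dtype=float).T
    detp = df[[f"detp:{s}" for s in samples]].to_numpy(dtype=float).T
    finite = beta[~np.isnan(beta)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError(f"{path}: β-value outside [0, 1]")
    inten = np.array([intensities.get(s, np.nan) for s in samples])
    m = MethylationMatrix(samples=samples, cpgs=list(df["cpg_id"]),
                          beta=beta, detection_p=detp, intensity=inten)
    return m, ann


def write_methylation(m: MethylationMatrix, ann: list[CpgAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, v in zip(m.samples, m.intensity):
            fh.write(f"##intensity\t{s}\t{_fmt(float(v))}\n")
        header = list(_METH_ANN_COLS)
        for s in m.samples:
            header += [f"beta:{s}", f"detp:{s}"]
        fh.write("\t".join(header) + "\n")
        for j, a in enumerate(ann):
            row = [a.cpg_id, a.chrom, str(a.pos), str(a.probe_start), str(a.probe_end)]
            for i in range(len(m.samples)):
                row.append(_fmt(float(m.beta[i, j])))
                row.append(_fmt(float(m.detection_p[i, j])))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# association results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["snp_id", "cpg_id", "distance_bp", "beta_hat", "t", "df",
                  "p", "p_holm", "significant"]


def write_results(results: list, path: str | Path) -> None:
    """Write meQTL results as a TSV sorted by (snp_id, cpg_id)."""
    rows = sorted(results, key=lambda r: (r.pair.snp_id, r.pair.cpg_id))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.pair.snp_id, r.pair.cpg_id, str(r.pair.distance_bp),
                _fmt(r.beta_hat), _fmt(r.t), str(r.df),
                _fmt(r.p), _fmt(r.p_holm), str(bool(r.significant)),
            ]) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------

def read_snp_set(path: str | Path) -> set[str]:
    """Plain-text target SNP list, one rsID per line; '#' lines ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_snp_set(snps, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(snps):
            fh.write(s + "\n")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """BED (0-based half-open) intervals converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out
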