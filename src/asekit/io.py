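"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as a minimal VCF (CHROM, POS, ID, REF, ALT, GT
only; "|" separates phased alleles, "/" unphased) or as a TSV matrix
(rows = subjects, columns = SNP ids, cells 0/1/2/NA counting allele 1).
Peaks and covariates are plain CSV; the simulation truth is JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

PEAKS_COLUMNS = ["subject_id", "snp_id", "template", "prep", "duplicate",
                 "area_allele0", "area_allele1"]


class ParseError(ValueError):
    pass


def write_vcf(subjects, path: str | Path, *, chrom: str = "9",
              start_pos: int = 1000, spacing: int = 1000) -> None:
    """Write phased (or unphased) subject genotypes as a minimal VCF."""
    snp_ids = subjects[0].snp_ids
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(s.subject_id for s in subjects),
    ]
    for j, snp in enumerate(snp_ids):
        pos = start_pos + spacing * j
        gts = []
        for s in subjects:
            sep = "|" if s.phase_known else "/"
            gts.append(f"{int(s.haplotype_a[j])}{sep}{int(s.haplotype_b[j])}")
        lines.append(f"{chrom}\t{pos}\t{snp}\tA\tC\t.\t.\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, bool]:
    """Read the minimal VCF dialect into a subjects x SNPs 0/1/2 matrix.

    Returns the matrix and whether every genotype was phased.  Positions are
    kept as column metadata in ``frame.attrs["positions"]``.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}: duplicate subject ids in VCF header")
        snp_ids, positions, rows, phased_flags = [], [], [], []
        for rec in vf:
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append(rec.pos)
            row, phased = [], []
            for sample in samples:
                call = rec.samples[sample]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    row.append(np.nan)
                else:
                    row.append(float(sum(gt)))
                phased.append(bool(call.phased))
            rows.append(row)
            phased_flags.append(all(phased))
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{path}: duplicate SNP ids")
    frame = pd.DataFrame(np.array(rows).T, index=pd.Index(samples, name="subject_id"),
                         columns=snp_ids)
    frame.attrs["positions"] = dict(zip(snp_ids, positions))
    return frame, all(phased_flags)


def write_genotype_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    out = genotypes.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])
    raw.index = raw.index.astype(str)
    frame = raw.apply(pd.to_numeric, errors="coerce").astype(float)
    garbled = frame.isna() & raw.notna()
    if garbled.any().any():
        i, j = np.argwhere(garbled.to_numpy())[0]
        raise ParseError(
            f"{path}: unparseable genotype {raw.iat[i, j]!r} at line {i + 2}, "
            f"column {frame.columns[j]!r}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        lines = [i + 2 for i, s in enumerate(frame.index) if s in dupes]
        raise ParseError(f"{path}: duplicate subject ids {dupes} (lines {lines})")
    values = frame.to_numpy()
    bad = ~(np.isnan(values) | np.isin(values, [0.0, 1.0, 2.0]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid genotype code {values[i, j]!r} at line {i + 2}, "
            f"column {frame.columns[j]!r}")
    return frame


def read_genotypes(path: str | Path) -> tuple[pd.DataFrame, bool]:
    """Dispatch on extension: .vcf -> VCF reader, else TSV matrix."""
    p = Path(path)
    if p.suffix.lower() == ".vcf":
        return read_vcf(p)
    return read_genotype_tsv(p), False


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[PEAKS_COLUMNS].to_csv(path, index=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    peaks = pd.read_csv(path)
    missing = set(PEAKS_COLUMNS) - set(peaks.columns)
    if missing:
        raise ParseError(f"{path}: peaks CSV missing columns {sorted(missing)}")
    if (peaks[["area_allele0", "area_allele1"]] <= 0).any().any():
        bad = peaks.index[(peaks[["area_allele0", "area_allele1"]] <= 0).any(axis=1)]
        raise ParseError(f"{path}: non-positive peak areas at lines {[i + 2 for i in bad[:5]]}")
    return peaks


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, index_label="subject_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, index_col="subject_id")
    cov.index = cov.index.astype(str)
    for col in cov.columns:
        if col != "age":
            cov[col] = cov[col].astype(object).where(cov[col].notna(), None)
            cov[col] = cov[col].map(lambda v: str(v) if v is not None else None)
    return cov


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
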