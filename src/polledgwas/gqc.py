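"""Genotype quality control.

SNPs are removed when unmapped, on a sex chromosome, monomorphic, with minor
allele frequency below 5% or call rate below 90%; samples are removed when
their call rate is below 90%.  All removal rules are strict inequalities
("less than 5%", "lower than 90%"), so a SNP with MAF exactly 0.05 or a
sample with call rate exactly 0.90 is retained.  Rules are applied in a fixed
order — unmapped, sex chromosomes, sample call rate, SNP call rate,
monomorphic, MAF — and per-SNP statistics are recomputed after sample
removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

SEX_CHROM_LABELS = frozenset({"X", "Y", "XY", "MT", "M"})


class EmptyGenotypesError(ValueError):
    """All SNPs (or all samples) were removed by QC."""

    def __init__(self, msg: str, report: "QcReport"):
        super().__init__(msg)
        self.report = report


@dataclass
class QcThresholds:
    min_maf: float = 0.05
    min_snp_call_rate: float = 0.90
    min_sample_call_rate: float = 0.90
    autosomes_only: bool = True
    drop_unmapped: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_snp_call_rate", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    """Per-rule removal counts, in application order."""

    n_snps_in: int = 0
    n_samples_in: int = 0
    snps_unmapped: int = 0
    snps_sex_chrom: int = 0
    samples_low_call_rate: int = 0
    snps_low_call_rate: int = 0
    snps_monomorphic: int = 0
    snps_low_maf: int = 0
    n_snps_out: int = 0
    n_samples_out: int = 0
    rule_order: tuple = (
        "unmapped",
        "sex_chromosomes",
        "sample_call_rate",
        "snp_call_rate",
        "monomorphic",
        "maf",
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", "snps", self.n_snps_in),
            ("input", "samples", self.n_samples_in),
            ("unmapped", "snps", self.snps_unmapped),
            ("sex_chromosomes", "snps", self.snps_sex_chrom),
            ("sample_call_rate", "samples", self.samples_low_call_rate),
            ("snp_call_rate", "snps", self.snps_low_call_rate),
            ("monomorphic", "snps", self.snps_monomorphic),
            ("maf", "snps", self.snps_low_maf),
            ("retained", "snps", self.n_snps_out),
            ("retained", "samples", self.n_samples_out),
        ]
        return pd.DataFrame(rows, columns=["rule", "axis", "count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _is_unmapped(snp_map: pd.DataFrame) -> np.ndarray:
    chrom = snp_map["chrom"].astype(str).str.strip()
    bp = snp_map["bp"].values
    return (chrom.isin(["0", ""]) | chrom.isna()).values | (bp <= 0)


def _is_sex_chrom(snp_map: pd.DataFrame) -> np.ndarray:
    chrom = snp_map["chrom"].astype(str).str.strip().str.upper()
    return chrom.isin(SEX_CHROM_LABELS).values


def qc_filter(geno: GenotypeMatrix, thr: QcThresholds | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the QC rules; return the filtered matrix and a removal report.

    The rule sequence is repeated until nothing more is removed (removing a
    SNP shifts sample call rates and vice versa, so a single pass can leave a
    sample or SNP marginally below threshold); this makes the filter
    idempotent.  Counts in the report accumulate per rule across passes.
    """
    thr = thr or QcThresholds()
    report = QcReport(n_snps_in=geno.n_snps, n_samples_in=geno.n_animals)
    g = geno
    while True:
        g, changed = _qc_pass(g, thr, report)
        if not changed:
            break
    report.n_snps_out = g.n_snps
    report.n_samples_out = g.n_animals
    if g.n_snps == 0:
        raise EmptyGenotypesError("QC removed every SNP", report)
    return g, report


def _qc_pass(
    geno: GenotypeMatrix, thr: QcThresholds, report: QcReport
) -> tuple[GenotypeMatrix, bool]:
    keep_snp = np.ones(geno.n_snps, dtype=bool)
    if thr.drop_unmapped:
        bad = _is_unmapped(geno.snp_map) & keep_snp
        report.snps_unmapped += int(bad.sum())
        keep_snp &= ~bad
    if thr.autosomes_only:
        bad = _is_sex_chrom(geno.snp_map) & keep_snp
        report.snps_sex_chrom += int(bad.sum())
        keep_snp &= ~bad

    g = geno.subset(snps=keep_snp)
    changed = g.n_snps != geno.n_snps

    # sample call rate on the mapped autosomal SNPs
    keep_sample = np.ones(g.n_animals, dtype=bool)
    if g.n_snps > 0 and g.n_animals > 0:
        keep_sample = g.sample_call_rate() >= thr.min_sample_call_rate
    report.samples_low_call_rate += int((~keep_sample).sum())
    changed |= not keep_sample.all()
    g = g.subset(animals=keep_sample)

    # per-SNP statistics recomputed on the retained samples
    if g.n_animals > 0 and g.n_snps > 0:
        cr = g.snp_call_rate()
        bad_cr = cr < thr.min_snp_call_rate
        report.snps_low_call_rate += int(bad_cr.sum())
        changed |= bool(bad_cr.any())
        g = g.subset(snps=~bad_cr)

        if thr.drop_monomorphic and g.n_snps > 0:
            maf = g.maf()
            mono = np.isnan(maf) | (maf == 0.0)
            report.snps_monomorphic += int(mono.sum())
            changed |= bool(mono.any())
            g = g.subset(snps=~mono)

        if g.n_snps > 0:
            maf = g.maf()
            low = maf < thr.min_maf
            report.snps_low_maf += int(low.sum())
            changed |= bool(low.any())
            g = g.subset(snps=~low)

    return g, changed
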