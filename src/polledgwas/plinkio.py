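"""Text I/O: PLINK PED/MAP genotypes, pedigree CSV, phenotype TSV.

PED rows are ``FID IID PAT MAT SEX PHENO`` followed by two allele calls per
SNP (``A``/``B``, ``0`` = missing).  MAP rows are ``chrom snp cM bp``.  The
internal genotype code is the count of the B allele.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

PED_COLS = ["fid", "iid", "pat", "mat", "sex", "pheno"]


def write_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": snp_map["chrom"],
            "snp": snp_map["snp"],
            "cm": 0,
            "bp": snp_map["bp"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp"],
        dtype={"chrom": str, "snp": str},
    )
    return pd.DataFrame({"snp": m["snp"], "chrom": m["chrom"], "bp": m["bp"].astype(np.int64)})


def write_ped(geno: GenotypeMatrix, path: str | Path) -> None:
    n, m = geno.M.shape
    # genotype code -> two allele characters
    allele1 = np.where(geno.M >= 1, "B", "A")
    allele2 = np.where(geno.M == 2, "B", "A")
    miss = geno.M == MISSING
    allele1[miss] = "0"
    allele2[miss] = "0"
    with open(path, "w") as fh:
        for i in range(n):
            aid = geno.animal_ids[i]
            fields = ["0", str(aid), "0", "0", "0", "-9"]
            pairs = np.empty(2 * m, dtype=allele1.dtype)
            pairs[0::2] = allele1[i]
            pairs[1::2] = allele2[i]
            fh.write(" ".join(fields) + " " + " ".join(pairs) + "\n")


def read_ped(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    snp_map = read_map(map_path)
    m = len(snp_map)
    ids = []
    rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, expected {6 + 2 * m}"
                )
            ids.append(int(parts[1]))
            alleles = np.array(parts[6:], dtype="U1").reshape(m, 2)
            miss = (alleles == "0").any(axis=1)
            code = (alleles == "B").sum(axis=1).astype(np.int8)
            code[miss] = MISSING
            rows.append(code)
    M = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    return GenotypeMatrix(animal_ids=np.array(ids, dtype=np.int64), snp_map=snp_map, M=M)


def write_pedigree(ped: pd.DataFrame, path: str | Path) -> None:
    ped[["animal", "sire", "dam"]].to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"animal", "sire", "dam"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: pedigree CSV must have columns {sorted(expected)}")
    return df[["animal", "sire", "dam"]].astype(np.int64)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno[["animal", "category"]].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = ~df["category"].isin([1, 2])
    if bad.any():
        raise ValueError(f"{path}: phenotype categories must be 1 (horned) or 2 (polled)")
    return df[["animal", "category"]].astype(np.int64)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) of gene/feature intervals.

    Returns a DataFrame with 1-based inclusive ``start``/``end`` columns to
    match the package-internal coordinate convention.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 tab-separated fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((parts[0], start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write intervals held 1-based inclusive as BED (0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
        }
    )
    if name_col is not None and name_col in df:
        out["name"] = df[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)
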