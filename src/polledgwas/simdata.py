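"""Synthetic pedigreed population with a liability-threshold horned/polled trait.

The generator emulates the data structure the downstream analysis assumes:

* a multi-generation pedigree in which only a subset of animals is genotyped
  (the single-step scenario),
* a dense SNP map over several autosomes,
* one major dominant causal locus near the start of one chromosome whose
  carriers express the "polled" category (2) at a target prevalence,
* very high liability-scale heritability (polygenic background plus the
  major locus).

Genotypes are gene-dropped through the pedigree with recombination (Haldane
map function, 1 cM/Mb by default), so Mendelian structure matches the
pedigree relationship matrix A.  Founder haplotypes are in linkage
equilibrium except around the causal locus: every haplotype carrying the
causal allele also carries one conserved flanking haplotype block, emulating
a single mutation origin.  Homozygous carriers are therefore homozygous
across the block, which is what makes the causal region detectable as a
runs-of-homozygosity island and gives the SNPs around the locus the linkage
disequilibrium a real association peak rests on.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeMatrix
from . import plinkio


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generation parameters for the synthetic population.

    Defaults give a desk-scale population of 1,000 animals (200 founders plus
    four generations of 200), five 10 Mb autosomes with 400 evenly spaced
    SNPs each, a dominant causal locus at 1.5 Mb on chromosome 1, polled
    prevalence 0.137 and a polygenic liability heritability of 0.8 on top of
    a large (8 liability-SD) causal effect, so total liability-scale
    heritability is very high.  The causal allele frequency (0.2) exceeds the
    value that would give 13.7% carriers under Hardy-Weinberg; the liability
    threshold then sits inside the carrier cluster, i.e. penetrance is
    incomplete, which matches the view that polledness in indicine cattle is
    not a clean one-locus Mendelian trait and, practically, keeps causal-
    haplotype homozygotes frequent enough for the ROH analysis to see them.
    """

    n_founders: int = 200
    n_generations: int = 4
    n_offspring_per_mating: int = 2
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    n_snps_per_chrom: int = 400
    causal_chrom: int = 1
    causal_pos_bp: int = 1_500_000
    causal_allele_freq: float = 0.20
    causal_block_bp: int = 3_000_000
    causal_effect: float = 8.0
    dominance_mode: str = "dominant"
    target_prevalence: float = 0.137
    h2_liability: float = 0.8
    genotyped_fraction: float = 0.4
    genotype_missing_rate: float = 0.01
    founder_maf_range: tuple = (0.05, 0.5)
    recomb_cm_per_mb: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_founders < 2:
            raise InvalidConfigError("n_founders must be >= 2")
        if self.n_generations < 0 or self.n_offspring_per_mating < 1:
            raise InvalidConfigError("generation counts must be non-negative")
        if self.n_snps_per_chrom < 2:
            raise InvalidConfigError("n_snps_per_chrom must be >= 2")
        if not 0 < self.target_prevalence < 1:
            raise InvalidConfigError("target_prevalence must be strictly inside (0, 1)")
        if not 0 <= self.h2_liability <= 1:
            raise InvalidConfigError("h2_liability must be in [0, 1]")
        for name in ("causal_allele_freq", "genotyped_fraction", "genotype_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if not 1 <= self.causal_chrom <= self.n_chromosomes:
            raise InvalidConfigError("causal_chrom out of range")
        if not 1 <= self.causal_pos_bp <= self.chrom_length_bp:
            raise InvalidConfigError("causal_pos_bp must lie on the chromosome")
        if self.dominance_mode not in ("dominant", "additive"):
            raise InvalidConfigError("dominance_mode must be 'dominant' or 'additive'")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("founder_maf_range must satisfy 0 < lo <= hi <= 0.5")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["founder_maf_range"] = list(self.founder_maf_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "founder_maf_range" in d:
            d["founder_maf_range"] = tuple(d["founder_maf_range"])
        return cls(**d)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per pipeline stage
    return np.random.default_rng([stage, config.seed])


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Random-mating pedigree: founders (generation 0) plus discrete generations.

    Each generation the previous generation is shuffled and paired into
    disjoint sire/dam couples; each couple leaves ``n_offspring_per_mating``
    offspring.  Ids are assigned in birth order, so parents always precede
    offspring.
    """
    config.validate()
    rng = _rng(config, 1)
    records = [(i + 1, 0, 0, 0) for i in range(config.n_founders)]
    prev = np.arange(1, config.n_founders + 1)
    next_id = config.n_founders + 1
    for g in range(1, config.n_generations + 1):
        perm = rng.permutation(prev)
        cur = []
        for k in range(len(perm) // 2):
            sire, dam = int(perm[2 * k]), int(perm[2 * k + 1])
            for _ in range(config.n_offspring_per_mating):
                records.append((next_id, sire, dam, g))
                cur.append(next_id)
                next_id += 1
        prev = np.array(cur, dtype=np.int64)
        if len(prev) < 2:
            break
    return pd.DataFrame(records, columns=["animal", "sire", "dam", "generation"])


def build_snp_map(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced SNP grid; the causal locus is the map SNP nearest its position."""
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        pos = np.linspace(1, config.chrom_length_bp, config.n_snps_per_chrom).round().astype(np.int64)
        pos = np.unique(pos)
        for j, bp in enumerate(pos):
            rows.append((f"snp{c}_{j + 1}", str(c), int(bp)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "bp"])


def causal_snp_index(snp_map: pd.DataFrame, config: SimConfig) -> int:
    on_chrom = snp_map["chrom"] == str(config.causal_chrom)
    idx = np.flatnonzero(on_chrom.values)
    bp = snp_map.loc[on_chrom, "bp"].values
    return int(idx[np.argmin(np.abs(bp - config.causal_pos_bp))])


def _founder_haplotypes(config: SimConfig, snp_map: pd.DataFrame, rng: np.random.Generator, n_founders: int):
    m = len(snp_map)
    n_hap = 2 * n_founders
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=m)
    ci = causal_snp_index(snp_map, config)
    p[ci] = config.causal_allele_freq

    H = (rng.random((n_hap, m)) < p).astype(np.int8)

    # conserved haplotype block around the causal allele: single mutation origin
    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.int64)
    half = config.causal_block_bp // 2
    in_block = (chrom == str(config.causal_chrom)) & (
        np.abs(bp - bp[ci]) <= half
    )
    # The conserved block carries the major allele at every flanking SNP:
    # carrier haplotypes are then identical over the block (homozygous
    # carriers show a run of homozygosity there) while per-SNP association
    # with the causal allele stays weak away from the causal SNP itself,
    # standing in for the LD decay of real data.
    block_pattern = np.zeros(int(in_block.sum()), dtype=np.int8)
    carriers = H[:, ci] == 1
    H[np.ix_(carriers, np.flatnonzero(in_block))] = block_pattern
    H[carriers, ci] = 1
    return H, p, ci


def _recomb_prob(snp_map: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """Recombination probability between adjacent map SNPs (Haldane).

    The first entry of each chromosome is 0.5 (independent chromosomes).
    """
    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.float64)
    d_morgan = np.diff(bp, prepend=bp[0]) * cm_per_mb * 1e-8
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    new_chrom = np.empty(len(chrom), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    r[new_chrom] = 0.5
    return r


def _gamete(parent_hap: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One meiosis: mosaic of the parent's two haplotypes with crossovers at rate r."""
    switches = rng.random(r.size) < r
    which = np.cumsum(switches) % 2  # starts uniformly because r[0] = 0.5 resolves chrom starts
    if rng.random() < 0.5:
        which = 1 - which
    return parent_hap[which, np.arange(r.size)]


def gene_drop(ped: pd.DataFrame, config: SimConfig):
    """Drop founder haplotypes through the pedigree.

    Returns (haplotypes (n_animals, 2, m) int8 for every pedigree animal in
    id order, snp_map, founder allele freqs, causal SNP column index).
    """
    rng = _rng(config, 2)
    snp_map = build_snp_map(config)
    n_founders = int(((ped["sire"] == 0) & (ped["dam"] == 0)).sum())
    H_founder, p, ci = _founder_haplotypes(config, snp_map, rng, n_founders)
    r = _recomb_prob(snp_map, config.recomb_cm_per_mb)

    n = len(ped)
    m = len(snp_map)
    idx_of = {a: i for i, a in enumerate(ped["animal"].values)}
    hap = np.zeros((n, 2, m), dtype=np.int8)
    founder_no = 0
    for i, (animal, sire, dam) in enumerate(ped[["animal", "sire", "dam"]].itertuples(index=False)):
        if sire == 0 and dam == 0:
            hap[i, 0] = H_founder[2 * founder_no]
            hap[i, 1] = H_founder[2 * founder_no + 1]
            founder_no += 1
        else:
            hap[i, 0] = _gamete(hap[idx_of[sire]], r, rng)
            hap[i, 1] = _gamete(hap[idx_of[dam]], r, rng)
    return hap, snp_map, p, ci


def drop_genotypes(ped: pd.DataFrame, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop genotypes; return the matrix for the genotyped subset only.

    Only ``genotyped_fraction`` of non-founder animals carry genotypes (the
    single-step scenario); missing calls are injected at
    ``genotype_missing_rate``.  Causal-locus dosages of *all* animals are
    kept on the returned object for phenotype assignment.
    """
    config.validate()
    hap, snp_map, _, ci = gene_drop(ped, config)
    rng = _rng(config, 3)

    dosage_all = hap.sum(axis=1)  # (n_animals, m)
    causal = {int(a): int(d) for a, d in zip(ped["animal"].values, dosage_all[:, ci])}

    non_founders = ped.index[(ped["sire"] != 0) | (ped["dam"] != 0)].values
    n_geno = int(round(config.genotyped_fraction * len(non_founders)))
    chosen = np.sort(rng.choice(non_founders, size=n_geno, replace=False))

    M = dosage_all[chosen].astype(np.int8)
    if config.genotype_missing_rate > 0 and M.size:
        miss = rng.random(M.shape) < config.genotype_missing_rate
        M[miss] = MISSING
    return GenotypeMatrix(
        animal_ids=ped["animal"].values[chosen],
        snp_map=snp_map,
        M=M,
        causal_dosage=causal,
    )


def assign_phenotypes(ped: pd.DataFrame, geno: GenotypeMatrix, config: SimConfig) -> pd.DataFrame:
    """Liability-threshold phenotypes: category 2 ("polled") iff liability > threshold.

    liability = polygenic breeding value (variance ``h2_liability``, simulated
    by pedigree gene dropping of breeding values with Mendelian-sampling
    variance shrunk by parental inbreeding) + causal-locus effect + residual
    (variance ``1 - h2_liability``).  The threshold is the empirical
    ``1 - target_prevalence`` quantile of the realized liabilities, so the
    expected prevalence of category 2 equals the target exactly under the
    mixed causal + polygenic model.

    The returned frame carries the simulation truth (breeding values,
    liabilities, threshold) in ``.attrs["truth"]`` for validation.
    """
    config.validate()
    if geno.causal_dosage is None:
        raise ValueError("genotype matrix lacks causal-locus bookkeeping (not simulated?)")
    from .relmat import inbreeding_coefficients

    rng = _rng(config, 4)
    h2 = config.h2_liability
    n = len(ped)
    F = inbreeding_coefficients(ped)
    idx_of = {a: i for i, a in enumerate(ped["animal"].values)}

    bv = np.zeros(n)
    for i, (animal, sire, dam) in enumerate(ped[["animal", "sire", "dam"]].itertuples(index=False)):
        if sire == 0 and dam == 0:
            bv[i] = rng.normal(0.0, np.sqrt(h2)) if h2 > 0 else 0.0
        else:
            si, di = idx_of[sire], idx_of[dam]
            ms_var = 0.5 * h2 * (1.0 - 0.5 * (F[si] + F[di]))
            bv[i] = 0.5 * (bv[si] + bv[di]) + (
                rng.normal(0.0, np.sqrt(ms_var)) if ms_var > 0 else 0.0
            )

    dose = np.array([geno.causal_dosage[int(a)] for a in ped["animal"].values], dtype=float)
    if config.dominance_mode == "dominant":
        causal = config.causal_effect * (dose > 0)
    else:
        causal = config.causal_effect * dose / 2.0

    resid_sd = np.sqrt(max(1.0 - h2, 0.0))
    liab = bv + causal + (rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else 0.0)
    threshold = float(np.quantile(liab, 1.0 - config.target_prevalence))
    category = np.where(liab > threshold, 2, 1)

    pheno = pd.DataFrame({"animal": ped["animal"].values, "category": category.astype(np.int64)})
    pheno.attrs["truth"] = pd.DataFrame(
        {
            "animal": ped["animal"].values,
            "bv": bv,
            "causal_dosage": dose,
            "liability": liab,
        }
    )
    pheno.attrs["threshold"] = threshold
    return pheno


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: pd.DataFrame = field(repr=False, default=None)
    causal_snp: str = ""

    @property
    def causal_index(self) -> int:
        return int(np.flatnonzero(self.genotypes.snp_map["snp"] == self.causal_snp)[0])


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full generation pass: pedigree, genotypes, phenotypes."""
    ped = simulate_pedigree(config)
    geno = drop_genotypes(ped, config)
    pheno = assign_phenotypes(ped, geno, config)
    ci = causal_snp_index(geno.snp_map, config)
    return SimulatedDataset(
        config=config,
        pedigree=ped,
        genotypes=geno,
        phenotypes=pheno,
        truth=pheno.attrs["truth"],
        causal_snp=str(geno.snp_map["snp"].iloc[ci]),
    )


def write_dataset(
    ped: pd.DataFrame,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    outdir: str | Path,
    config: SimConfig | None = None,
) -> dict:
    """Write pedigree CSV, PLINK PED/MAP, phenotype TSV (and the config YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "ped": outdir / "genotypes.ped",
        "map": outdir / "genotypes.map",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    plinkio.write_pedigree(ped, paths["pedigree"])
    plinkio.write_ped(geno, paths["ped"])
    plinkio.write_map(geno.snp_map, paths["map"])
    plinkio.write_phenotypes(pheno, paths["phenotypes"])
    if config is not None:
        paths["config"] = outdir / "sim_config.yaml"
        config.to_yaml(paths["config"])
    return paths


def read_dataset(outdir: str | Path):
    outdir = Path(outdir)
    ped = plinkio.read_pedigree(outdir / "pedigree.csv")
    geno = plinkio.read_ped(outdir / "genotypes.ped", outdir / "genotypes.map")
    pheno = plinkio.read_phenotypes(outdir / "phenotypes.tsv")
    return ped, geno, pheno
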