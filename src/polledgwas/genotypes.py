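"""In-memory container for coded SNP genotypes with map positions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # internal missing-genotype code


@dataclass
class GenotypeMatrix:
    """Coded genotypes (counts of the B allele) for a set of animals.

    Attributes
    ----------
    animal_ids:
        Integer ids of the genotyped animals (rows), in row order.
    snp_map:
        DataFrame with columns ``snp``, ``chrom`` (string label), ``bp``
        (1-based position), one row per SNP in column order, sorted by
        (chrom, bp) within each chromosome block.
    M:
        ``int8`` array of shape (n_animals, n_snps) with values 0/1/2 and
        ``-1`` for missing.
    causal_dosage:
        Optional mapping animal id -> causal-locus dosage for *every*
        pedigree animal (simulation bookkeeping; the causal locus genotype is
        needed for phenotype assignment even for animals that never enter the
        genotype panel).
    """

    animal_ids: np.ndarray
    snp_map: pd.DataFrame
    M: np.ndarray
    causal_dosage: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.M.shape != (len(self.animal_ids), len(self.snp_map)):
            raise ValueError(
                f"genotype matrix shape {self.M.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.snp_map)} SNPs"
            )

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency p_i of the B allele per SNP, from non-missing genotypes.

        SNPs with no observed genotypes get ``nan``.
        """
        obs = self.M >= 0
        counts = obs.sum(axis=0)
        dose = np.where(obs, self.M, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose / (2.0 * counts)
        return np.where(counts > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return (self.M >= 0).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return (self.M >= 0).mean(axis=1)

    def centered(self, p: np.ndarray | None = None) -> np.ndarray:
        """Centered matrix Z = M - 2p with missing genotypes mean-imputed.

        Mean imputation (replacing a missing genotype by 2p before
        centering, i.e. by 0 after) preserves zero column means.
        """
        if p is None:
            p = self.allele_freqs()
        Z = self.M.astype(np.float64)
        Z[self.M == MISSING] = 0.0
        Z -= np.where(self.M == MISSING, 0.0, 2.0 * p)
        return Z

    def subset(self, animals: np.ndarray | None = None, snps: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or index array."""
        a_idx = np.arange(self.n_animals) if animals is None else np.asarray(animals)
        s_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if a_idx.dtype == bool:
            a_idx = np.flatnonzero(a_idx)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[a_idx],
            snp_map=self.snp_map.iloc[s_idx].reset_index(drop=True),
            M=self.M[np.ix_(a_idx, s_idx)],
            causal_dosage=self.causal_dosage,
        )
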