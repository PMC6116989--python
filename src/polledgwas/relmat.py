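"""Pedigree, genomic and combined relationship matrices.

* ``build_A``: tabular (recursive) numerator relationship matrix, diagonal
  1 + F_i.
* ``build_A_inverse``: Henderson rules with inbreeding (Mendelian-sampling
  variances from the tabular inbreeding coefficients).
* ``build_G``: (weighted) genomic relationship matrix G* = Z D Z' lambda with
  lambda = 1 / sum_i 2 p_i (1 - p_i), i.e. VanRaden method 1 when D = I.
* ``build_H_inverse``: single-step combined inverse
  H^-1 = A^-1 + [0 0; 0 G_blend^-1 - A22^-1] on the genotyped block, with
  G_blend = (1 - blend) G* + blend A22 for invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .genotypes import GenotypeMatrix


class CyclicPedigreeError(ValueError):
    pass


class DegenerateFrequencyError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Liability-scale variance components with unit total variance."""

    sigma2_a: float
    sigma2_e: float

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)

    @classmethod
    def from_h2(cls, h2: float) -> "VarianceComponents":
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        return cls(sigma2_a=h2, sigma2_e=1.0 - h2)

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")


def _parent_indices(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """0-based parent index arrays (-1 unknown); verifies parents precede offspring."""
    animals = ped["animal"].values
    idx_of = {int(a): i for i, a in enumerate(animals)}
    n = len(animals)
    si = np.full(n, -1, dtype=np.int64)
    di = np.full(n, -1, dtype=np.int64)
    for i, (a, s, d) in enumerate(ped[["animal", "sire", "dam"]].itertuples(index=False)):
        for code, arr in ((s, si), (d, di)):
            if code == 0:
                continue
            j = idx_of.get(int(code))
            if j is None:
                raise ValueError(f"parent {code} of animal {a} is not in the pedigree")
            if j >= i:
                raise CyclicPedigreeError(
                    f"parent {code} does not precede offspring {a}; pedigree is not sorted or is cyclic"
                )
            arr[i] = j
    return si, di


@njit(cache=True)
def _tabular_A(si, di):  # pragma: no cover - numba
    n = si.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[s, j]
            if d >= 0:
                aij += 0.5 * A[d, j]
            A[i, j] = aij
            A[j, i] = aij
        dii = 1.0
        if s >= 0 and d >= 0:
            dii += 0.5 * A[s, d]
        A[i, i] = dii
    return A


def build_A(ped: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix in pedigree order; a(i,i) = 1 + F_i."""
    si, di = _parent_indices(ped)
    return _tabular_A(si, di)


def inbreeding_coefficients(ped: pd.DataFrame) -> np.ndarray:
    return np.diag(build_A(ped)) - 1.0


def build_A_inverse(ped: pd.DataFrame) -> sparse.csr_matrix:
    """A^-1 by Henderson rules, with inbreeding.

    Mendelian-sampling variances use the exact inbreeding coefficients from
    the tabular A, so the result equals the dense inverse of ``build_A`` on
    any pedigree (inbred ones included).
    """
    si, di = _parent_indices(ped)
    F = np.diag(_tabular_A(si, di)) - 1.0
    n = si.size
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = si[i], di[i]
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            msv = 0.5 - 0.25 * (fs + fd)
        elif s >= 0 or d >= 0:
            msv = 0.75 - 0.25 * (fs if s >= 0 else fd)
        else:
            msv = 1.0
        alpha = 1.0 / msv
        add(i, i, alpha)
        for par in (s, d):
            if par >= 0:
                add(i, par, -0.5 * alpha)
                add(par, i, -0.5 * alpha)
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 >= 0 and p2 >= 0:
                    add(p1, p2, 0.25 * alpha)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def compute_lambda(p: np.ndarray) -> float:
    """Normalizing constant lambda = 1 / sum_i 2 p_i (1 - p_i)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)) or p.size == 0:
        raise DegenerateFrequencyError("allele frequencies must lie strictly in (0, 1)")
    return float(1.0 / np.sum(2.0 * p * (1.0 - p)))


def build_G(Z: np.ndarray, p: np.ndarray, D: np.ndarray | None = None) -> np.ndarray:
    """Weighted genomic relationship matrix G* = Z D Z' lambda.

    ``D`` is the per-SNP weight vector (diagonal of the weight matrix);
    omitted D means D = I, which gives the VanRaden method-1 G.
    """
    Z = np.asarray(Z, dtype=float)
    lam = compute_lambda(p)
    if Z.shape[1] != len(p):
        raise ValueError("Z and p disagree on the number of SNPs")
    if D is None:
        ZD = Z
    else:
        D = np.asarray(D, dtype=float)
        if D.shape != (Z.shape[1],):
            raise ValueError("D must be a per-SNP weight vector")
        ZD = Z * D
    return (ZD @ Z.T) * lam


def blend_G(G_star: np.ndarray, A22: np.ndarray, blend: float = 0.05) -> np.ndarray:
    """G_blend = (1 - blend) G* + blend A22 (keeps the genomic block invertible)."""
    if not 0 <= blend <= 1:
        raise ValueError("blend must be in [0, 1]")
    return (1.0 - blend) * G_star + blend * A22


def build_H_inverse(
    A_inv: sparse.spmatrix | np.ndarray,
    A22: np.ndarray,
    G_star: np.ndarray,
    geno_idx: np.ndarray,
    blend: float = 0.05,
) -> np.ndarray:
    """Combined single-step inverse relationship matrix (dense).

    H^-1 = A^-1 + [0 0; 0 G_blend^-1 - A22^-1] where the corner block sits on
    the genotyped animals ``geno_idx`` (indices into the pedigree ordering).
    """
    H = A_inv.toarray() if sparse.issparse(A_inv) else np.array(A_inv, dtype=float, copy=True)
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    if geno_idx.size == 0:
        return H
    Gb = blend_G(G_star, A22, blend)
    try:
        Gb_inv = np.linalg.inv(Gb)
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"genomic block singular even at blend={blend}; increase blending"
        ) from exc
    H[np.ix_(geno_idx, geno_idx)] += Gb_inv - A22_inv
    return H


@dataclass
class RelationshipMatrices:
    """All matrices needed downstream, in pedigree order."""

    animal_ids: np.ndarray
    geno_idx: np.ndarray  # positions of genotyped animals within the pedigree ordering
    A: np.ndarray
    A_inv: sparse.csr_matrix
    A22: np.ndarray
    G_star: np.ndarray
    H_inv: np.ndarray
    p: np.ndarray
    lambda_norm: float
    Z: np.ndarray
    blend: float


def build_relationships(
    ped: pd.DataFrame,
    geno: GenotypeMatrix,
    D: np.ndarray | None = None,
    blend: float = 0.05,
) -> RelationshipMatrices:
    """Assemble A, A^-1, A22, G*, H^-1 for a pedigree + genotyped subset.

    Allele frequencies are computed from the genotyped animals (post QC);
    missing genotypes are mean-imputed in the centered Z.
    """
    animals = ped["animal"].values
    idx_of = {int(a): i for i, a in enumerate(animals)}
    missing = [int(a) for a in geno.animal_ids if int(a) not in idx_of]
    if missing:
        raise ValueError(f"genotyped animals absent from pedigree: {missing[:5]}...")
    geno_idx = np.array([idx_of[int(a)] for a in geno.animal_ids], dtype=np.int64)

    A = build_A(ped)
    A_inv = build_A_inverse(ped)
    A22 = A[np.ix_(geno_idx, geno_idx)]

    p = geno.allele_freqs()
    # guard against fixed alleles slipping past QC
    p = np.clip(p, 1e-8, 1 - 1e-8)
    Z = geno.centered(p)
    G_star = build_G(Z, p, D)
    H_inv = build_H_inverse(A_inv, A22, G_star, geno_idx, blend)
    return RelationshipMatrices(
        animal_ids=animals,
        geno_idx=geno_idx,
        A=A,
        A_inv=A_inv,
        A22=A22,
        G_star=G_star,
        H_inv=H_inv,
        p=p,
        lambda_norm=compute_lambda(p),
        Z=Z,
        blend=blend,
    )
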