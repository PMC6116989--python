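"""Weighted single-step GWAS: SNP effects from GEBV, reweighting, 1 Mb windows.

SNP effects are backsolved from the GEBV of the genotyped animals,

    u_hat = lambda D Z' G*^-1 a_g_hat = D Z' [Z D Z']^-1 a_g_hat,

each SNP's variance is u_hat_i^2 * 2 p_i (1 - p_i), and these variances become
the next diagonal weight matrix D after normalization that keeps the total
additive variance constant.  The iteration is:

  1. D = I
  2. build G* = Z D Z' lambda (blended for invertibility)
  3. estimate GEBV for all animals by single-step threshold-model GBLUP
  4. backsolve SNP effects
  5. per-SNP variances
  6. normalize D
  7. back to 2; by default one loop (two passes in total).

Windows of consecutive SNPs spanning at most 1 Mb partition the additive
variance: the share of window w is 100 * var(sum_{j in w} z_j u_hat_j) /
sigma2_a, the empirical variance taken across genotyped individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .relmat import (
    RelationshipMatrices,
    VarianceComponents,
    blend_G,
    build_relationships,
    compute_lambda,
)
from .tgibbs import GibbsConfig, run_gibbs

WINDOW_BP = 1_000_000


class SingularBacksolveError(np.linalg.LinAlgError):
    pass


@dataclass
class SnpEffectSet:
    iteration: int
    snp_map: pd.DataFrame
    u_hat: np.ndarray
    var_u_hat: np.ndarray
    weights: np.ndarray  # the D used to obtain these effects
    gebv: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.snp_map.copy()
        out["u_hat"] = self.u_hat
        out["var_u_hat"] = self.var_u_hat
        out["weight"] = self.weights
        out["iteration"] = self.iteration
        return out


@dataclass
class WindowResult:
    chrom: str
    start_bp: int
    end_bp: int
    snp_count: int
    var_share_pct: float
    snp_ids: list
    first_snp_index: int  # map index of the first member SNP


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    total_var_share_pct: float
    source: str = "gwas"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def backsolve_snp_effects(
    a_g_hat: np.ndarray,
    Z: np.ndarray,
    D: np.ndarray | None = None,
    G_star_inv: np.ndarray | None = None,
    lam: float | None = None,
) -> np.ndarray:
    """u_hat = D Z' [Z D Z']^-1 a_g_hat.

    When ``G_star_inv`` (the inverse of the — possibly blended — G*) is
    supplied together with ``lam``, the equivalent first form
    u_hat = lambda D Z' G*^-1 a_g_hat is used; with an unblended G* the two
    forms coincide.
    """
    Z = np.asarray(Z, dtype=float)
    a_g_hat = np.asarray(a_g_hat, dtype=float)
    d = np.ones(Z.shape[1]) if D is None else np.asarray(D, dtype=float)
    if G_star_inv is not None:
        if lam is None:
            raise ValueError("lam is required with a precomputed G* inverse")
        return lam * d * (Z.T @ (G_star_inv @ a_g_hat))
    ZDZt = (Z * d) @ Z.T
    try:
        sol = np.linalg.solve(ZDZt, a_g_hat)
    except np.linalg.LinAlgError as exc:
        raise SingularBacksolveError(
            "Z D Z' is singular; blend the genomic relationship matrix"
        ) from exc
    return d * (Z.T @ sol)


def snp_variances(u_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-SNP variance sigma2_u_hat_i = u_hat_i^2 * 2 p_i (1 - p_i)."""
    u_hat = np.asarray(u_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    return u_hat**2 * 2.0 * p * (1.0 - p)


def normalize_weights(raw: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rescale raw per-SNP variances into weights that conserve total variance.

    d_i is proportional to raw_i with sum_i d_i 2 p_i (1 - p_i) equal to
    sum_i 2 p_i (1 - p_i); an all-zero raw vector falls back to D = I.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw variances must be non-negative")
    het = 2.0 * np.asarray(p) * (1.0 - np.asarray(p))
    total = het.sum()
    denom = float(raw @ het)
    if denom == 0.0:
        import warnings

        warnings.warn("all SNP variances are zero; falling back to D = I")
        return np.ones_like(raw)
    return raw * (total / denom)


def sliding_windows(snp_map: pd.DataFrame, window_bp: int = WINDOW_BP) -> list[np.ndarray]:
    """One window per starting SNP: consecutive SNPs with span <= window_bp.

    Span is measured first-to-last member SNP, 1-based inclusive
    (end - start + 1 <= window_bp).
    """
    windows = []
    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.int64)
    n = len(snp_map)
    start_of_chrom = 0
    for i in range(n):
        if i > 0 and chrom[i] != chrom[i - 1]:
            start_of_chrom = i
        j = i
        while j + 1 < n and chrom[j + 1] == chrom[i] and bp[j + 1] - bp[i] + 1 <= window_bp:
            j += 1
        windows.append(np.arange(i, j + 1))
    return windows


def tiling_windows(snp_map: pd.DataFrame, window_bp: int = WINDOW_BP) -> list[np.ndarray]:
    """Non-overlapping window_bp bins per chromosome (empty bins skipped)."""
    windows = []
    bp = snp_map["bp"].values.astype(np.int64)
    for c in snp_map["chrom"].unique():
        idx = np.flatnonzero((snp_map["chrom"] == c).values)
        bins = (bp[idx] - 1) // window_bp
        for b in np.unique(bins):
            windows.append(idx[bins == b])
    return windows


def window_variances(
    u_hat: np.ndarray,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    sigma2_a: float,
    mode: str = "sliding",
    window_bp: int = WINDOW_BP,
) -> list[WindowResult]:
    """Variance shares of 1 Mb SNP windows.

    For each window the genetic values a_i = Z_w u_w of the genotyped
    individuals are computed and their empirical (population) variance is
    expressed as a percentage of sigma2_a.
    """
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    if sigma2_a <= 0:
        raise ValueError("sigma2_a must be positive")
    bad = snp_map.groupby("chrom", sort=False)["bp"].apply(lambda s: (s.diff().dropna() < 0).any())
    if bad.any():
        raise ValueError("SNP map must be sorted by position within chromosome")
    if mode == "sliding":
        windows = sliding_windows(snp_map, window_bp)
    elif mode == "tiling":
        windows = tiling_windows(snp_map, window_bp)
    else:
        raise ValueError("mode must be 'sliding' or 'tiling'")

    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.int64)
    snps = snp_map["snp"].values
    results = []
    for idx in windows:
        a_i = Z[:, idx] @ u_hat[idx]
        share = 100.0 * float(np.var(a_i)) / sigma2_a
        results.append(
            WindowResult(
                chrom=str(chrom[idx[0]]),
                start_bp=int(bp[idx[0]]),
                end_bp=int(bp[idx[-1]]),
                snp_count=len(idx),
                var_share_pct=share,
                snp_ids=list(snps[idx]),
                first_snp_index=int(idx[0]),
            )
        )
    return results


def select_regions(
    windows: list[WindowResult],
    threshold_pct: float = 1.0,
) -> list[CandidateRegion]:
    """Windows explaining more than ``threshold_pct`` of the additive variance,
    merged into candidate regions.

    Selected windows that are consecutive in map order on the same chromosome
    (no rejected window between them) merge into one region.  A region's
    total share sums a greedy left-to-right non-overlapping subset of its
    selected windows, so heavily overlapping sliding windows are not double
    counted.
    """
    order = sorted(range(len(windows)), key=lambda k: (windows[k].chrom, windows[k].first_snp_index))
    regions: list[CandidateRegion] = []
    group: list[WindowResult] = []

    def flush():
        if not group:
            return
        total = 0.0
        last_end = -1
        for w in group:
            if w.start_bp > last_end:
                total += w.var_share_pct
                last_end = w.end_bp
        regions.append(
            CandidateRegion(
                chrom=group[0].chrom,
                start_bp=min(w.start_bp for w in group),
                end_bp=max(w.end_bp for w in group),
                total_var_share_pct=total,
                source="gwas",
            )
        )
        group.clear()

    for pos, k in enumerate(order):
        w = windows[k]
        selected = w.var_share_pct > threshold_pct
        if not selected:
            flush()
            continue
        if group and (
            w.chrom != group[-1].chrom
            or windows[order[pos - 1]].var_share_pct <= threshold_pct
        ):
            flush()
        group.append(w)
    flush()
    return regions


def windows_frame(windows: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "snp_count": [w.snp_count for w in windows],
            "var_share_pct": [w.var_share_pct for w in windows],
        }
    )


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp for r in regions],
            "end": [r.end_bp for r in regions],
            "total_var_share_pct": [r.total_var_share_pct for r in regions],
            "source": [r.source for r in regions],
        }
    )


@dataclass
class WssgwasConfig:
    n_loops: int = 1  # reweighting loops after the D = I pass
    blend: float = 0.05
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    window_mode: str = "sliding"
    region_threshold_pct: float = 1.0


def run_iterations(
    ped: pd.DataFrame,
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    cfg: WssgwasConfig,
) -> list[SnpEffectSet]:
    """Full iterative weighted single-step GWAS.

    Each pass rebuilds G* and H^-1 with the current weights, re-estimates
    GEBV with the threshold-model sampler (step 3 sits inside the loop), and
    backsolves SNP effects.  ``n_loops`` reweighting loops yield
    ``n_loops + 1`` effect sets; the default single loop matches obtaining
    results "after one loop".
    """
    animals = ped["animal"].values
    idx_of = {int(a): i for i, a in enumerate(animals)}
    if geno.n_animals == 0:
        raise ValueError("no genotyped animals: SNP effects cannot be backsolved")
    rec_animal = np.array([idx_of[int(a)] for a in pheno["animal"].values], dtype=np.int64)

    d = np.ones(geno.n_snps)
    results: list[SnpEffectSet] = []
    for it in range(cfg.n_loops + 1):
        rel = build_relationships(ped, geno, D=d, blend=cfg.blend)
        gcfg = GibbsConfig(
            n_cycles=cfg.gibbs.n_cycles,
            burn_in=cfg.gibbs.burn_in,
            thin=cfg.gibbs.thin,
            seed=cfg.gibbs.seed + it,  # fresh chain per pass, still seed-determined
            var=cfg.gibbs.var,
        )
        draws = run_gibbs(pheno, rec_animal, rel.H_inv, gcfg, animal_ids=animals)
        a_g_hat = draws.gebv[rel.geno_idx]

        Gb = blend_G(rel.G_star, rel.A22, cfg.blend)
        try:
            Gb_inv = np.linalg.inv(Gb)
        except np.linalg.LinAlgError as exc:
            raise SingularBacksolveError(
                "blended G* is singular; increase blending"
            ) from exc
        u_hat = backsolve_snp_effects(
            a_g_hat, rel.Z, D=d, G_star_inv=Gb_inv, lam=rel.lambda_norm
        )
        var_u = snp_variances(u_hat, rel.p)
        results.append(
            SnpEffectSet(
                iteration=it,
                snp_map=geno.snp_map,
                u_hat=u_hat,
                var_u_hat=var_u,
                weights=d.copy(),
                gebv=draws.gebv_frame(),
            )
        )
        d = normalize_weights(var_u, rel.p)
    return results
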