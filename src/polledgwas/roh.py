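"""Runs of homozygosity (ROH) and ROH islands.

Detection follows the sliding-window scanning approach of PLINK-style ROH
callers with seven parameters: (i) a 50-SNP sliding window, (ii) a SNP is in
a potential ROH when at least 5% of the windows covering it are
"homozygous-eligible", (iii) at least 100 consecutive SNPs per ROH, (iv)
minimum length 1 Mb, (v) maximum 0.5 Mb gap between consecutive SNPs, (vi)
density of at least one SNP per 50 kb, and (vii) at most one heterozygous
genotype in a ROH (the same single-het allowance applies inside a scanning
window).

A reported segment is a *maximal* SNP interval in which every member SNP has
window support and all of constraints (iii)-(vii) hold; maximal means not
contained in any other interval that also passes.  Segment length is
end_bp - start_bp.

Islands: per-SNP ROH incidence (fraction of animals whose ROH cover the SNP)
is screened with the boxplot outlier fence Q3 + 1.5 IQR; at least 100
consecutive outlier SNPs form an island.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .wssgwas import CandidateRegion


@dataclass
class RohParams:
    window_snps: int = 50
    het_in_window: int = 1
    missing_in_window: int = 2
    overlap_threshold: float = 0.05
    min_snps: int = 100
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 500_000
    max_bp_per_snp: int = 50_000  # density >= 1 SNP / 50 kb
    het_in_roh: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        for name in (
            "window_snps",
            "min_snps",
            "min_length_bp",
            "max_gap_bp",
            "max_bp_per_snp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.het_in_window < 0 or self.het_in_roh < 0 or self.missing_in_window < 0:
            raise ValueError("het/missing allowances must be non-negative")


@dataclass
class RohSegment:
    animal_id: int
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class RohIsland:
    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: np.ndarray = field(repr=False)
    incidences: np.ndarray = field(repr=False)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def window_support(g: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP in-ROH state for one animal on one (sorted) chromosome.

    A 50-SNP window is homozygous-eligible when it holds at most one
    heterozygote and at most ``missing_in_window`` missing calls; a SNP is in
    a potential ROH when the eligible fraction of the windows covering it
    reaches ``overlap_threshold``.  Windows are truncated at chromosome
    edges: the denominator is the number of windows actually covering the
    SNP.
    """
    n = g.size
    W = params.window_snps
    if n < W:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(np.int64)
    mis = (g < 0).astype(np.int64)
    elig = (_sliding_sum(het, W) <= params.het_in_window) & (
        _sliding_sum(mis, W) <= params.missing_in_window
    )
    ce = np.concatenate([[0], np.cumsum(elig)])
    s = np.arange(n)
    lo = np.maximum(0, s - W + 1)
    hi = np.minimum(s, n - W)
    num = ce[hi + 1] - ce[lo]
    den = hi - lo + 1
    return num / den >= params.overlap_threshold


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, end) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[brk + 1]])
    ends = np.concatenate([idx[brk], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _max_passing_j(i: int, z1: int, bp: np.ndarray, params: RohParams) -> int:
    """Largest j in [i, z1] such that the interval (i, j) passes size, length
    and density; -1 if none."""
    for j in range(z1, i + params.min_snps - 2, -1):
        span = bp[j] - bp[i]
        n = j - i + 1
        if n < params.min_snps:
            break
        if span >= params.min_length_bp and span <= n * params.max_bp_per_snp:
            return j
    return -1


def _candidates_one_chrom(g: np.ndarray, bp: np.ndarray, params: RohParams):
    """Maximal passing intervals (i, j) for one animal on one chromosome."""
    state = window_support(g, params)
    het = g == 1
    cands = []
    for a, b in _runs(state):
        # split where the inter-SNP gap exceeds the allowance
        cut = [a] + [k + 1 for k in range(a, b) if bp[k + 1] - bp[k] > params.max_gap_bp] + [b + 1]
        for c, d in zip(cut[:-1], cut[1:]):
            d -= 1
            if d - c + 1 < params.min_snps:
                continue
            # for each start l, the furthest right end r(l) keeping the het
            # count within the allowance (two-pointer; r is monotone in l)
            hcum = np.concatenate([[0], np.cumsum(het[c : d + 1])])
            r = c - 1
            for l in range(c, d + 1):
                if r < l - 1:
                    r = l - 1
                while r + 1 <= d and hcum[r + 2 - c] - hcum[l - c] <= params.het_in_roh:
                    r += 1
                j = _max_passing_j(l, r, bp, params)
                if j >= 0:
                    cands.append((l, j))
    # global maximality: drop intervals contained in another passing interval
    cands = sorted(set(cands), key=lambda ij: (ij[0], -ij[1]))
    out = []
    max_end = -1
    for i, j in cands:
        if j > max_end:
            out.append((i, j))
            max_end = j
    return out


def detect_roh(geno: GenotypeMatrix, params: RohParams | None = None) -> list[RohSegment]:
    """Detect ROH segments for every animal, chromosome by chromosome."""
    params = params or RohParams()
    segments: list[RohSegment] = []
    chrom_vals = geno.snp_map["chrom"].values
    bp_all = geno.snp_map["bp"].values.astype(np.int64)
    for c in pd.unique(chrom_vals):
        cols = np.flatnonzero(chrom_vals == c)
        bp = bp_all[cols]
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"SNP map not sorted by position on chromosome {c}")
        for row in range(geno.n_animals):
            g = geno.M[row, cols]
            for i, j in _candidates_one_chrom(g, bp, params):
                seg_het = int(np.sum(g[i : j + 1] == 1))
                segments.append(
                    RohSegment(
                        animal_id=int(geno.animal_ids[row]),
                        chrom=str(c),
                        start_bp=int(bp[i]),
                        end_bp=int(bp[j]),
                        n_snps=j - i + 1,
                        n_het=seg_het,
                    )
                )
    return segments


def segments_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": [s.animal_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start_bp": [s.start_bp for s in segments],
            "end_bp": [s.end_bp for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "n_het": [s.n_het for s in segments],
            "length_bp": [s.length_bp for s in segments],
        }
    )


def snp_incidence(
    segments: list[RohSegment], snp_map: pd.DataFrame, n_animals: int
) -> np.ndarray:
    """Per SNP, the fraction of animals whose ROH cover it.

    An animal is counted once per SNP even when (overlapping) segments of
    that animal cover the SNP more than once.
    """
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.int64)
    covered: dict[int, np.ndarray] = {}
    for s in segments:
        mask = (chrom == s.chrom) & (bp >= s.start_bp) & (bp <= s.end_bp)
        if s.animal_id not in covered:
            covered[s.animal_id] = mask.copy()
        else:
            covered[s.animal_id] |= mask
    counts = np.zeros(len(snp_map), dtype=np.int64)
    for mask in covered.values():
        counts += mask
    return counts / n_animals


def call_islands(
    incidence: np.ndarray,
    snp_map: pd.DataFrame,
    min_consecutive: int = 100,
    fence_scope: str = "genome",
) -> list[RohIsland]:
    """ROH islands: >= ``min_consecutive`` consecutive boxplot-outlier SNPs.

    The outlier fence is Q3 + 1.5 IQR of the incidence distribution
    (quartiles by linear interpolation), computed over all input SNPs by
    default, or per chromosome with ``fence_scope='chromosome'``.  At desk
    scale a simulated island can occupy a large share of its small
    chromosome, which would contaminate a per-chromosome Q3; the genome-wide
    fence is robust to that and coincides with the per-chromosome fence when
    a single chromosome is scanned.
    """
    incidence = np.asarray(incidence, dtype=float)
    if len(incidence) != len(snp_map):
        raise ValueError("incidence and map lengths differ")
    chrom = snp_map["chrom"].values
    bp = snp_map["bp"].values.astype(np.int64)
    islands: list[RohIsland] = []

    def fence_of(values: np.ndarray) -> float | None:
        if values.max() == values.min():
            return None
        q1, q3 = np.percentile(values, [25, 75])
        return q3 + 1.5 * (q3 - q1)

    global_fence = fence_of(incidence) if fence_scope == "genome" else np.nan
    if fence_scope == "genome" and global_fence is None:
        warnings.warn("constant ROH incidence (zero IQR): no islands called")
        return []

    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        vals = incidence[cols]
        if fence_scope == "chromosome":
            fence = fence_of(vals)
            if fence is None:
                warnings.warn(f"constant ROH incidence on chromosome {c}: no islands called")
                continue
        else:
            fence = global_fence
        outlier = vals > fence
        for a, b in _runs(outlier):
            if b - a + 1 >= min_consecutive:
                idx = cols[a : b + 1]
                islands.append(
                    RohIsland(
                        chrom=str(c),
                        start_bp=int(bp[idx[0]]),
                        end_bp=int(bp[idx[-1]]),
                        snp_indices=idx,
                        incidences=incidence[idx],
                    )
                )
    return islands


def islands_frame(islands: list[RohIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in islands],
            "start": [i.start_bp for i in islands],
            "end": [i.end_bp for i in islands],
            "n_snps": [len(i.snp_indices) for i in islands],
            "length_bp": [i.length_bp for i in islands],
        }
    )


def intersect_regions(
    gwas: list[CandidateRegion], islands: list[RohIsland]
) -> list[CandidateRegion]:
    """Pairwise interval intersections (1-based inclusive); the consensus regions.

    Empty intersections are dropped; each consensus region keeps the variance
    share of its GWAS parent.
    """
    out: list[CandidateRegion] = []
    for g in gwas:
        for isl in islands:
            if g.chrom != isl.chrom:
                continue
            start = max(g.start_bp, isl.start_bp)
            end = min(g.end_bp, isl.end_bp)
            if start <= end:
                out.append(
                    CandidateRegion(
                        chrom=g.chrom,
                        start_bp=start,
                        end_bp=end,
                        total_var_share_pct=g.total_var_share_pct,
                        source="consensus",
                    )
                )
    return out
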