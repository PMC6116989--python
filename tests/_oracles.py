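"""Independent reference implementations used only by the tests.

Everything here is deliberately naive (enumeration, dense algebra, direct
loops) and shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int | None = None) -> pd.DataFrame:
    """Random valid pedigree of n animals; matings among earlier animals,
    so close inbreeding (parent-offspring, full sibs) happens by chance."""
    n_founders = n_founders if n_founders is not None else max(2, n // 4)
    rows = []
    for i in range(1, n + 1):
        if i <= n_founders:
            rows.append((i, 0, 0, 0))
        else:
            s, d = rng.integers(1, i, size=2)
            rows.append((i, int(s), int(d), 1))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation"])


def dense_A(ped: pd.DataFrame) -> np.ndarray:
    """Wright's numerator relationship matrix by the textbook recursion."""
    animals = ped["animal"].tolist()
    pos = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    A = np.zeros((n, n))
    for i, (a, s, d) in enumerate(ped[["animal", "sire", "dam"]].itertuples(index=False)):
        si = pos[s] if s != 0 else None
        di = pos[d] if d != 0 else None
        for j in range(i):
            v = 0.0
            if si is not None:
                v += 0.5 * A[si, j]
            if di is not None:
                v += 0.5 * A[di, j]
            A[i, j] = A[j, i] = v
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    return A


def dense_H(A: np.ndarray, geno_idx: np.ndarray, Gb: np.ndarray) -> np.ndarray:
    """Joint H with the genomic block replacing A22, by the standard identity:

    H11 = A11 + A12 A22^-1 (Gb - A22) A22^-1 A21,  H12 = A12 A22^-1 Gb,
    H22 = Gb.
    """
    n = A.shape[0]
    g = np.asarray(geno_idx)
    o = np.setdiff1d(np.arange(n), g)
    A11 = A[np.ix_(o, o)]
    A12 = A[np.ix_(o, g)]
    A22 = A[np.ix_(g, g)]
    A22i = np.linalg.inv(A22)
    H = np.empty_like(A)
    H[np.ix_(o, o)] = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
    H[np.ix_(o, g)] = A12 @ A22i @ Gb
    H[np.ix_(g, o)] = H[np.ix_(o, g)].T
    H[np.ix_(g, g)] = Gb
    return H


def weighted_min_norm_backsolve(a_hat: np.ndarray, Z: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve min u' D^-1 u subject to Z u = a_hat via the KKT system."""
    n, m = Z.shape
    K = np.zeros((m + n, m + n))
    K[:m, :m] = np.diag(1.0 / d)
    K[:m, m:] = Z.T
    K[m:, :m] = Z
    rhs = np.concatenate([np.zeros(m), a_hat])
    sol = np.linalg.solve(K, rhs)
    return sol[:m]


def window_share_direct(u: np.ndarray, Z: np.ndarray, idx: np.ndarray, sigma2_a: float) -> float:
    """Window variance share by explicit per-individual loops."""
    vals = []
    for row in range(Z.shape[0]):
        s = 0.0
        for j in idx:
            s += Z[row, j] * u[j]
        vals.append(s)
    vals = np.array(vals)
    return 100.0 * float(np.mean((vals - vals.mean()) ** 2)) / sigma2_a


# --- ROH -----------------------------------------------------------------------


def roh_window_support(g: np.ndarray, window_snps: int, het_in_window: int,
                       missing_in_window: int, overlap_threshold: float) -> np.ndarray:
    """Direct (loopy) per-SNP window support."""
    n = g.size
    if n < window_snps:
        return np.zeros(n, dtype=bool)
    eligible = []
    for w in range(n - window_snps + 1):
        win = g[w : w + window_snps]
        eligible.append(
            int(np.sum(win == 1)) <= het_in_window
            and int(np.sum(win < 0)) <= missing_in_window
        )
    state = np.zeros(n, dtype=bool)
    for s in range(n):
        covering = [w for w in range(max(0, s - window_snps + 1), min(s, n - window_snps) + 1)]
        frac = sum(eligible[w] for w in covering) / len(covering)
        state[s] = frac >= overlap_threshold
    return state


def roh_enumerate(g: np.ndarray, bp: np.ndarray, params) -> list[tuple[int, int]]:
    """Exhaustive enumeration of maximal ROH intervals for one animal/chromosome.

    Every SNP interval is tested against window support, the gap rule, the
    size/length/density constraints and the heterozygote cap; intervals
    contained in another passing interval are discarded.
    """
    n = g.size
    state = roh_window_support(
        g, params.window_snps, params.het_in_window, params.missing_in_window,
        params.overlap_threshold,
    )
    passing = []
    for i in range(n):
        if not state[i]:
            continue
        hets = 1 if g[i] == 1 else 0
        for j in range(i, n):
            if j > i:
                if not state[j]:
                    break
                if bp[j] - bp[j - 1] > params.max_gap_bp:
                    break
                if g[j] == 1:
                    hets += 1
            if hets > params.het_in_roh:
                break
            n_snps = j - i + 1
            span = bp[j] - bp[i]
            if (
                n_snps >= params.min_snps
                and span >= params.min_length_bp
                and span <= n_snps * params.max_bp_per_snp
            ):
                passing.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in passing
        if not any((i2 <= i and j2 >= j and (i2, j2) != (i, j)) for (i2, j2) in passing)
    ]
    return sorted(set(maximal))


def random_roh_fixture(rng: np.random.Generator, n_snps: int):
    """Genotypes and positions likely to contain near-threshold ROH cases."""
    # blocks of elevated homozygosity to create candidate runs
    g = np.empty(n_snps, dtype=np.int8)
    i = 0
    while i < n_snps:
        L = int(rng.integers(20, 140))
        mode = rng.random()
        if mode < 0.55:  # homozygous stretch with occasional het/missing
            block = rng.choice([0, 2], size=L)
            het_idx = rng.random(L) < 0.01
            block[het_idx] = 1
            block[rng.random(L) < 0.01] = -1
        else:  # ordinary segregating stretch
            block = rng.choice([0, 1, 2, -1], size=L, p=[0.42, 0.38, 0.15, 0.05])
        g[i : i + min(L, n_snps - i)] = block[: n_snps - i]
        i += L
    gaps = rng.integers(2_000, 40_000, size=n_snps)
    # sprinkle a few oversized gaps to exercise the gap rule
    big = rng.random(n_snps) < 0.01
    gaps[big] = rng.integers(400_000, 900_000, size=int(big.sum()))
    bp = np.cumsum(gaps).astype(np.int64)
    return g, bp
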