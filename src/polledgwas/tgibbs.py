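"""Threshold-model Gibbs sampler for a binary trait under H^-1.

Model (liability scale): I = 1*mu + X a + e with e ~ N(0, I sigma2_e) and
a ~ N(0, H sigma2_a); the observed category is 2 ("polled") iff the latent
liability exceeds the threshold, which is fixed at t = 0 with mu free (the
standard two-category identifiability constraint).  Variance components are
fixed; the default follows the unit-total-variance convention
sigma2_a = h2, sigma2_e = 1 - h2 with h2 = 0.99.

The sampler cycles:
  1. liabilities from their truncated-normal full conditionals,
  2. mu from its normal full conditional (flat prior),
  3. each animal effect a_j by single-site Gibbs using the row of H^-1.

Genomic estimated breeding values (GEBV) are the posterior means of a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .relmat import VarianceComponents


class NumericalFailureError(RuntimeError):
    def __init__(self, cycle: int):
        super().__init__(f"non-finite draw at Gibbs cycle {cycle}")
        self.cycle = cycle


@dataclass
class GibbsConfig:
    """Chain settings.

    The real-data setting in the source methodology is a single chain of
    300,000 cycles; the desk-scale default is 20,000 with 10% burn-in and
    thinning 10.
    """

    n_cycles: int = 20_000
    burn_in: int | None = None
    thin: int = 10
    seed: int = 0
    var: VarianceComponents = field(default_factory=lambda: VarianceComponents.from_h2(0.99))

    def resolved_burn_in(self) -> int:
        b = self.burn_in if self.burn_in is not None else self.n_cycles // 10
        if not 0 <= b < self.n_cycles:
            raise ValueError("burn_in must be < n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        return b


@dataclass
class PosteriorDraws:
    animal_ids: np.ndarray
    mu_samples: np.ndarray
    a_samples: np.ndarray  # (n_kept, n_animals)

    @property
    def n_kept(self) -> int:
        return len(self.mu_samples)

    @property
    def gebv(self) -> np.ndarray:
        return self.a_samples.mean(axis=0)

    @property
    def gebv_sd(self) -> np.ndarray:
        return self.a_samples.std(axis=0, ddof=1)

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal_ids, "gebv": self.gebv, "sd": self.gebv_sd}
        )


@njit(cache=True)
def _rtnorm_lower(a):  # pragma: no cover - numba
    """Standard normal truncated to (a, inf); robust far into the tail.

    Plain rejection below a = 0.4, Robert's translated-exponential rejection
    above (acceptance bounded away from zero for any a).
    """
    if a < 0.4:
        while True:
            x = np.random.normal()
            if x > a:
                return x
    lam = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        x = a - math.log(1.0 - np.random.random()) / lam
        diff = x - lam
        if np.random.random() <= math.exp(-0.5 * diff * diff):
            return x


@njit(cache=True)
def _sample_liabilities_kernel(mean, sd, category, t, out):  # pragma: no cover - numba
    for r in range(mean.size):
        if category[r] == 2:
            out[r] = mean[r] + sd * _rtnorm_lower((t - mean[r]) / sd)
        else:
            out[r] = mean[r] - sd * _rtnorm_lower((mean[r] - t) / sd)


def sample_liabilities(
    mean: np.ndarray,
    sd: float,
    category: np.ndarray,
    t: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw liabilities from N(mean, sd^2) truncated to (t, inf) for category 2
    and (-inf, t] for category 1."""
    mean = np.asarray(mean, dtype=np.float64)
    category = np.asarray(category, dtype=np.int64)
    out = np.empty_like(mean)
    np.random.seed(seed)  # numba kernels use the numpy legacy global stream
    _sample_liabilities_kernel(mean, float(sd), category, float(t), out)
    return out


@njit(cache=True)
def _gibbs_kernel(  # pragma: no cover - numba
    category,
    rec_animal,
    rec_ptr,
    rec_idx,
    Hinv,
    sigma2_a,
    sigma2_e,
    t,
    n_cycles,
    burn_in,
    thin,
    seed,
    observed,
    liab,
):
    n_anim = Hinv.shape[0]
    n_rec = rec_animal.size
    sd_e = math.sqrt(sigma2_e)
    mu = 0.0
    a = np.zeros(n_anim)
    n_keep = (n_cycles - burn_in) // thin
    mu_samples = np.empty(n_keep)
    a_samples = np.empty((n_keep, n_anim))
    np.random.seed(seed)

    kept = 0
    for cycle in range(n_cycles):
        if not observed:
            for r in range(n_rec):
                m = mu + a[rec_animal[r]]
                if category[r] == 2:
                    liab[r] = m + sd_e * _rtnorm_lower((t - m) / sd_e)
                else:
                    liab[r] = m - sd_e * _rtnorm_lower((m - t) / sd_e)

        s = 0.0
        for r in range(n_rec):
            s += liab[r] - a[rec_animal[r]]
        mu = s / n_rec + np.random.normal() * math.sqrt(sigma2_e / n_rec)

        for j in range(n_anim):
            off = 0.0
            row = Hinv[j]
            for k in range(n_anim):
                off += row[k] * a[k]
            off -= row[j] * a[j]
            rhs = -off / sigma2_a
            nj = rec_ptr[j + 1] - rec_ptr[j]
            for q in range(rec_ptr[j], rec_ptr[j + 1]):
                rhs += (liab[rec_idx[q]] - mu) / sigma2_e
            prec = nj / sigma2_e + row[j] / sigma2_a
            a[j] = rhs / prec + np.random.normal() / math.sqrt(prec)
            if not math.isfinite(a[j]):
                return mu_samples, a_samples, cycle

        if cycle >= burn_in and (cycle - burn_in) % thin == 0 and kept < n_keep:
            mu_samples[kept] = mu
            a_samples[kept] = a
            kept += 1
    return mu_samples, a_samples, -1


def run_gibbs(
    pheno: pd.DataFrame | np.ndarray,
    animal_index: np.ndarray,
    H_inv: np.ndarray,
    cfg: GibbsConfig,
    observed_liabilities: np.ndarray | None = None,
    animal_ids: np.ndarray | None = None,
    threshold: float = 0.0,
) -> PosteriorDraws:
    """Run the sampler and return retained posterior draws.

    Parameters
    ----------
    pheno:
        Phenotype table with a ``category`` column (or a bare category array),
        one record per row.
    animal_index:
        For each record, the 0-based index of its animal in the H^-1
        ordering (the incidence matrix X in index form).
    observed_liabilities:
        When given, the liabilities are treated as observed continuous data
        (no truncated sampling) — the Gaussian reduction of the model, used
        for validating against the direct mixed-model-equation solution.
    """
    if isinstance(pheno, pd.DataFrame):
        category = pheno["category"].values.astype(np.int64)
    else:
        category = np.asarray(pheno, dtype=np.int64)
    animal_index = np.asarray(animal_index, dtype=np.int64)
    if category.size == 0:
        raise ValueError("no phenotype records")
    if category.size != animal_index.size:
        raise ValueError("pheno and animal_index lengths differ")
    H_inv = np.ascontiguousarray(H_inv, dtype=np.float64)
    n_anim = H_inv.shape[0]
    if animal_index.min() < 0 or animal_index.max() >= n_anim:
        raise ValueError("animal_index out of range for H_inv")

    order = np.argsort(animal_index, kind="stable")
    rec_idx = order.astype(np.int64)
    counts = np.bincount(animal_index, minlength=n_anim)
    rec_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    observed = observed_liabilities is not None
    liab = (
        np.asarray(observed_liabilities, dtype=np.float64).copy()
        if observed
        else np.zeros(category.size)
    )

    burn_in = cfg.resolved_burn_in()
    mu_samples, a_samples, fail_cycle = _gibbs_kernel(
        category,
        animal_index,
        rec_ptr,
        rec_idx,
        H_inv,
        float(cfg.var.sigma2_a),
        float(cfg.var.sigma2_e),
        float(threshold),
        int(cfg.n_cycles),
        int(burn_in),
        int(cfg.thin),
        int(cfg.seed),
        observed,
        liab,
    )
    if fail_cycle >= 0:
        raise NumericalFailureError(fail_cycle)
    if animal_ids is None:
        animal_ids = np.arange(n_anim)
    return PosteriorDraws(animal_ids=np.asarray(animal_ids), mu_samples=mu_samples, a_samples=a_samples)


def mme_solution(
    liab: np.ndarray,
    animal_index: np.ndarray,
    H_inv: np.ndarray,
    var: VarianceComponents,
) -> tuple[float, np.ndarray]:
    """Direct mixed-model-equation solution for observed (continuous) liabilities.

    Solves [1'1  1'X; X'1  X'X + H^-1 alpha] [mu; a] = [1'y; X'y] with
    alpha = sigma2_e / sigma2_a.  Used as the deterministic reference for the
    Gaussian reduction of the sampler.
    """
    liab = np.asarray(liab, dtype=float)
    animal_index = np.asarray(animal_index, dtype=np.int64)
    n_anim = H_inv.shape[0]
    n_rec = liab.size
    X = sparse.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), animal_index)), shape=(n_rec, n_anim)
    ).toarray()
    alpha = var.sigma2_e / var.sigma2_a
    lhs = np.zeros((1 + n_anim, 1 + n_anim))
    lhs[0, 0] = n_rec
    lhs[0, 1:] = X.sum(axis=0)
    lhs[1:, 0] = X.sum(axis=0)
    lhs[1:, 1:] = X.T @ X + np.asarray(H_inv) * alpha
    rhs = np.concatenate([[liab.sum()], X.T @ liab])
    sol = np.linalg.solve(lhs, rhs)
    return float(sol[0]), sol[1:]


def mc_standard_error(samples: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte-Carlo standard error of the chain mean (per column)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        samples = samples.T
    n = samples.shape[0]
    b = max(n // n_batches, 1)
    usable = (n // b) * b
    means = samples[:usable].reshape(n // b, b, -1).mean(axis=1)
    return means.std(axis=0, ddof=1) / math.sqrt(means.shape[0])
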