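"""Haplotype-level population statistics.

Implements the Arlequin-style toolkit used for intra- and inter-population
analysis of phased haplotypes:

* gene (haplotype) diversity H = n/(n-1) * (1 - sum p_h^2) and nucleotide
  diversity pi (mean pairwise Hamming difference per polymorphic site, with
  the same small-sample correction);
* pairwise AMOVA-based Phi_ST from inter-haplotype Hamming distances, with
  permutation significance (gene copies reallocated between the two
  populations, which is a multivariate hypergeometric draw on the pooled
  haplotype counts);
* a Monte-Carlo exact test of population differentiation on the
  haplotype x population contingency table (fixed margins, Patefield
  sampling, tables ranked by conditional probability);
* the Ewens-Watterson homozygosity test of selective neutrality.  The null
  distribution of F = sum p_h^2 is the Ewens sampling formula conditional on
  the sample size n and the number of distinct haplotypes k.  Conditional on
  k the ESF is theta-free and coincides with the cycle-type law of a uniform
  random permutation of n elements with exactly k cycles, so the sampler
  draws block sizes sequentially from the exact recursion expressed with
  unsigned Stirling numbers of the first kind (computed in log space).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import random_table

from .phasing import HaplotypeFrequencySet

__all__ = [
    "DiversityResult",
    "FstResult",
    "EwResult",
    "diversity",
    "pairwise_fst",
    "exact_differentiation",
    "ewens_watterson",
    "hamming_matrix",
]


# -- distances -----------------------------------------------------------

def hamming_matrix(haplotypes: list[str]) -> np.ndarray:
    """Pairwise Hamming distances between equal-length 0/1 strings."""
    if not haplotypes:
        return np.zeros((0, 0))
    arr = np.array([[int(c) for c in h] for h in haplotypes], dtype=np.int16)
    return np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2).astype(float)


def _as_counts(hfs) -> pd.Series:
    """Integer haplotype counts from a HaplotypeFrequencySet or a Series."""
    if isinstance(hfs, HaplotypeFrequencySet):
        counts = (hfs.freqs * hfs.n_genes).round().astype(int)
    else:
        counts = pd.Series(hfs).astype(int)
    return counts[counts > 0]


# -- diversity -----------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    population: str
    n: int  # gene copies
    k: int  # distinct haplotypes
    H: float  # haplotype (gene) diversity
    pi: float  # nucleotide diversity per polymorphic site
    L: int  # polymorphic sites within this sample


def diversity(hfs, population: str | None = None) -> DiversityResult:
    """Haplotype and nucleotide diversity for one population sample."""
    counts = _as_counts(hfs)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("diversity needs at least 2 gene copies")
    haps = list(counts.index)
    p = counts.to_numpy() / n
    H = n / (n - 1) * (1.0 - float((p**2).sum()))
    arr = np.array([[int(c) for c in h] for h in haps])
    poly = ((arr.max(axis=0) - arr.min(axis=0)) > 0) if arr.size else np.array([])
    L = int(poly.sum())
    if L == 0:
        pi = 0.0
    else:
        D = hamming_matrix(haps)
        pi = n / (n - 1) * float(p @ D @ p) / L  # p'Dp = sum_{i<j} 2 p_i p_j d_ij
    name = population or (hfs.population if isinstance(hfs, HaplotypeFrequencySet) else "")
    return DiversityResult(name, n, len(haps), H, pi, L)


# -- pairwise AMOVA Phi_ST -----------------------------------------------

@dataclass(frozen=True)
class FstResult:
    pair: tuple[str, str]
    fst: float
    n_perm: int
    p_value: float
    is_negative: bool


def _amova_fst(counts: np.ndarray, D: np.ndarray) -> float:
    """Two-level AMOVA Phi_ST from per-population haplotype counts (rows =
    populations) and squared inter-haplotype distances ``D``."""
    n_p = counts.sum(axis=1).astype(float)
    N = n_p.sum()
    P = counts.shape[0]
    pooled = counts.sum(axis=0).astype(float)
    ssd_total = 0.5 * pooled @ D @ pooled / N
    ssd_within = sum(0.5 * c @ D @ c / n for c, n in zip(counts.astype(float), n_p))
    ssd_among = ssd_total - ssd_within
    if abs(ssd_among) < 1e-12:
        return 0.0  # no among-group variation at all (e.g. identical samples)
    df_w = N - P
    sigma_w = ssd_within / df_w if df_w > 0 else 0.0
    n_c = (N - (n_p**2).sum() / N) / (P - 1)
    msd_a = ssd_among / (P - 1)
    sigma_a = (msd_a - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_fst(
    hfs_a,
    hfs_b,
    n_perm: int = 100_000,
    seed: int | None = None,
    distance: str = "hamming",
) -> FstResult:
    """AMOVA-based Phi_ST between two population samples with permutation
    significance.

    ``distance="hamming"`` (Arlequin's haplotypic default) uses the number of
    differing sites as squared inter-haplotype distance; ``"identity"`` gives
    the pure frequency-based F_ST (distance 1 between distinct haplotypes).
    The permutation null reallocates gene copies between the two samples
    (equivalently a multivariate hypergeometric draw of one group from the
    pooled counts); p = Pr(F_perm >= F_obs) with the +1 correction.  Negative
    estimates are reported as computed, flagged by ``is_negative``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ca = _as_counts(hfs_a)
    cb = _as_counts(hfs_b)
    if ca.sum() < 2 or cb.sum() < 2:
        raise ValueError("each population needs at least 2 gene copies")
    haps = sorted(set(ca.index) | set(cb.index))
    a = ca.reindex(haps, fill_value=0).to_numpy()
    b = cb.reindex(haps, fill_value=0).to_numpy()
    if distance == "hamming":
        D = hamming_matrix(haps)
    elif distance == "identity":
        D = 1.0 - np.eye(len(haps))
    else:
        raise ValueError(f"unknown distance {distance!r}")
    obs = _amova_fst(np.stack([a, b]), D)

    rng = np.random.default_rng(seed)
    pooled = a + b
    n_a = int(a.sum())
    hits = 0
    for _ in range(n_perm):
        pa = rng.multivariate_hypergeometric(pooled, n_a)
        if _amova_fst(np.stack([pa, pooled - pa]), D) >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    name_a = hfs_a.population if isinstance(hfs_a, HaplotypeFrequencySet) else "A"
    name_b = hfs_b.population if isinstance(hfs_b, HaplotypeFrequencySet) else "B"
    return FstResult((name_a, name_b), obs, n_perm, p, is_negative=obs < 0)


# -- exact test of differentiation ---------------------------------------

def _log_table_prob(t: np.ndarray) -> float:
    """Log conditional probability of a contingency table given its margins
    (multivariate hypergeometric)."""
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def exact_differentiation(
    counts: pd.DataFrame, n_mc: int = 10_000, seed: int | None = None
) -> float:
    """Monte-Carlo exact test of population differentiation on a
    haplotype x population count table (columns = populations).

    p = (1 + #{simulated tables with conditional probability <= observed})
        / (n_mc + 1), tables drawn with fixed margins.
    """
    t = np.asarray(counts, dtype=int)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0] if t.size else t
    if t.shape[0] < 2:
        return 1.0  # single haplotype: no differentiation possible
    if t.shape[1] < 2:
        raise ValueError("need at least 2 populations")
    obs = _log_table_prob(t)
    rng = np.random.default_rng(seed)
    sampler = random_table(t.sum(axis=1), t.sum(axis=0))
    sims = sampler.rvs(n_mc, random_state=rng)
    hits = sum(_log_table_prob(np.asarray(s)) <= obs + 1e-9 for s in sims)
    return (hits + 1) / (n_mc + 1)


# -- Ewens-Watterson neutrality test -------------------------------------

@dataclass(frozen=True)
class EwResult:
    population: str
    n: int
    k: int
    observed_F: float
    expected_F: float
    p_value: float
    n_samples: int


@lru_cache(maxsize=8)
def _log_stirling1(n_max: int) -> np.ndarray:
    """log |s(n, k)| (unsigned Stirling numbers of the first kind) for
    0 <= k <= n <= n_max, via s(n+1,k) = s(n,k-1) + n*s(n,k)."""
    ls = np.full((n_max + 1, n_max + 1), -np.inf)
    ls[0, 0] = 0.0
    with np.errstate(divide="ignore"):
        for n in range(1, n_max + 1):
            ls[n, 1:n + 1] = np.logaddexp(
                ls[n - 1, 0:n], np.log(n - 1) + ls[n - 1, 1:n + 1]
            )
    return ls


def _block_size_logprobs(n: int, k: int, ls: np.ndarray) -> np.ndarray:
    """log P(block containing a marked element has size j | n, k), for
    j = 1..n-k+1."""
    j = np.arange(1, n - k + 2)
    # choose j-1 companions, arrange the block as a cycle, partition the rest
    logw = (
        gammaln(n) - gammaln(n - j + 1)  # (n-1)!/(n-j)! falling factorial
        + ls[n - j, k - 1]
        - ls[n, k]
    )
    return logw - logsumexp(logw)


@lru_cache(maxsize=None)
def _block_size_dist(n: int, k: int, n_max: int):
    """Cached (probs, cumulative) block-size distribution for state (n, k)."""
    probs = np.exp(_block_size_logprobs(n, k, _log_stirling1(n_max)))
    probs = probs / probs.sum()
    return probs, np.cumsum(probs)


def sample_esf_partitions(
    n: int, k: int, size: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Draw ``size`` partitions of n into k blocks from the Ewens sampling
    formula conditional on (n, k).  Exact (no rejection): block sizes are
    drawn sequentially from the Stirling-number recursion, with draws that
    share a prefix batched through multinomial splits."""
    n_max = n
    out: list[tuple[int, ...]] = []

    def recurse(n_rem: int, k_rem: int, count: int, prefix: tuple[int, ...]):
        if count == 0:
            return
        if k_rem == 1:
            out.extend([prefix + (n_rem,)] * count)
            return
        if k_rem == n_rem:
            out.extend([prefix + (1,) * n_rem] * count)
            return
        probs, cum = _block_size_dist(n_rem, k_rem, n_max)
        if count == 1:
            j = int(np.searchsorted(cum, rng.random())) + 1
            recurse(n_rem - j, k_rem - 1, 1, prefix + (j,))
            return
        alloc = rng.multinomial(count, probs)
        for idx, c in enumerate(alloc):
            if c:
                j = idx + 1
                recurse(n_rem - j, k_rem - 1, int(c), prefix + (j,))

    recurse(n, k, size, ())
    return out


def ewens_watterson(
    hfs, n_null: int = 10_000, seed: int | None = None, population: str | None = None
) -> EwResult:
    """Ewens-Watterson homozygosity test of selective neutrality.

    Observed F = sum p_h^2.  The null distribution of F is simulated from
    the ESF conditional on (n, k); p = Pr(F_null <= F_obs), the lower-tail
    convention under which balancing selection (too-even frequencies) gives
    small p and the drift-dominated case of a few common haplotypes gives
    large p.  Degenerate samples (k = 1 or k = n: a single attainable
    configuration) return p = 1 analytically.
    """
    counts = _as_counts(hfs)
    n = int(counts.sum())
    k = int(counts.size)
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 gene copies and k >= 1 haplotypes")
    p_obs = counts.to_numpy() / n
    f_obs = float((p_obs**2).sum())
    name = population or (hfs.population if isinstance(hfs, HaplotypeFrequencySet) else "")
    if k == 1 or k == n:
        return EwResult(name, n, k, f_obs, f_obs, 1.0, 0)
    rng = np.random.default_rng(seed)
    parts = sample_esf_partitions(n, k, n_null, rng)
    f_null = np.array([sum(b * b for b in part) for part in parts], dtype=float) / n**2
    expected = float(f_null.mean())
    p = float((f_null <= f_obs + 1e-12).mean())
    return EwResult(name, n, k, f_obs, expected, p, n_null)
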