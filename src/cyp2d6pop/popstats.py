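"""Allele/genotype frequency statistics: Hardy-Weinberg goodness-of-fit,
between-population contingency tests, and Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HweResult",
    "ContingencyResult",
    "hwe_test",
    "contingency_test",
    "bonferroni",
]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p_value: float
    testable: bool
    n_called: int
    alt_freq: float


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float | None
    df: int | None
    p_value: float
    method: str
    table: np.ndarray


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Pearson goodness-of-fit chi-square (df=1, no continuity correction)
    against Hardy-Weinberg proportions computed from the observed allele
    frequencies.

    A monomorphic cell (one allele absent) is structurally untestable:
    ``testable=False`` and ``p_value=nan``.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype counts")
    n = counts.sum()
    if n < 1:
        raise ValueError("no called genotypes")
    q = (counts[1] + 2 * counts[2]) / (2 * n)  # alt allele frequency
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, p_value=float("nan"), testable=False,
                         n_called=int(n), alt_freq=float(q))
    p = 1.0 - q
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p_value=pval, testable=True,
                     n_called=int(n), alt_freq=float(q))


def contingency_test(table, method: str = "pearson_chi2") -> ContingencyResult:
    """Test association in an r x c count table.

    ``pearson_chi2`` is the uncorrected Pearson statistic; ``fisher_exact``
    (2x2 only) is the two-sided exact test summing tables with probability
    <= the observed one; ``auto`` picks Fisher for 2x2 tables with any
    expected cell below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("negative counts")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero-sum row or column")

    if method == "auto":
        if t.shape == (2, 2):
            expected = stats.contingency.expected_freq(t)
            method = "fisher_exact" if (expected < 5).any() else "pearson_chi2"
        else:
            method = "pearson_chi2"

    if method == "pearson_chi2":
        chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
        return ContingencyResult(chi2=float(chi2), df=int(df), p_value=float(p),
                                 method="pearson_chi2", table=t.astype(int))
    if method == "fisher_exact":
        if t.shape != (2, 2):
            raise ValueError("fisher_exact supports 2x2 tables only")
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
        return ContingencyResult(chi2=None, df=None, p_value=float(p),
                                 method="fisher_exact", table=t.astype(int))
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values, alpha: float = 0.05, m: int | None = None):
    """Bonferroni-corrected significance flags.

    ``m`` defaults to the number of p-values supplied; the study-style
    override (e.g. correcting for all loci rather than all performed tests)
    is available by passing ``m`` explicitly.

    Returns ``(flags, threshold)`` with ``flags[i] = p_i < alpha / m``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m_eff = m if m is not None else p.size
    if m_eff < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m_eff
    return p < threshold, threshold
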