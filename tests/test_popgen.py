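import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cyp2d6pop.popgen import (
    diversity,
    ewens_watterson,
    exact_differentiation,
    pairwise_fst,
    sample_esf_partitions,
)
from cyp2d6pop.popstats import contingency_test


# -- diversity ------------------------------------------------------------

def test_haplotype_diversity_hand_value():
    d = diversity(pd.Series({"00": 2, "01": 1, "11": 1}))
    assert d.H == pytest.approx(0.8333, abs=1e-4)
    assert d.n == 4 and d.k == 3


def test_single_haplotype_zero_diversity():
    d = diversity(pd.Series({"0101": 7}))
    assert d.H == 0 and d.pi == 0 and d.L == 0


def test_nucleotide_diversity_direct_pairwise_oracle():
    """pi equals the mean per-polymorphic-site difference over all ordered
    gene-copy pairs (without replacement), computed by brute force."""
    counts = {"0011": 5, "1100": 4, "0000": 1}
    copies = [h for h, c in counts.items() for _ in range(c)]
    n = len(copies)
    L = 4
    diffs = [
        sum(a != b for a, b in zip(copies[i], copies[j]))
        for i in range(n) for j in range(n) if i != j
    ]
    oracle = np.mean(diffs) / L  # E[d]/L over pairs without replacement
    d = diversity(pd.Series(counts))
    assert d.pi == pytest.approx(oracle, rel=1e-12)
    # the two-haplotype balanced case converges to half a difference per site
    d2 = diversity(pd.Series({"00": 500, "11": 500}))
    assert d2.pi == pytest.approx(0.5, abs=1e-3)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.integers(1, 100), min_size=2, max_size=10))
def test_gene_diversity_formula_property(counts):
    """H equals the one-line estimator n/(n-1)(1 - sum p^2)."""
    n = sum(counts)
    haps = {format(i, "04b"): c for i, c in enumerate(counts)}
    d = diversity(pd.Series(haps))
    oracle = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts))
    assert d.H == pytest.approx(oracle, abs=1e-12)


# -- pairwise Phi_ST ------------------------------------------------------

def test_fst_hand_computed_amova():
    """8:2 vs 2:8 of two haplotypes one step apart: SSD_T=5, SSD_W=3.2,
    n_c=10 gives sigma_a=0.1622, sigma_w=0.1778, Phi_ST=0.4771."""
    r = pairwise_fst(pd.Series({"0": 8, "1": 2}), pd.Series({"0": 2, "1": 8}),
                     n_perm=100, seed=0)
    assert r.fst == pytest.approx(0.4771, abs=1e-4)


def test_fst_limits():
    fixed = pairwise_fst(pd.Series({"0": 10}), pd.Series({"1": 10}),
                         n_perm=50, seed=0)
    assert fixed.fst == pytest.approx(1.0)
    same = pairwise_fst(pd.Series({"0": 5, "1": 5}), pd.Series({"0": 5, "1": 5}),
                        n_perm=50, seed=0)
    assert abs(same.fst) < 1e-12


def test_fst_p_invariant_to_haplotype_relabeling():
    a = pd.Series({"00": 7, "11": 3})
    b = pd.Series({"00": 2, "11": 8})
    ra = pairwise_fst(a, b, n_perm=500, seed=42, distance="identity")
    swap = {"00": "11", "11": "00"}
    a2 = pd.Series({swap[h]: c for h, c in a.items()})
    b2 = pd.Series({swap[h]: c for h, c in b.items()})
    rb = pairwise_fst(a2, b2, n_perm=500, seed=42, distance="identity")
    assert ra.p_value == rb.p_value and ra.fst == pytest.approx(rb.fst)


def test_fst_needs_permutations():
    with pytest.raises(ValueError):
        pairwise_fst(pd.Series({"0": 5}), pd.Series({"1": 5}), n_perm=0)


# -- exact differentiation ------------------------------------------------

def test_exact_differentiation_identical_pops():
    tab = pd.DataFrame({"a": [20, 20], "b": [20, 20]})
    assert exact_differentiation(tab, n_mc=2000, seed=1) > 0.5


def test_exact_differentiation_disjoint_pops():
    tab = pd.DataFrame({"a": [20, 0], "b": [0, 20]})
    assert exact_differentiation(tab, n_mc=10_000, seed=1) <= 0.001


def test_exact_differentiation_single_haplotype():
    assert exact_differentiation(pd.DataFrame({"a": [10], "b": [10]})) == 1.0


def test_exact_differentiation_2x2_matches_fisher():
    tab = pd.DataFrame({"a": [8, 2], "b": [1, 9]})
    p_mc = exact_differentiation(tab, n_mc=20_000, seed=3)
    p_fisher = contingency_test(tab.to_numpy(), method="fisher_exact").p_value
    assert p_mc == pytest.approx(p_fisher, abs=0.01)


# -- Ewens-Watterson ------------------------------------------------------

def _esf_conditional_oracle(n, k):
    """Exhaustive conditional ESF: P(partition | n, k) proportional to
    n! / (prod n_i * prod_j m_j!) over partitions of n into k parts."""
    def partitions(n, k, largest):
        if k == 1:
            if n <= largest:
                yield (n,)
            return
        for first in range(min(n - k + 1, largest), 0, -1):
            for rest in partitions(n - first, k - 1, first):
                yield (first,) + rest

    weights = {}
    for part in partitions(n, k, n):
        mult = Counter(part)
        w = math.factorial(n)
        for size in part:
            w //= size
        for m in mult.values():
            w //= math.factorial(m)
        weights[part] = w
    total = sum(weights.values())
    return {p: w / total for p, w in weights.items()}


def test_ew_exact_four_gene_example():
    """n=4, k=2: the null is P(3,1)=8/11, P(2,2)=3/11; E[F]=0.5909 and the
    even configuration has lower-tail p = 3/11."""
    oracle = _esf_conditional_oracle(4, 2)
    assert oracle[(3, 1)] == pytest.approx(8 / 11)
    assert oracle[(2, 2)] == pytest.approx(3 / 11)
    ew = ewens_watterson(pd.Series({"a": 2, "b": 2}), n_null=100_000, seed=0)
    assert ew.observed_F == pytest.approx(0.5)  # configuration (2,2)
    assert ew.expected_F == pytest.approx(8 / 11 * 0.625 + 3 / 11 * 0.5, abs=0.005)
    assert ew.p_value == pytest.approx(3 / 11, abs=0.01)


@pytest.mark.parametrize("n,k", [(n, k) for n in range(2, 9)
                                 for k in range(2, min(n, 4) + 1) if k < n])
def test_ew_sampler_matches_exhaustive_oracle(n, k):
    """Sampled partition probabilities agree with the exhaustive conditional
    ESF for all small (n, k) within Monte-Carlo error at 100,000 draws."""
    oracle = _esf_conditional_oracle(n, k)
    rng = np.random.default_rng(7)
    draws = sample_esf_partitions(n, k, 100_000, rng)
    freq = Counter(tuple(sorted(p, reverse=True)) for p in draws)
    for part, p in oracle.items():
        se = math.sqrt(p * (1 - p) / 100_000)
        assert freq.get(part, 0) / 100_000 == pytest.approx(p, abs=5 * se + 1e-4)


def test_ew_degenerate_cases():
    mono = ewens_watterson(pd.Series({"a": 9}))
    assert mono.observed_F == 1.0 and mono.p_value == 1.0
    unique = ewens_watterson(pd.Series({c: 1 for c in "abcdef"}))
    assert unique.p_value == 1.0


def test_ew_synthetic_cohort_bounds(phased_cohort):
    """Observed homozygosity and p-value stay in their structural ranges on
    every synthetic cohort group."""
    from cyp2d6pop.genotypes import COMBINED

    for pop, hfs in phased_cohort.freq_sets.items():
        if pop == COMBINED:
            continue
        ew = ewens_watterson(hfs, n_null=2000, seed=11)
        assert 1 / ew.k <= ew.observed_F <= 1
        assert 0 <= ew.p_value <= 1


def test_ew_drift_pattern_on_study_scale_configuration():
    """A Balkan-like sample (n=190 gene copies, k=46 haplotypes, a few
    common haplotypes over a long rare tail) shows the drift-typical
    pattern: observed homozygosity above the conditional-ESF expectation
    with an unremarkable lower-tail p."""
    counts = [25, 19, 16, 14, 12, 11, 10, 9, 8, 7, 6, 5, 4, 4, 3, 3,
              2, 2, 2, 2] + [1] * 26
    hfs = pd.Series({f"h{i}": c for i, c in enumerate(counts)})
    ew = ewens_watterson(hfs, n_null=10_000, seed=9)
    assert ew.n == 190 and ew.k == 46
    assert ew.observed_F >= ew.expected_F
    assert 0.5 <= ew.p_value <= 1.0
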