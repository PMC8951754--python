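import itertools

import numpy as np
import pandas as pd
import pytest

from cyp2d6pop.phasing import EMPhaser, em_phase, switch_error_rate
from cyp2d6pop.synthetic import CohortSpec, PoolEntry, PopulationSpec, simulate


def test_all_homozygous_sample_has_unique_phase():
    ph = EMPhaser(seed=0).fit(np.array([[0, 2, 0, 2]]))
    row = ph.phases_.iloc[0]
    assert row.hap1 == "0101" and row.hap2 == "0101"
    assert row.posterior == 1.0


def test_single_het_sample_has_unique_phase():
    ph = EMPhaser(seed=0).fit(np.array([[0, 1, 2]]))
    row = ph.phases_.iloc[0]
    assert {row.hap1, row.hap2} == {"001", "011"}
    assert row.posterior == 1.0


def test_loglik_trace_monotone():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(40, 6))
    ph = EMPhaser(seed=2, n_restarts=1).fit(g)
    trace = np.array(ph.loglik_trace_)
    assert (np.diff(trace) >= -1e-9).all()


def test_unambiguous_data_equals_direct_counting():
    """With at most one het site per sample the phase is certain and EM must
    reproduce plain haplotype counting."""
    g = np.array([[0, 0], [2, 0], [2, 2], [1, 0], [0, 0], [2, 0]])
    ph = EMPhaser(seed=0).fit(g)
    expected = {"00": 5 / 12, "10": 5 / 12, "11": 2 / 12}
    for h, f in expected.items():
        assert ph.frequencies_full_[h] == pytest.approx(f, abs=1e-9)


def _grid_search_loglik(genotypes, haps, step=0.01):
    """Maximum multinomial-pair log-likelihood over a frequency grid on the
    simplex (independent oracle for the 2-locus problem)."""
    best = -np.inf
    ticks = np.arange(0, 1 + step / 2, step)
    for p1, p2, p3 in itertools.product(ticks, repeat=3):
        p4 = 1 - p1 - p2 - p3
        if p4 < -1e-9:
            continue
        f = dict(zip(haps, (p1, p2, p3, max(p4, 0.0))))
        ll = 0.0
        for row in genotypes:
            s = 0.0
            for h1 in haps:
                for h2 in haps:
                    if all(int(a) + int(b) == c for a, b, c in zip(h1, h2, row)):
                        s += f[h1] * f[h2]
            if s <= 0:
                ll = -np.inf
                break
            ll += np.log(s)
        best = max(best, ll)
    return best


def test_two_locus_em_matches_grid_search_oracle():
    haps = ["00", "01", "10", "11"]
    true_f = np.array([0.5, 0.3, 0.2, 0.0])
    rng = np.random.default_rng(1)
    draws = rng.choice(4, size=(20, 2), p=true_f)
    genotypes = np.array(
        [[int(haps[a][j]) + int(haps[b][j]) for j in range(2)] for a, b in draws]
    )
    ph = EMPhaser(seed=1, n_restarts=5, tol=1e-10).fit(genotypes)
    oracle = _grid_search_loglik(genotypes.tolist(), haps)
    # EM attains the grid-search maximum (up to grid resolution)
    assert ph.loglik_ >= oracle - 1e-6


def test_missing_genotypes_are_marginalized():
    g = np.array([[0, 0], [0, 0], [2, 2], [2, 2], [0, -1]])
    ph = EMPhaser(seed=0).fit(g)
    row = ph.phases_.iloc[-1]
    # the missing site resolves to the ref allele carried by the common pool
    assert row.hap1 == "00" and row.hap2 == "00"


def test_all_missing_sample_skipped_with_warning():
    with pytest.warns(UserWarning, match="skipped"):
        ph = EMPhaser(seed=0).fit(np.array([[0, 0], [-1, -1]]))
    assert ph.skipped_samples_ == ["S1"]


# -- switch error ---------------------------------------------------------

def _phase_df(rows):
    return pd.DataFrame(rows, columns=["sample", "hap1", "hap2"])


def test_switch_error_zero_when_identical():
    t = _phase_df([("s", "0011", "1100")])
    assert switch_error_rate(t, t) == 0.0


def test_switch_error_one_for_flipped_double_het():
    t = _phase_df([("s", "00", "11")])
    f = _phase_df([("s", "01", "10")])
    assert switch_error_rate(t, f) == 1.0


def test_switch_error_sample_mismatch_is_error():
    with pytest.raises(ValueError):
        switch_error_rate(_phase_df([("a", "0", "0")]), _phase_df([("b", "0", "0")]))


def test_switch_error_low_on_synthetic_cohort():
    """Five common 28-locus haplotypes, 100 individuals: phasing is near
    perfect."""
    loci = [f"rs{i}" for i in range(28)]
    haps = {
        "0" * 28: 0.35,
        "1" + "0" * 27: 0.25,
        "11" + "0" * 26: 0.15,
        "0" * 26 + "11": 0.15,
        "1" * 4 + "0" * 24: 0.10,
    }
    spec = CohortSpec(
        populations=[
            PopulationSpec(
                "pop", 100,
                [PoolEntry(h, "*1", f) for h, f in haps.items()],
            )
        ],
        locus_ids=loci,
        seed=1,
    )
    gm, truth = simulate(spec)
    res = em_phase(gm, seed=1, n_restarts=3)
    rate = switch_error_rate(
        truth[["sample", "hap1", "hap2"]], res.phases[["sample", "hap1", "hap2"]]
    )
    assert rate < 0.05


def test_pooled_frequency_sets_sum_to_one(phased_cohort):
    for hfs in phased_cohort.freq_sets.values():
        assert hfs.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (hfs.freqs >= 0).all()


def test_phase_pairs_reproduce_genotypes(default_cohort, phased_cohort):
    gm, _ = default_cohort
    calls = {s: gm.calls[i] for i, s in enumerate(gm.samples)}
    for r in phased_cohort.phases.itertuples():
        dosage = [int(a) + int(b) for a, b in zip(r.hap1, r.hap2)]
        assert (calls[r.sample] == dosage).all()
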