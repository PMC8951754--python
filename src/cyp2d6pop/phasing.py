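"""Statistical haplotype phasing by expectation-maximization.

Multilocus genotypes over L biallelic SNPs are resolved into pairs of
haplotypes (strings over {0,1}) under the multinomial haplotype-pair
likelihood: an individual with haplotype pair (h, g) has probability
2*p_h*p_g (h != g) or p_h^2. EM alternates expected pair weights with
frequency updates; the log-likelihood is non-decreasing by construction and
is asserted at every iteration. Multiple restarts with Dirichlet-jittered
initial frequencies guard against local optima. This is a desk-scale
replacement for coalescent-prior samplers (PHASE-style): deterministic given
a seed and adequate for tightly linked loci carrying few common haplotypes.

Missing genotypes are marginalized over all compatible completions during
pair enumeration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EMPhaser", "PhasingResult", "HaplotypeFrequencySet",
           "em_phase", "switch_error_rate"]


@dataclass
class HaplotypeFrequencySet:
    """Haplotype -> frequency map for one population (or the pooled sample)."""

    population: str
    freqs: pd.Series  # index: haplotype string, values sum to 1
    n_genes: int

    def __post_init__(self) -> None:
        total = float(self.freqs.sum())
        if self.freqs.size and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if (self.freqs < 0).any():
            raise ValueError("negative haplotype frequency")


@dataclass
class PhasingResult:
    freq_sets: dict[str, HaplotypeFrequencySet]
    phases: pd.DataFrame  # sample, population, hap1, hap2, posterior
    loglik: float
    haplotypes: list[str]
    skipped_samples: list[str] = field(default_factory=list)


def _site_options(call: int) -> list[tuple[str, str]]:
    if call == 0:
        return [("0", "0")]
    if call == 2:
        return [("1", "1")]
    if call == 1:
        return [("0", "1"), ("1", "0")]
    return [("0", "0"), ("0", "1"), ("1", "0"), ("1", "1")]  # missing


def _compatible_pairs(row: np.ndarray, max_pairs: int) -> list[tuple[str, str]] | None:
    """Unordered haplotype pairs consistent with one genotype row, or None
    when the enumeration would exceed ``max_pairs``."""
    sizes = [len(_site_options(int(c))) for c in row]
    total = 1
    for s in sizes:
        total *= s
        if total > 4 * max_pairs:
            return None
    pairs: set[tuple[str, str]] = set()
    for combo in itertools.product(*(_site_options(int(c)) for c in row)):
        a = "".join(x[0] for x in combo)
        b = "".join(x[1] for x in combo)
        pairs.add((a, b) if a <= b else (b, a))
    return sorted(pairs)


class EMPhaser:
    """EM estimator of haplotype frequencies with per-sample phase calls.

    Parameters
    ----------
    max_iter, tol : EM stopping rule (delta log-likelihood below ``tol``).
    n_restarts : restarts with Dirichlet(1)-jittered initial frequencies;
        the first restart starts uniform; best log-likelihood wins.
    seed : RNG seed for the jitter (recorded on the instance).
    max_pairs : per-sample cap on enumerated haplotype-pair resolutions;
        samples above the cap (or with every site missing) are skipped with
        a warning.

    Fitted attributes (trailing underscore): ``haplotypes_``,
    ``frequencies_`` (pruned & renormalized), ``frequencies_full_``,
    ``loglik_``, ``loglik_trace_``, ``phases_``.
    """

    def __init__(self, max_iter: int = 1000, tol: float = 1e-8,
                 n_restarts: int = 5, seed: int | None = None,
                 max_pairs: int = 8192) -> None:
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_pairs = max_pairs

    # -- fitting ----------------------------------------------------------
    def fit(self, genotypes: np.ndarray, sample_ids=None) -> "EMPhaser":
        g = np.asarray(genotypes)
        n, L = g.shape
        if sample_ids is None:
            sample_ids = [f"S{i}" for i in range(n)]
        registry: dict[str, int] = {}
        pair_a, pair_b, pair_mult, pair_sample = [], [], [], []
        sample_slices: list[slice | None] = []
        skipped: list[str] = []
        used = 0
        for i in range(n):
            if (g[i] < 0).all() and L > 0:
                pairs = None
            else:
                pairs = _compatible_pairs(g[i], self.max_pairs)
                if pairs is not None and len(pairs) > self.max_pairs:
                    pairs = None
            if pairs is None:
                warnings.warn(f"sample {sample_ids[i]} skipped (unresolvable "
                              "or too many phase resolutions)")
                skipped.append(sample_ids[i])
                sample_slices.append(None)
                continue
            start = len(pair_a)
            for a, b in pairs:
                ia = registry.setdefault(a, len(registry))
                ib = registry.setdefault(b, len(registry))
                pair_a.append(ia)
                pair_b.append(ib)
                pair_mult.append(1.0 if a == b else 2.0)
                pair_sample.append(used)
            sample_slices.append(slice(start, len(pair_a)))
            used += 1
        if used == 0:
            raise ValueError("no usable samples")

        pa = np.array(pair_a)
        pb = np.array(pair_b)
        mult = np.array(pair_mult)
        sidx = np.array(pair_sample)
        K = len(registry)
        rng = np.random.default_rng(self.seed)

        best = None
        for r in range(self.n_restarts):
            if r == 0:
                f = np.full(K, 1.0 / K)
            else:
                f = rng.dirichlet(np.ones(K))
            trace = []
            prev = -np.inf
            for _ in range(self.max_iter):
                w = mult * f[pa] * f[pb]
                s = np.bincount(sidx, weights=w, minlength=used)
                loglik = float(np.log(s).sum())
                # monotonicity of EM, with float slack
                assert loglik >= prev - 1e-9 * max(1.0, abs(prev)), \
                    "EM log-likelihood decreased"
                trace.append(loglik)
                r_w = w / s[sidx]
                counts = (np.bincount(pa, weights=r_w, minlength=K)
                          + np.bincount(pb, weights=r_w, minlength=K))
                f = counts / (2.0 * used)
                if loglik - prev < self.tol:
                    break
                prev = loglik
            if best is None or trace[-1] > best[0]:
                best = (trace[-1], f, trace)

        self.loglik_, f, self.loglik_trace_ = best
        self.haplotypes_ = [h for h, _ in sorted(registry.items(), key=lambda kv: kv[1])]
        self.frequencies_full_ = pd.Series(f, index=self.haplotypes_)
        cutoff = 1.0 / (2 * used * 10)
        kept = self.frequencies_full_[self.frequencies_full_ >= cutoff]
        self.frequencies_ = kept / kept.sum()
        self.n_genes_ = 2 * used
        self.skipped_samples_ = skipped

        # most-probable phase per sample
        rows = []
        f_arr = f
        for i, sl in enumerate(sample_slices):
            if sl is None:
                continue
            w = mult[sl] * f_arr[pa[sl]] * f_arr[pb[sl]]
            total = w.sum()
            post = w / total if total > 0 else np.full(w.size, 1.0 / w.size)
            # deterministic tie-break: highest posterior, then lexicographic pair
            cand = sorted(
                range(w.size),
                key=lambda j: (-post[j], self.haplotypes_[pa[sl][j]],
                               self.haplotypes_[pb[sl][j]]),
            )[0]
            h1 = self.haplotypes_[pa[sl][cand]]
            h2 = self.haplotypes_[pb[sl][cand]]
            if h2 < h1:
                h1, h2 = h2, h1
            rows.append(dict(sample=sample_ids[i], hap1=h1, hap2=h2,
                             posterior=float(post[cand])))
        self.phases_ = pd.DataFrame(rows)
        return self


def em_phase(gm, per_pop: bool = False, **em_kwargs) -> PhasingResult:
    """Phase a :class:`~cyp2d6pop.genotypes.GenotypeMatrix`.

    By default all populations are phased jointly on the pooled sample
    (matching total-sample haplotype counting) and per-population frequency
    sets are derived from the per-sample best phases; ``per_pop=True`` runs
    an independent EM per population instead.
    """
    from .genotypes import COMBINED

    if per_pop:
        freq_sets: dict[str, HaplotypeFrequencySet] = {}
        all_phases = []
        haps: set[str] = set()
        loglik = 0.0
        skipped: list[str] = []
        for p in gm.populations:
            sub = gm.subset_population(p)
            ph = EMPhaser(**em_kwargs).fit(sub.calls, sub.samples)
            freq_sets[p] = HaplotypeFrequencySet(p, ph.frequencies_, ph.n_genes_)
            df = ph.phases_.copy()
            df.insert(1, "population", p)
            all_phases.append(df)
            haps.update(df["hap1"])
            haps.update(df["hap2"])
            loglik += ph.loglik_
            skipped += ph.skipped_samples_
        phases = pd.concat(all_phases, ignore_index=True)
        return PhasingResult(freq_sets, phases, loglik, sorted(haps), skipped)

    phaser = EMPhaser(**em_kwargs).fit(gm.calls, gm.samples)
    pop_of = dict(zip(gm.samples, gm.pops))
    phases = phaser.phases_.copy()
    phases.insert(1, "population", phases["sample"].map(pop_of))
    reconstructed = sorted(set(phases["hap1"]) | set(phases["hap2"]))
    freq_sets = {
        COMBINED: HaplotypeFrequencySet(COMBINED, phaser.frequencies_,
                                        phaser.n_genes_)
    }
    for p in gm.populations:
        sub = phases[phases["population"] == p]
        copies = pd.concat([sub["hap1"], sub["hap2"]])
        counts = copies.value_counts().sort_index()
        freq_sets[p] = HaplotypeFrequencySet(p, counts / counts.sum(),
                                             int(counts.sum()))
    return PhasingResult(freq_sets, phases, phaser.loglik_,
                         reconstructed, phaser.skipped_samples_)


def switch_error_rate(truth: pd.DataFrame, inferred: pd.DataFrame) -> float:
    """Standard switch error over heterozygous sites.

    Both inputs need columns ``sample, hap1, hap2``; samples must match and
    each inferred pair must resolve the same genotype as the truth pair.
    Returns switches / switch opportunities (0 when there are none).
    """
    t = truth.set_index("sample")
    f = inferred.set_index("sample")
    if set(t.index) != set(f.index):
        raise ValueError("truth and inferred cover different samples")
    switches = 0
    opportunities = 0
    for s in t.index:
        th1, th2 = t.loc[s, "hap1"], t.loc[s, "hap2"]
        ih1, ih2 = f.loc[s, "hap1"], f.loc[s, "hap2"]
        geno_t = sorted((a, b) for a, b in zip(th1, th2))
        geno_i = sorted((a, b) for a, b in zip(ih1, ih2))
        if [tuple(sorted(x)) for x in geno_t] != [tuple(sorted(x)) for x in geno_i]:
            raise ValueError(f"genotype mismatch at sample {s}")
        het = [k for k in range(len(th1)) if th1[k] != th2[k]]
        if len(het) < 2:
            continue
        orient = [th1[k] == ih1[k] for k in het]
        switches += sum(orient[j] != orient[j + 1] for j in range(len(orient) - 1))
        opportunities += len(het) - 1
    return switches / opportunities if opportunities else 0.0
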