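# Methods

This note documents the statistical procedures implemented in `cyp2d6pop`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not emulate.

## Data model and locus filtering

Genotypes are biallelic, stored as alt-allele dosage (0/1/2, −1 missing)
per sample × variant, with a population label per sample. Variant
coordinates are the gene-relative positions conventional for *CYP2D6*
print-outs; they are opaque keys matched by rsID, and no genomic lift-over
or strand handling is attempted (the gene is minus-strand; all allele
states here follow the as-printed orientation). Missing genotypes are
excluded from every count, so per-variant denominators are called samples,
not cohort size.

**Phasing-locus selection.** A variant is excluded as *low heterozygosity*
when its minor allele (oriented on the pooled sample) is absent from all
but one population and occurs fewer than `min_private_count` (default 3,
i.e. "two or less") times there: such private near-singletons carry no
linkage information and destabilize phasing. Indels surviving that screen
are excluded separately as unphaseable. The low-heterozygosity rule is
applied *first*, so a rare private indel is classed as a
low-heterozygosity exclusion — this precedence is deliberate and matches
how population surveys report their exclusions; on the bundled 43-locus
study table it yields 14 low-het exclusions, 1 indel exclusion and 28
retained loci.

## Hardy–Weinberg and contingency testing

HWE uses the plain Pearson goodness-of-fit χ² with df = 1 and no
continuity correction, against expected proportions computed from the
observed allele frequency. A cell is untestable when one allele is absent
entirely. The exact (Wigginton-style) test is intentionally not used: the
χ² form is what the reference print-outs reproduce (e.g. counts 102/1/0
give p = 0.9605 under χ², while the exact test would give 1.0); for
extreme rare-allele configurations the two can differ wildly, but both are
then far below any correction threshold. Contingency tests are uncorrected
Pearson χ² for r×c tables and the two-sided Fisher exact test
(probability-ordering convention) for 2×2; `auto` switches to Fisher when
a 2×2 expected cell drops below 5. Larger sparse tables are handled by the
Monte-Carlo exact test in `popgen`. Bonferroni correction defaults to
m = number of tests performed, overridable when a study-wide m is wanted.

## EM haplotype phasing

Phasing maximizes the multinomial haplotype-pair likelihood
P(genotype) = Σ over compatible pairs of (2−δ_hg)·p_h·p_g by EM. Per
sample, every compatible unordered pair is enumerated (2^(h−1) for h het
sites; missing sites are marginalized by enumerating all completions);
samples above `max_pairs` (default 8192) resolutions or with no typed site
are skipped with a warning. The E-step/M-step loop asserts a non-decreasing
log-likelihood at every iteration and stops when the gain drops below
`tol` (1e−8). Initialisation is uniform over observed-compatible
haplotypes for the first restart plus Dirichlet(1)-jittered restarts
(default 5 in the estimator, 3 in the pipeline); the best log-likelihood
wins, and the seed is recorded. Output frequencies below 1/(20n) are
pruned and renormalized. Per-sample phases report the highest-posterior
pair, ties broken lexicographically.

This is a deliberate desk-scale replacement for coalescent-prior Gibbs
samplers (PHASE-style). For a few dozen tightly linked SNPs dominated by a
handful of common haplotypes, EM with restarts recovers pool frequencies
within binomial error and phases with near-zero switch error (both are
asserted in the tests); no recombination, partition–ligation or imputation
is attempted. Populations are phased jointly on the pooled sample by
default — mirroring total-sample haplotype reconstruction — with
per-population frequency sets derived by counting the per-sample best
phases; an independent per-population EM is available via `per_pop=True`.

## Star alleles and phenotypes

Definitions are data (TSV): name, function class, activity value, core tag
SNPs that must carry the alternate allele, and optional exclusion SNPs
that must not. Exclusions encode "without" constraints such as *10 = 100C>T
+ 4181G>C *without* the *4 splice defect; without them the *4 and *10
cores would overlap ambiguously. Matching is most-specific-wins (largest
satisfied core); equal-size maxima are flagged ambiguous. A haplotype
matching nothing is `*1` when it carries no alternate allele at any
core-defining site (alleles are then distinguished only by non-defining
variation) and `NDT` otherwise. Definitions whose core references an
untyped locus load with a warning and are marked partially evaluable.
Suballeles are collapsed to the parent star throughout.

Activity values: normal-function alleles (*1, *2, *34, *35) = 1;
*41 = 0.5; *10 = 0.25; no-function *4 = 0; the uncertain-function alleles
are pinned at *39 = 1, *22 = 0, *65 = 0.25 — the assignment consistent
with CPIC-style scoring under which every diplotype in the bundled
28-diplotype reference table classifies correctly (*65 is only constrained
to (0, 0.5]; 0.25 is the midpoint). Categories: PM = 0,
IM ∈ (0, 1], NM ∈ (1, 2]. Without copy-number calls a score above 2 is
unreachable, so no ultrarapid category exists.

## Haplotype-level statistics

*Diversity.* H = n/(n−1)·(1 − Σp²). Nucleotide diversity
π = n/(n−1)·Σ_{i<j} 2 p_i p_j d_ij / L with d = Hamming distance and L =
number of polymorphic sites within the sample; for two equifrequent
haplotypes differing at every site this converges to 0.5 per site (the
probability two random copies differ at a site), which the tests assert
via a brute-force pairwise oracle.

*Pairwise Φ_ST.* Two-level AMOVA with squared inter-haplotype distance =
Hamming (the haplotypic default of Arlequin-style software); a pure
frequency F_ST is available via `distance="identity"` since print-outs
rarely state which option was used. Variance components follow the
standard SSD decomposition with n_c correction. Significance: gene copies
are reallocated between the two samples (a multivariate hypergeometric
draw of one group from the pooled counts), p = Pr(Φ_perm ≥ Φ_obs) with
the +1 correction; default 100 000 permutations. Negative estimates are
reported as computed and flagged; the single degenerate case of exactly
zero among-group SSD (e.g. identical samples) reports 0.

*Exact test of differentiation.* Tables with the observed margins are
drawn by Patefield's algorithm; p is the +1-corrected fraction with
conditional (multivariate hypergeometric) probability ≤ the observed
table's. Default 10 000 tables; a single-haplotype table returns p = 1.

*Ewens–Watterson.* Observed F = Σp². The null is the Ewens sampling
formula conditional on (n, k), which is θ-free and equals the cycle-type
law of a uniform permutation of n elements with k cycles. The sampler is
exact, not rejection-based: block sizes are drawn sequentially with
probabilities from the unsigned-Stirling-number recursion (log-space;
distributions cached per state; draws sharing a prefix batched through
multinomial splits), so study-scale samples (n ≈ 200, k ≈ 46, 10 000
nulls) take about a second. p = Pr(F_null ≤ F_obs), the lower-tail
convention under which balancing selection (too-even frequencies) is the
alarming direction and drift-shaped samples give large p; k = 1 and k = n
admit a single configuration and return p = 1 analytically. Correctness is
tested against exhaustive enumeration of the conditional law for all
small (n, k).

## Median-joining networks

Binary haplotypes only (as produced by phasing). Feasible links are pairs
whose direct Hamming distance does not exceed the minimax MST-path
distance by more than ε (default 0, reproducing the minimum spanning
network). Candidate medians are per-site majority vectors of triples
(u, v, w) with u−v and u−w feasible; medians are added greedily while they
reduce the total MST length (asserted never to increase), then medians of
degree ≤ 2 are pruned — on binary Hamming data the triangle equality means
such nodes never shorten a connection, so surviving medians have degree
≥ 3. All tie-breaks are lexicographic; the network is invariant under
input permutation. Node frequency, star label and population are metadata
passed through to GraphML/DOT export, not computed here.

## Synthetic cohort

The generator emulates three endogamous groups of 98/108/117 individuals.
Each individual draws two haplotypes i.i.d. from its group's pool
(within-group random mating; an optional `f_is` adds an
identical-by-descent fraction for robustness experiments — the default is
0 because the observed cohorts are themselves consistent with HWE). Pools
hold one canonical 28-locus backbone per star allele (core tags plus
tightly linked non-core sites) at the observed per-group star frequencies.
The Balkan-private intron variant rs368389952 is injected onto *1
backgrounds at its observed count of 18 gene copies, reproducing the
private-rare-variant signature without disturbing star calls.

What this does **not** emulate: suballele diversity below the star level.
The real cohorts carry ~37–47 distinct haplotypes per group because
non-defining variants ride on star backgrounds; the synthetic pools give
~10. Consequently haplotype counts, diversity magnitudes and
Ewens–Watterson expectations on synthetic groups are not comparable to
the published per-group values, and the drift-pattern check
(observed ≥ expected homozygosity at unremarkable p) is exercised on a
study-scale configuration (n = 190, k = 46) constructed directly. Passing
tests therefore validate the estimators and the pipeline plumbing, not the
published diversity magnitudes, which would require the unpublished raw
haplotypes.

## Problem sizes and determinism

Default test/pipeline problem sizes (323 individuals × 28 loci; 100–1000
permutations and null samples in tests, with the production defaults of
100 000 / 10 000 available in the run configuration) were chosen so the
whole suite runs in about a minute on one core while keeping every
statistical check well-powered. All stochastic stages consume seeds spawned
from the single run seed; two runs with the same configuration produce
byte-identical tables, and the JSON manifest records seeds, thresholds and
library versions needed to re-run any stage in isolation.
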