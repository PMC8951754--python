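"""Star-allele translation of phased haplotypes and metabolizer phenotypes.

A star allele (PharmVar-style nomenclature, e.g. CYP2D6*4) is defined by a
set of core variants that must carry the alternate allele, optionally with
exclusion variants that must NOT carry it (encoding definitions such as
"*10 = 100C>T + 4181G>C without the *4 splice defect"). Matching is
most-specific-wins: among definitions whose full core set is satisfied, the
one with the largest core set is called; equal-size maxima are flagged
ambiguous. A haplotype matching no definition maps to *1 (the reference
allele, empty core) when it carries no alternate allele at any core-defining
site, and to NDT (not determined) otherwise.

Diplotypes are scored with per-allele activity values; the activity score
(the sum over the two alleles) bins individuals into normal (1 < score <= 2),
intermediate (0 < score <= 1) and poor (score = 0) metabolizers. With no
copy-number calls in the assay a score above 2 is unreachable, so no
ultrarapid category is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "NDT",
    "StarAlleleDefinition",
    "StarCall",
    "PhenotypeCall",
    "load_definitions",
    "call_star",
    "call_phenotype",
    "classify_activity",
]

NDT = "NDT"


@dataclass(frozen=True)
class StarAlleleDefinition:
    name: str
    function: str  # normal | decreased | no_function | uncertain
    activity: float
    core: frozenset[str]  # rsIDs that must carry the alternate allele
    exclude: frozenset[str] = frozenset()  # rsIDs that must not
    evaluable: bool = True  # False when a core rsID is not among typed loci


@dataclass(frozen=True)
class StarCall:
    haplotype: str
    star: str
    matched_core_count: int
    ambiguous: bool


@dataclass(frozen=True)
class PhenotypeCall:
    sample: str | None
    star1: str
    star2: str
    activity_score: float | None
    category: str | None  # NM | IM | PM | None (undetermined, NDT present)


def _bundled_path():
    return resources.files("cyp2d6pop.data").joinpath("star_alleles.tsv")


def load_definitions(
    table: str | Path | None = None, typed_loci: list[str] | None = None
) -> list[StarAlleleDefinition]:
    """Load star-allele definitions from a TSV with columns
    ``star, function, activity, core, exclude`` (semicolon-joined rsIDs,
    "." for empty).  Defaults to the bundled CYP2D6 table covering the ten
    star alleles observed in the study cohort."""
    if table is None:
        with resources.as_file(_bundled_path()) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    if df["star"].duplicated().any():
        dup = df.loc[df["star"].duplicated(), "star"].tolist()
        raise ValueError(f"duplicate star allele definitions: {dup}")
    defs: list[StarAlleleDefinition] = []
    for r in df.itertuples():
        core = frozenset() if r.core in (".", "", None) else frozenset(r.core.split(";"))
        excl = frozenset() if r.exclude in (".", "", None) else frozenset(r.exclude.split(";"))
        evaluable = True
        if typed_loci is not None:
            missing = (core | excl) - set(typed_loci)
            if missing:
                warnings.warn(
                    f"{r.star}: core/exclude variants not among typed loci: "
                    f"{sorted(missing)}; definition only partially evaluable"
                )
                evaluable = False
        defs.append(
            StarAlleleDefinition(
                name=r.star,
                function=r.function,
                activity=float(r.activity),
                core=core,
                exclude=excl,
                evaluable=evaluable,
            )
        )
    return defs


def call_star(
    haplotype: str, defs: list[StarAlleleDefinition], locus_ids: list[str]
) -> StarCall:
    """Translate one 0/1 haplotype string into star nomenclature."""
    if len(haplotype) != len(locus_ids):
        raise ValueError(
            f"haplotype length {len(haplotype)} != locus count {len(locus_ids)}"
        )
    state = dict(zip(locus_ids, haplotype))
    typed = set(locus_ids)

    matches = []
    for d in defs:
        if not d.core:
            continue
        typed_core = d.core & typed
        if not typed_core:
            continue  # fully untypeable definition cannot match
        if all(state[r] == "1" for r in typed_core) and not any(
            state[r] == "1" for r in d.exclude & typed
        ):
            matches.append((len(typed_core), d.name))
    if matches:
        best = max(m[0] for m in matches)
        top = sorted(name for size, name in matches if size == best)
        return StarCall(haplotype, top[0], best, ambiguous=len(top) > 1)

    core_sites = set().union(*(d.core for d in defs)) & typed
    if any(state[r] == "1" for r in core_sites):
        return StarCall(haplotype, NDT, 0, ambiguous=False)
    return StarCall(haplotype, "*1", 0, ambiguous=False)


def classify_activity(score: float) -> str:
    if score == 0:
        return "PM"
    if score <= 1:
        return "IM"
    if score <= 2:
        return "NM"
    raise ValueError(f"activity score {score} out of range (no CNV support)")


def call_phenotype(
    star1: str, star2: str, defs: list[StarAlleleDefinition], sample: str | None = None
) -> PhenotypeCall:
    """Score an unordered star-allele pair into a metabolizer category.

    A pair containing NDT (or a star without a definition) is returned with
    ``category=None`` and is excluded from phenotype tallies downstream.
    """
    by_name = {d.name: d for d in defs}
    s1, s2 = sorted((star1, star2))
    if s1 not in by_name or s2 not in by_name:
        return PhenotypeCall(sample, s1, s2, None, None)
    score = by_name[s1].activity + by_name[s2].activity
    return PhenotypeCall(sample, s1, s2, score, classify_activity(score))
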