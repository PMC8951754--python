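"""Sample/variant/genotype data model, I/O, and the phasing-locus filter.

Genotypes are biallelic and stored as alt-allele dosage per (sample, variant):
0 = hom ref, 1 = het, 2 = hom alt, -1 = missing. Population labels attach to
samples; per-population genotype counting and the low-heterozygosity exclusion
rule used to select loci for haplotype phasing live here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "GenotypeCounts",
    "read_genotypes",
    "read_labels",
    "write_vcf",
    "write_labels",
    "count_genotypes",
    "select_phasing_loci",
    "load_table1",
    "table1_matrix_counts",
    "COMBINED",
]

#: pseudo-population name for the pooled sample in count tables
COMBINED = "combined"


class GenotypeError(ValueError):
    """Malformed genotype input."""


@dataclass(frozen=True)
class Variant:
    """A biallelic variant keyed by rsID.

    ``gene_pos`` is the gene-relative coordinate as conventionally printed for
    CYP2D6 (an opaque integer key; no genomic lift-over is attempted).
    """

    id: str
    gene_pos: int
    ref: str
    alt: str
    kind: str = field(default="")
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise GenotypeError(f"{self.id}: ref and alt alleles are identical")
        kind = "indel" if len(self.ref) != len(self.alt) else "snv"
        if self.kind and self.kind != kind:
            raise GenotypeError(
                f"{self.id}: kind={self.kind!r} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )
        object.__setattr__(self, "kind", kind)

    @property
    def is_indel(self) -> bool:
        return self.kind == "indel"


class GenotypeMatrix:
    """Per-sample biallelic genotypes with population labels.

    Parameters
    ----------
    variants : sequence of Variant
    samples : sequence of sample ids (unique)
    pops : population label per sample
    calls : int array (n_samples, n_variants); alt dosage 0/1/2, -1 missing
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        samples: Sequence[str],
        pops: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.variants = list(variants)
        self.samples = list(samples)
        self.pops = list(pops)
        self.calls = np.asarray(calls, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicate sample ids")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate variant ids")
        if len(self.pops) != len(self.samples):
            raise GenotypeError("population label count != sample count")
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid call {self.calls[i, j]} at sample {self.samples[i]}, "
                f"variant {self.variants[j].id}"
            )

    # -- basic views ------------------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def variant_index(self, rsid: str) -> int:
        try:
            return self.variant_ids.index(rsid)
        except ValueError:
            raise KeyError(rsid) from None

    def subset_variants(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.variant_index(r) for r in rsids]
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            self.samples,
            self.pops,
            self.calls[:, idx],
        )

    def subset_population(self, pop: str) -> "GenotypeMatrix":
        keep = [i for i, p in enumerate(self.pops) if p == pop]
        return GenotypeMatrix(
            self.variants,
            [self.samples[i] for i in keep],
            [self.pops[i] for i in keep],
            self.calls[keep],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeMatrix({len(self.samples)} samples x "
            f"{len(self.variants)} variants, pops={self.populations})"
        )


# -- I/O -----------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column sample->population TSV (optional header line)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenotypeError(f"{path}:{ln}: expected 2 tab-separated columns")
            if ln == 1 and parts[0].lower() in ("sample", "sample_id"):
                continue
            labels[parts[0]] = parts[1]
    return labels


_GT_RE = re.compile(r"^([0-9.])[/|]([0-9.])$")


def _parse_gt(gt: str, where: str) -> int:
    m = _GT_RE.match(gt)
    if not m:
        raise GenotypeError(f"malformed genotype field {gt!r} at {where}")
    a, b = m.group(1), m.group(2)
    if "." in (a, b):
        return -1
    return int(a) + int(b)


def read_genotypes(
    vcf_or_tsv: str | Path,
    labels: str | Path | dict[str, str],
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Load genotypes from a VCF (v4.x) or the documented TSV dialect.

    The TSV dialect has columns ``rsid pos ref alt <sample...>`` with GT
    strings (``0/0``, ``0/1``, ``1/1``, ``./.``).  Every sample must be
    present in the label table; multiallelic VCF records are rejected unless
    ``split_multiallelic`` (the study loci are biallelic).
    """
    label_map = labels if isinstance(labels, dict) else read_labels(labels)
    path = Path(vcf_or_tsv)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        samples, variants, rows = _read_vcf(path, split_multiallelic)
    else:
        samples, variants, rows = _read_tsv(path)
    missing = [s for s in samples if s not in label_map]
    if missing:
        raise GenotypeError(f"samples absent from label table: {missing}")
    pops = [label_map[s] for s in samples]
    calls = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypeMatrix(variants, samples, pops, calls)


def _read_vcf(path: Path, split_multiallelic: bool):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[list[int]] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1:
            if not split_multiallelic:
                raise GenotypeError(
                    f"multiallelic record {rec.ID or rec.POS} "
                    "(pass split_multiallelic=True to split)"
                )
            alt_list = alts
        else:
            alt_list = alts
        gts = rec.genotypes  # [[a, b, phased], ...]
        for ai, alt in enumerate(alt_list, start=1):
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            if len(alt_list) > 1:
                vid = f"{vid}_{alt}"  # keep split records uniquely keyed
            variants.append(
                Variant(id=vid, gene_pos=rec.POS, ref=rec.REF, alt=alt)
            )
            row = []
            for s, g in zip(samples, gts):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    row.append(-1)
                else:
                    row.append(int(a == ai) + int(b == ai))
            rows.append(row)
    return samples, variants, rows


def _read_tsv(path: Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["rsid", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise GenotypeError(f"TSV genotype table must start with columns {fixed}")
    samples = list(df.columns[4:])
    variants = [
        Variant(id=r.rsid, gene_pos=int(r.pos), ref=r.ref, alt=r.alt)
        for r in df.itertuples()
    ]
    rows = [
        [_parse_gt(df.iloc[i][s], f"{path}:{r.rsid}:{s}") for s in samples]
        for i, r in enumerate(df.itertuples())
    ]
    return samples, variants, rows


def write_vcf(gm: GenotypeMatrix, path: str | Path, phased: dict | None = None) -> None:
    """Write a minimal VCF v4.2. ``phased`` maps sample -> (hap1, hap2) allele
    strings over the matrix's variant order; when given, GT uses ``|``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=CYP2D6>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, v in enumerate(gm.variants):
            fields = ["CYP2D6", str(v.gene_pos), v.id, v.ref, v.alt, ".", "PASS", ".", "GT"]
            for i, s in enumerate(gm.samples):
                c = gm.calls[i, j]
                if phased is not None and s in phased:
                    h1, h2 = phased[s]
                    fields.append(f"{h1[j]}|{h2[j]}")
                elif c < 0:
                    fields.append("./.")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(c)])
            fh.write("\t".join(fields) + "\n")


def write_labels(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in zip(gm.samples, gm.pops):
            fh.write(f"{s}\t{p}\n")


# -- counting ------------------------------------------------------------

@dataclass
class GenotypeCounts:
    """Per-population genotype counts as a tidy DataFrame.

    ``table`` is indexed by (population, rsid) with columns ``n_hom_ref``,
    ``n_het``, ``n_hom_alt``, ``n_called``, ``alt_count``, ``alt_freq``,
    ``minor_allele``, ``minor_count``, ``maf``.  The pseudo-population
    :data:`COMBINED` holds the pooled sample.  The minor allele is defined
    from the pooled counts so per-population minor counts refer to the same
    allele everywhere.
    """

    table: pd.DataFrame
    variants: list[Variant]

    @property
    def populations(self) -> list[str]:
        return [p for p in self.table.index.get_level_values(0).unique() if p != COMBINED]

    def pop(self, population: str) -> pd.DataFrame:
        return self.table.loc[population]

    def to_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)


def _count_block(calls: np.ndarray) -> np.ndarray:
    """Counts (hom_ref, het, hom_alt) per variant column."""
    return np.stack(
        [(calls == 0).sum(0), (calls == 1).sum(0), (calls == 2).sum(0)], axis=1
    )


def count_genotypes(gm: GenotypeMatrix, by_pop: bool = True) -> GenotypeCounts:
    """Genotype and allele counts per population plus the pooled sample.

    Missing genotypes are excluded throughout (the denominator is the number
    of called samples, so per-variant totals may fall short of the sample
    size).
    """
    pops = gm.populations if by_pop else []
    blocks: dict[str, np.ndarray] = {}
    for p in pops:
        sub = gm.calls[[i for i, q in enumerate(gm.pops) if q == p]]
        blocks[p] = _count_block(sub)
    blocks[COMBINED] = _count_block(gm.calls)

    # minor allele orientation from pooled counts
    pooled = blocks[COMBINED]
    pooled_alt = pooled[:, 1] + 2 * pooled[:, 2]
    pooled_ref = pooled[:, 1] + 2 * pooled[:, 0]
    minor_is_alt = pooled_alt <= pooled_ref

    records = []
    for p, blk in blocks.items():
        n_called = blk.sum(1)
        alt_count = blk[:, 1] + 2 * blk[:, 2]
        ref_count = blk[:, 1] + 2 * blk[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            alt_freq = np.where(n_called > 0, alt_count / (2 * n_called), np.nan)
        for j, v in enumerate(gm.variants):
            minor = v.alt if minor_is_alt[j] else v.ref
            mcount = alt_count[j] if minor_is_alt[j] else ref_count[j]
            maf = mcount / (2 * n_called[j]) if n_called[j] else np.nan
            records.append(
                dict(
                    population=p,
                    rsid=v.id,
                    n_hom_ref=int(blk[j, 0]),
                    n_het=int(blk[j, 1]),
                    n_hom_alt=int(blk[j, 2]),
                    n_called=int(n_called[j]),
                    alt_count=int(alt_count[j]),
                    alt_freq=float(alt_freq[j]),
                    minor_allele=minor,
                    minor_count=int(mcount),
                    maf=float(maf),
                )
            )
    table = pd.DataFrame.from_records(records).set_index(["population", "rsid"])
    return GenotypeCounts(table=table, variants=list(gm.variants))


# -- phasing-locus selection ---------------------------------------------

def select_phasing_loci(
    counts: GenotypeCounts, min_private_count: int = 3
) -> dict[str, list[str]]:
    """Partition variants into phasing-eligible and excluded sets.

    A variant is ``excluded_low_het`` when its minor allele is absent from all
    but one population and occurs fewer than ``min_private_count`` times (the
    study's "frequency of two or less") in that one.  Indels that survive the
    low-heterozygosity screen are ``excluded_indel`` (unphasable).  The
    low-heterozygosity rule is applied first: a rare private indel counts as a
    low-heterozygosity exclusion, matching how the study itself classified its
    excluded loci.
    """
    pops = counts.populations
    if len(pops) < 2:
        raise ValueError("low-heterozygosity rule needs >= 2 populations")
    retained: list[str] = []
    low_het: list[str] = []
    indel: list[str] = []
    for v in counts.variants:
        mc = np.array([counts.table.loc[(p, v.id), "minor_count"] for p in pops])
        n_present = int((mc > 0).sum())
        if n_present <= 1 and mc.max(initial=0) < min_private_count:
            low_het.append(v.id)
        elif v.is_indel:
            indel.append(v.id)
        else:
            retained.append(v.id)
    return {
        "retained": retained,
        "excluded_low_het": low_het,
        "excluded_indel": indel,
    }


# -- bundled study table --------------------------------------------------

def _data_path(name: str):
    return resources.files("cyp2d6pop.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The bundled per-population genotype-count transcription of the study's
    43 CYP2D6 polymorphisms (counts, alleles, and printed HWE p-values)."""
    with resources.as_file(_data_path("table1_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"rsid": str}, na_values=["."])


POPULATIONS = ("balkan", "medjimurje", "baranja")


def table1_matrix_counts(df: pd.DataFrame | None = None) -> GenotypeCounts:
    """Build a :class:`GenotypeCounts` directly from the bundled count table
    (no per-sample data needed)."""
    if df is None:
        df = load_table1()
    variants = [
        Variant(
            id=r.rsid,
            gene_pos=int(re.match(r"(\d+)", r.label).group(1)),
            ref=r.ref,
            alt=r.alt,
            annotation=r.annotation,
        )
        for r in df.itertuples()
    ]
    records = []
    blocks: dict[str, list[tuple[int, int, int]]] = {p: [] for p in POPULATIONS}
    for r in df.itertuples():
        for p in POPULATIONS:
            blocks[p].append(
                (
                    getattr(r, f"{p}_hom_ref"),
                    getattr(r, f"{p}_het"),
                    getattr(r, f"{p}_hom_alt"),
                )
            )
    combined = [
        tuple(sum(blocks[p][j][i] for p in POPULATIONS) for i in range(3))
        for j in range(len(variants))
    ]
    all_blocks: dict[str, list] = {**blocks, COMBINED: combined}
    pooled_alt = np.array([b[1] + 2 * b[2] for b in combined])
    pooled_ref = np.array([b[1] + 2 * b[0] for b in combined])
    minor_is_alt = pooled_alt <= pooled_ref
    for p, blk in all_blocks.items():
        for j, v in enumerate(variants):
            hr, het, ha = blk[j]
            n_called = hr + het + ha
            alt_count = het + 2 * ha
            ref_count = het + 2 * hr
            minor = v.alt if minor_is_alt[j] else v.ref
            mcount = alt_count if minor_is_alt[j] else ref_count
            records.append(
                dict(
                    population=p,
                    rsid=v.id,
                    n_hom_ref=hr,
                    n_het=het,
                    n_hom_alt=ha,
                    n_called=n_called,
                    alt_count=alt_count,
                    alt_freq=alt_count / (2 * n_called) if n_called else np.nan,
                    minor_allele=minor,
                    minor_count=mcount,
                    maf=mcount / (2 * n_called) if n_called else np.nan,
                )
            )
    table = pd.DataFrame.from_records(records).set_index(["population", "rsid"])
    return GenotypeCounts(table=table, variants=variants)
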