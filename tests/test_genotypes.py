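import numpy as np
import pytest

from cyp2d6pop.genotypes import (
    GenotypeError,
    GenotypeMatrix,
    Variant,
    count_genotypes,
    read_genotypes,
    select_phasing_loci,
    write_labels,
    write_vcf,
)
from cyp2d6pop.synthetic import default_spec, simulate

TOY_VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=CYP2D6>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
CYP2D6\t100\trsA\tG\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
CYP2D6\t200\trsB\tA\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def _labels(tmp_path, pairs):
    return _write(
        tmp_path, "labels.tsv",
        "sample\tpopulation\n" + "".join(f"{s}\t{p}\n" for s, p in pairs),
    )


def test_vcf_parse_toy(tmp_path):
    vcf = _write(tmp_path, "toy.vcf", TOY_VCF)
    labels = _labels(tmp_path, [("S1", "a"), ("S2", "a"), ("S3", "b")])
    gm = read_genotypes(vcf, labels)
    assert len(gm.variants) == 2 and len(gm.samples) == 3
    assert gm.calls.tolist() == [[0, 1], [1, -1], [2, 0]]
    assert gm.populations == ["a", "b"]


def test_unlabeled_sample_is_error(tmp_path):
    vcf = _write(tmp_path, "toy.vcf", TOY_VCF)
    labels = _labels(tmp_path, [("S1", "a"), ("S2", "a")])
    with pytest.raises(GenotypeError, match="S3"):
        read_genotypes(vcf, labels)


def test_multiallelic_rejected_unless_split(tmp_path):
    vcf_text = TOY_VCF.replace("rsB\tA\tT", "rsB\tA\tT,G")
    vcf_text = vcf_text.replace("0/1\t./.\t0/0", "0/2\t./.\t0/1")
    vcf = _write(tmp_path, "multi.vcf", vcf_text)
    labels = _labels(tmp_path, [("S1", "a"), ("S2", "a"), ("S3", "b")])
    with pytest.raises(GenotypeError, match="multiallelic"):
        read_genotypes(vcf, labels)
    gm = read_genotypes(vcf, labels, split_multiallelic=True)
    assert len(gm.variants) == 3  # rsB split into T and G records


def test_malformed_genotype_names_record(tmp_path):
    tsv = _write(
        tmp_path, "geno.tsv",
        "rsid\tpos\tref\talt\tS1\nrsA\t100\tG\tC\tbogus\n",
    )
    labels = _labels(tmp_path, [("S1", "a")])
    with pytest.raises(GenotypeError, match="rsA"):
        read_genotypes(tsv, labels)


def test_synthetic_vcf_round_trip(tmp_path):
    gm, _ = simulate(default_spec(seed=3))
    write_vcf(gm, tmp_path / "c.vcf")
    write_labels(gm, tmp_path / "c.labels.tsv")
    back = read_genotypes(tmp_path / "c.vcf", tmp_path / "c.labels.tsv")
    assert back.samples == gm.samples
    assert back.variant_ids == gm.variant_ids
    assert np.array_equal(back.calls, gm.calls)
    assert back.pops == gm.pops


def test_variant_invariants():
    with pytest.raises(GenotypeError):
        Variant(id="x", gene_pos=1, ref="A", alt="A")
    assert Variant(id="x", gene_pos=1, ref="A", alt="AT").kind == "indel"
    assert Variant(id="x", gene_pos=1, ref="A", alt="T").kind == "snv"


# -- counting ------------------------------------------------------------

def test_table1_allele_counts(table1_counts):
    """Re-derived allele counts reproduce the printed study values."""
    t = table1_counts.table
    c = t.loc[("balkan", "rs1135840")]
    assert c.alt_count == 141  # C allele
    assert round(100 * c.alt_freq, 2) == 71.94
    c = t.loc[("balkan", "rs368389952")]
    assert c.alt_count == 18
    assert round(100 * c.maf, 2) == 9.18
    # combined equals the sum over populations everywhere
    pops = table1_counts.populations
    for rsid in [v.id for v in table1_counts.variants]:
        total = sum(t.loc[(p, rsid), "n_called"] for p in pops)
        assert t.loc[("combined", rsid), "n_called"] == total


def test_maf_bounded(table1_counts):
    maf = table1_counts.table["maf"].dropna()
    assert ((maf >= 0) & (maf <= 0.5)).all()


def _toy_matrix(calls, pops):
    calls = np.asarray(calls)
    variants = [Variant(id=f"rs{j}", gene_pos=j, ref="A", alt="G")
                for j in range(calls.shape[1])]
    samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(variants, samples, pops, calls)


def test_monomorphic_locus_counts():
    gm = _toy_matrix([[0], [0], [0]], ["a", "a", "b"])
    c = count_genotypes(gm).table.loc[("combined", "rs0")]
    assert c.maf == 0 and c.n_het == 0


# -- phasing-locus selection ---------------------------------------------

def test_low_het_rule_on_study_table(table1_counts):
    parts = select_phasing_loci(table1_counts)
    assert len(parts["retained"]) == 28
    assert set(parts["excluded_low_het"]) == {
        "rs28371732", "rs867985262", "rs79596243", "rs28578778",
        "rs141009491", "rs762158210", "rs35742686", "rs28371717",
        "rs1349481801", "rs376056664", "rs189736703", "rs28371703",
        "rs1080992", "rs769811346",
    }
    assert parts["excluded_indel"] == ["rs1269631565"]
    # partition is exhaustive and disjoint
    everything = sum(parts.values(), [])
    assert sorted(everything) == sorted(v.id for v in table1_counts.variants)
    assert len(set(everything)) == len(everything)


@pytest.mark.parametrize(
    "per_pop_calls, expected",
    [
        # minor allele private to one group with 6 copies -> retained
        (([1] * 6 + [0] * 4, [0] * 10, [0] * 10), "retained"),
        # private with 2 copies -> excluded (frequency of two or less)
        (([1, 1] + [0] * 8, [0] * 10, [0] * 10), "excluded_low_het"),
        # one copy in each of two groups -> retained (present in two groups)
        (([1] + [0] * 9, [1] + [0] * 9, [0] * 10), "retained"),
    ],
)
def test_low_het_rule_edges(per_pop_calls, expected):
    rows, pops = [], []
    for p, block in zip("abc", per_pop_calls):
        for v in block:
            rows.append([v])
            pops.append(p)
    gm = _toy_matrix(rows, pops)
    parts = select_phasing_loci(count_genotypes(gm))
    assert "rs0" in parts[expected]


def test_single_population_is_error():
    gm = _toy_matrix([[0], [1]], ["a", "a"])
    with pytest.raises(ValueError):
        select_phasing_loci(count_genotypes(gm))
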