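"""End-to-end orchestration: filter -> phase -> star -> phenotype ->
population statistics -> networks, with TSV/GraphML/JSON export."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import (
    COMBINED,
    GenotypeMatrix,
    count_genotypes,
    read_genotypes,
    select_phasing_loci,
)
from .mjnet import build_mj_network, export_dot
from .phasing import em_phase
from .popgen import diversity, ewens_watterson, exact_differentiation, pairwise_fst
from .popstats import bonferroni, contingency_test, hwe_test
from .star import NDT, call_phenotype, call_star, load_definitions
from .synthetic import default_spec, simulate

log = logging.getLogger("cyp2d6pop")

__all__ = ["RunConfig", "PipelineError", "run_all", "compare_external",
           "weighted_mean", "top_star_table"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-serializable)."""

    outdir: str = "results"
    vcf: str | None = None  # None -> simulate the default synthetic cohort
    labels: str | None = None
    seed: int = 0
    min_private_count: int = 3
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_restarts: int = 3
    n_perm: int = 100_000  # F_ST permutations
    n_null: int = 10_000  # Ewens-Watterson null samples
    n_mc: int = 10_000  # exact-differentiation tables
    alpha: float = 0.05
    epsilon: float = 0.0  # median-joining tolerance
    fst_distance: str = "hamming"
    definitions: str | None = None  # star-allele table; None -> bundled

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s", name)
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(name, e) from e
        return wrapper
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    if cfg.vcf is None:
        spec = default_spec(seed=cfg.seed)
        gm, truth = simulate(spec)
        return gm, truth
    if cfg.labels is None:
        raise ValueError("labels file required with a VCF input")
    return read_genotypes(cfg.vcf, cfg.labels), None


@_stage("counts")
def _counts_table(gm: GenotypeMatrix, cfg: RunConfig, outdir: Path):
    counts = count_genotypes(gm)
    pops = counts.populations
    rows = []
    hwe_ps = []
    for v in counts.variants:
        rec = {"rsid": v.id, "ref": v.ref, "alt": v.alt}
        for p in pops + [COMBINED]:
            c = counts.table.loc[(p, v.id)]
            rec[f"{p}_genotypes"] = f"{c.n_hom_ref}/{c.n_het}/{c.n_hom_alt}"
            rec[f"{p}_maf"] = round(c.maf, 4)
            res = hwe_test(c.n_hom_ref, c.n_het, c.n_hom_alt)
            rec[f"hwe_{p}"] = round(res.p_value, 6) if res.testable else ""
            if res.testable:
                hwe_ps.append(res.p_value)
        # allele-level group comparison (2 x P table of allele counts)
        tab = np.array(
            [
                [
                    counts.table.loc[(p, v.id), "alt_count"],
                    2 * counts.table.loc[(p, v.id), "n_called"]
                    - counts.table.loc[(p, v.id), "alt_count"],
                ]
                for p in pops
            ]
        )
        if (tab.sum(axis=0) > 0).all():
            res = contingency_test(tab)
            rec["allele_chi2"] = round(res.chi2, 5)
            rec["allele_p"] = res.p_value
        rows.append(rec)
    df = pd.DataFrame(rows)
    _, hwe_thresh = bonferroni(hwe_ps, alpha=cfg.alpha)
    _, chi_thresh = bonferroni(
        df["allele_p"].dropna(), alpha=cfg.alpha, m=len(counts.variants)
    )
    df.to_csv(outdir / "table1_counts_hwe.tsv", sep="\t", index=False)
    return counts, {"hwe_bonferroni": hwe_thresh, "chi2_bonferroni": chi_thresh}


@_stage("filter")
def _filter(gm, counts, cfg: RunConfig, outdir: Path):
    parts = select_phasing_loci(counts, min_private_count=cfg.min_private_count)
    with open(outdir / "locus_partition.json", "w") as fh:
        json.dump(parts, fh, indent=1)
    return gm.subset_variants(parts["retained"]), parts


@_stage("phase")
def _phase(gm, cfg: RunConfig, outdir: Path, seed: int):
    res = em_phase(
        gm,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        n_restarts=cfg.em_restarts,
        seed=seed,
    )
    res.phases.to_csv(outdir / "phases.tsv", sep="\t", index=False)
    rows = [
        dict(population=p, haplotype=h, frequency=f)
        for p, hfs in res.freq_sets.items()
        for h, f in hfs.freqs.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "haplotype_frequencies.tsv", sep="\t",
                              index=False)
    return res


@_stage("star")
def _stars(phasing, gm, cfg: RunConfig, outdir: Path):
    defs = load_definitions(cfg.definitions, typed_loci=gm.variant_ids)
    loci = gm.variant_ids
    hap_star = {h: call_star(h, defs, loci) for h in phasing.haplotypes}
    calls = phasing.phases.copy()
    calls["star1"] = calls["hap1"].map(lambda h: hap_star[h].star)
    calls["star2"] = calls["hap2"].map(lambda h: hap_star[h].star)
    calls.to_csv(outdir / "star_calls.tsv", sep="\t", index=False)

    copies = pd.concat(
        [
            calls[["population", "star1"]].rename(columns={"star1": "star"}),
            calls[["population", "star2"]].rename(columns={"star2": "star"}),
        ]
    )
    star_counts = (
        copies.groupby(["population", "star"]).size().unstack(fill_value=0).T
    )
    star_counts["total"] = star_counts.sum(axis=1)
    star_counts.to_csv(outdir / "star_frequencies.tsv", sep="\t")
    n_raw = len(phasing.haplotypes)
    n_translated = sum(1 for c in hap_star.values() if c.star != NDT)
    return defs, calls, star_counts, {"haplotypes_raw": n_raw,
                                      "haplotypes_translated": n_translated}


def top_star_table(star_counts: pd.DataFrame, n_top: int = 5) -> pd.DataFrame:
    """Population x star count table restricted to the overall ``n_top`` most
    prevalent star alleles (the study's five-allele comparison)."""
    counts = star_counts.drop(columns=["total"], errors="ignore")
    counts = counts.loc[[s for s in counts.index if s != NDT]]
    top = counts.sum(axis=1).sort_values(ascending=False).head(n_top).index
    return counts.loc[top].T  # rows = populations


@_stage("star_stats")
def _star_stats(star_counts, cfg: RunConfig, outdir: Path):
    top = top_star_table(star_counts)
    rows = []
    res = contingency_test(top.to_numpy())
    rows.append(dict(comparison="all_groups_top5", chi2=res.chi2, p=res.p_value))
    pops = list(top.index)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            r = contingency_test(top.loc[[a, b]].to_numpy())
            rows.append(dict(comparison=f"{a}_vs_{b}_top5", chi2=r.chi2, p=r.p_value))
    for star in top.columns:  # one allele vs the other four merged
        tab = np.stack([top[star], top.drop(columns=star).sum(axis=1)], axis=1)
        r = contingency_test(tab)
        rows.append(dict(comparison=f"{star}_vs_rest", chi2=r.chi2, p=r.p_value))
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "star_group_tests.tsv", sep="\t", index=False)
    return df


@_stage("phenotype")
def _phenotypes(calls, defs, outdir: Path):
    recs = []
    for r in calls.itertuples():
        ph = call_phenotype(r.star1, r.star2, defs, sample=r.sample)
        recs.append(dict(sample=r.sample, population=r.population,
                         diplotype=f"{ph.star1}/{ph.star2}",
                         activity_score=ph.activity_score,
                         phenotype=ph.category))
    df = pd.DataFrame(recs)
    df.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    tally = (
        df.dropna(subset=["phenotype"])
        .groupby(["population", "phenotype"])
        .size()
        .unstack(fill_value=0)
    )
    tally.to_csv(outdir / "phenotype_tally.tsv", sep="\t")
    return df, tally


@_stage("popgen")
def _popgen(phasing, cfg: RunConfig, outdir: Path, seed_seq):
    pops = [p for p in phasing.freq_sets if p != COMBINED]
    div_rows = []
    for p in pops:
        d = diversity(phasing.freq_sets[p])
        ew = ewens_watterson(
            phasing.freq_sets[p], n_null=cfg.n_null,
            seed=int(seed_seq.spawn(1)[0].generate_state(1)[0] % 2**31),
        )
        div_rows.append(dict(population=p, n=d.n, k=d.k,
                             haplotype_diversity=round(d.H, 4),
                             nucleotide_diversity=round(d.pi, 4),
                             polymorphic_sites=d.L,
                             observed_F=round(ew.observed_F, 4),
                             expected_F=round(ew.expected_F, 4),
                             ew_p=round(ew.p_value, 4)))
    pd.DataFrame(div_rows).to_csv(outdir / "diversity_ew.tsv", sep="\t",
                                  index=False)

    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    fst_p = pd.DataFrame(1.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            r = pairwise_fst(
                phasing.freq_sets[a], phasing.freq_sets[b],
                n_perm=cfg.n_perm, distance=cfg.fst_distance,
                seed=int(seed_seq.spawn(1)[0].generate_state(1)[0] % 2**31),
            )
            fst.loc[a, b] = fst.loc[b, a] = r.fst
            fst_p.loc[a, b] = fst_p.loc[b, a] = r.p_value
    fst.to_csv(outdir / "fst_matrix.tsv", sep="\t")
    fst_p.to_csv(outdir / "fst_pvalues.tsv", sep="\t")

    hap_table = pd.DataFrame(
        {p: (phasing.freq_sets[p].freqs * phasing.freq_sets[p].n_genes).round()
         for p in pops}
    ).fillna(0).astype(int)
    p_exact = exact_differentiation(
        hap_table, n_mc=cfg.n_mc,
        seed=int(seed_seq.spawn(1)[0].generate_state(1)[0] % 2**31),
    )
    return {"exact_differentiation_p": p_exact}


@_stage("network")
def _networks(phasing, calls, cfg: RunConfig, outdir: Path):
    star_of = {}
    for r in calls.itertuples():
        star_of[r.hap1] = r.star1
        star_of[r.hap2] = r.star2
    paths = []
    for p, hfs in phasing.freq_sets.items():
        if p == COMBINED or len(hfs.freqs) < 2:
            continue
        meta = {h: {"star": star_of.get(h, NDT), "population": p}
                for h in hfs.freqs.index}
        g = build_mj_network(list(hfs.freqs.index), frequencies=hfs.freqs,
                             epsilon=cfg.epsilon, metadata=meta)
        gml = outdir / f"network_{p}.graphml"
        nx.write_graphml(g, gml)
        export_dot(g, outdir / f"network_{p}.dot")
        paths.append(str(gml))
    return paths


def run_all(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(cfg.seed)
    gm, truth = _load(cfg)
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    counts, thresholds = _counts_table(gm, cfg, outdir)
    gm_phase, parts = _filter(gm, counts, cfg, outdir)
    phasing = _phase(
        gm_phase, cfg, outdir,
        seed=int(seed_seq.spawn(1)[0].generate_state(1)[0] % 2**31),
    )
    defs, calls, star_counts, hap_info = _stars(phasing, gm_phase, cfg, outdir)
    star_tests = _star_stats(star_counts, cfg, outdir)
    _, tally = _phenotypes(calls, defs, outdir)
    popgen_info = _popgen(phasing, cfg, outdir, seed_seq)
    _networks(phasing, calls, cfg, outdir)

    manifest = {
        "package": "cyp2d6pop",
        "version": __version__,
        "versions": {m.__name__: m.__version__ for m in
                     (np, pd, __import__("scipy"), nx)},
        "seed": cfg.seed,
        "config": asdict(cfg),
        "n_samples": len(gm.samples),
        "populations": gm.populations,
        "locus_partition_sizes": {k: len(v) for k, v in parts.items()},
        "thresholds": thresholds,
        **hap_info,
        **popgen_info,
        "phenotype_tally": tally.to_dict(),
        "star_tests": star_tests.to_dict("records"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("pipeline complete: %s", outdir)
    return manifest


# -- external-frequency comparison ---------------------------------------

def compare_external(maf: pd.DataFrame, external: pd.DataFrame,
                     on: str = "rsid") -> pd.DataFrame:
    """Join per-SNP study MAFs with an external (gnomAD-style) frequency
    table and categorize the external frequencies as ``monomorphic``
    (MAF = 0), ``<1%`` or ``polymorphic`` per population column.

    Missing rsIDs are reported in the ``missing_external`` column attribute,
    not fatal.
    """
    merged = maf.merge(external, on=on, how="left", suffixes=("", "_ext"))
    ext_cols = [c for c in external.columns if c != on]
    for c in ext_cols:
        vals = merged[c]
        merged[f"{c}_category"] = np.select(
            [vals.isna(), vals == 0, vals < 0.01],
            ["missing", "monomorphic", "<1%"],
            default="polymorphic",
        )
    merged.attrs["missing_external"] = merged.loc[
        merged[ext_cols[0]].isna(), on
    ].tolist() if ext_cols else []
    return merged


def weighted_mean(df: pd.DataFrame, value: str, weight: str,
                  by: str | list[str]) -> pd.Series:
    """Sample-size-weighted mean of ``value`` within groups ``by`` (used to
    average star-allele frequencies across studies per ethnic group)."""
    def agg(g):
        w = g[weight].astype(float)
        return float((g[value] * w).sum() / w.sum())
    return df.groupby(by).apply(agg, include_groups=False)
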