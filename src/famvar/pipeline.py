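"""End-to-end orchestration: QC -> annotate -> linkage filter -> family
prioritization -> segregation -> gene drop -> replication -> correction ->
burden, composing over TSV artifacts in a run directory."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
import numpy as np
import pandas as pd

from . import annotate as ann
from . import familyprior as fp
from . import genedrop as gd
from . import io as fio
from . import linkage as lk
from . import qc as qcmod
from . import replication as rep
from .model import Cohort, VariantRecord

log = logging.getLogger("famvar")

__all__ = ["RunConfig", "load_corpus", "run_pipeline"]


@dataclass
class RunConfig:
    indir: Path
    outdir: Path
    seed: int = 0
    genedrop_sims: int = 10_000
    lod_threshold: float = 1.5
    lfam_min_affected: int = 4
    sharing_fraction: float = 0.75
    linkage_af_max: float = 0.05
    rare_af_max: float = 0.005
    include_ibdu_in_cd: bool = False
    thresholds: qcmod.QCThresholds = dc_field(default_factory=qcmod.QCThresholds)
    run_burden: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = qcmod.QCThresholds(**raw.pop("thresholds", {}))
        raw["indir"] = Path(raw["indir"])
        raw["outdir"] = Path(raw["outdir"])
        return cls(thresholds=thr, **raw)


def load_corpus(indir: str | Path) -> dict:
    indir = Path(indir)
    corpus = {
        "cohort": fio.read_pedigree(indir / "cohort.ped"),
        "records": fio.read_vcf(indir / "variants.vcf"),
        "annotations": fio.read_annotations(indir / "annotations.tsv"),
        "lod_curve": pd.read_csv(indir / "lod_curve.tsv", sep="\t",
                                 dtype={"chrom": str}),
        "lod_table": fio.read_lod_table(indir / "lod_families.tsv"),
        "genes": fio.read_gene_intervals(indir / "genes.tsv"),
        "replication": fio.read_replication_table(indir / "replication.tsv"),
    }
    return corpus


def stage_qc(records: list[VariantRecord],
             thresholds: qcmod.QCThresholds) -> tuple[list[VariantRecord], pd.DataFrame]:
    kept = []
    rows = []
    for rec in records:
        qcmod.apply_genotype_qc(rec, thresholds)
        ok, reasons = qcmod.variant_qc(rec, thresholds)
        rows.append({"key": rec.key, "pass": ok, "reasons": ";".join(reasons)})
        if ok:
            kept.append(rec)
    return kept, pd.DataFrame(rows, columns=["key", "pass", "reasons"])


def stage_annotate(records: list[VariantRecord],
                   annotations: pd.DataFrame) -> list[VariantRecord]:
    fio.attach_annotations(records, annotations)
    return [ann.orient_to_minor_allele(r) for r in records]


def stage_linkage(records: list[VariantRecord], corpus: dict, cohort: Cohort,
                  config: RunConfig, scope: str = "CD") -> tuple[pd.DataFrame, list[lk.Locus]]:
    curve = corpus["lod_curve"]
    loci = lk.select_loci(curve["chrom"], curve["bp"], curve["lod"],
                          threshold=config.lod_threshold)
    shared = lk.linkage_shared_variants(
        records, loci, cohort, corpus["lod_table"], corpus["genes"], scope=scope,
        af_max=config.linkage_af_max,
        include_ibdu_in_cd=config.include_ibdu_in_cd,
    )
    return shared, loci


def stage_famprior(records: list[VariantRecord], cohort: Cohort,
                   config: RunConfig, scope: str) -> pd.DataFrame:
    lfams = fp.select_lfams(cohort, scope, config.lfam_min_affected,
                            config.include_ibdu_in_cd)
    return fp.prioritize_rare_family_variants(
        records, lfams, scope, af_max=config.rare_af_max,
        min_fraction=config.sharing_fraction,
        include_ibdu_in_cd=config.include_ibdu_in_cd,
    )


def stage_genedrop(prioritized: pd.DataFrame, records: dict[str, VariantRecord],
                   cohort: Cohort, config: RunConfig, scope: str) -> pd.DataFrame:
    rows = []
    for r in prioritized.itertuples():
        rec = records[r.key]
        index_family = r.families.split(";")[0].split(":")[0]
        gcfg = gd.GeneDropConfig(
            n_sims=config.genedrop_sims, seed=config.seed,
            exclude_family=index_family, scope=scope,
            include_ibdu_in_cd=config.include_ibdu_in_cd,
        )
        founder_af = ann.control_af(rec, "genedrop")
        result = gd.simulate_cohort_af(cohort, founder_af, gcfg)
        observed = gd.observed_cohort_af(cohort, rec, gcfg)
        p = gd.genedrop_pvalue(observed, result)
        rows.append({"key": r.key, "scope": scope, "index_family": index_family,
                     "founder_af": founder_af, "observed_af": observed,
                     "genedrop_p": p})
    return pd.DataFrame(rows, columns=["key", "scope", "index_family",
                                       "founder_af", "observed_af", "genedrop_p"])


def stage_segregation(prioritized: pd.DataFrame, records: dict[str, VariantRecord],
                      cohort: Cohort, config: RunConfig, scope: str) -> pd.DataFrame:
    rows = []
    for r in prioritized.itertuples():
        rec = records[r.key]
        for entry in r.families.split(";"):
            fid = entry.split(":")[0]
            fam = cohort.families[fid]
            res = fp.segregation_filter(rec, fam, scope,
                                        include_ibdu_in_cd=config.include_ibdu_in_cd)
            if res is None:
                continue
            rows.append({
                "key": r.key, "family_id": fid, "scope": scope,
                "unaffected_carriers": res.n_unaffected_carriers,
                "unaffected": res.n_unaffected,
                "passes_third": res.passes_third,
            })
    return pd.DataFrame(rows, columns=["key", "family_id", "scope",
                                       "unaffected_carriers", "unaffected",
                                       "passes_third"])


def stage_replication(keys: list[str], replication: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for key in keys:
        sub = replication[replication["key"] == key]
        results = []
        for r in sub.itertuples():
            p, odds, flag = rep.fisher_allele_test(r.case_alt, r.case_ref,
                                                   r.ctrl_alt, r.ctrl_ref)
            results.append(rep.ReplicationResult(
                key=key, phenotype=r.phenotype, p=p, odds_ratio=odds,
                case_af=r.case_alt / (r.case_alt + r.case_ref),
                control_af=r.ctrl_alt / (r.ctrl_alt + r.ctrl_ref),
                or_flag=flag,
            ))
            rows.append({"key": key, "phenotype": r.phenotype, "p": p,
                         "odds_ratio": odds, "min": False})
        if results:
            best = rep.min_phenotype_result(results)
            for row in rows:
                if row["key"] == key and row["phenotype"] == best.phenotype:
                    row["min"] = True
    return pd.DataFrame(rows, columns=["key", "phenotype", "p", "odds_ratio", "min"])


def stage_correct(n_linkage: int, n_rare: int, cc_pvalues: pd.DataFrame,
                  gd_pvalues: pd.DataFrame) -> tuple[rep.TestBudget, float]:
    """Derive the effective dataset counts and the Bonferroni threshold.

    Falls back to counting the datasets as fully independent when too few
    shared variants exist to estimate correlations.
    """
    def eff(df: pd.DataFrame, default: int) -> int:
        if df.shape[1] < 2 or df.dropna().shape[0] < 3:
            return default
        return rep.effective_dataset_count(df)

    eff_cc = eff(cc_pvalues, max(cc_pvalues.shape[1], 1))
    eff_gd = eff(gd_pvalues, max(gd_pvalues.shape[1], 1))
    budget = rep.TestBudget(n_linkage, n_rare, eff_cc, eff_gd)
    if budget.total_tests < 1:
        return budget, 0.05
    return budget, rep.bonferroni_threshold(budget)


def stage_burden(records: list[VariantRecord], cohort: Cohort,
                 config: RunConfig) -> pd.DataFrame:
    """Per-gene CMC burden over unrelated cases (sporadics) vs controls."""
    cases = [m.id for m in cohort.sporadic_cases if m.sequenced]
    controls = [m.id for m in cohort.controls if m.sequenced]
    if len(cases) < 5 or len(controls) < 5:
        return pd.DataFrame(columns=["gene", "llr", "p", "flag"])
    ids = cases + controls
    labels = np.array([1] * len(cases) + [0] * len(controls))
    damaging = [
        r for r in records
        if r.gene and ann.is_damaging(r.consequence, r.carol, r.cadd)
        and ann.control_af(r, "filtering") < 0.05
    ]
    if not damaging:
        return pd.DataFrame(columns=["gene", "llr", "p", "flag"])
    idx_of = {s: i for i, s in enumerate(damaging[0].samples)}
    take = [idx_of[s] for s in ids if s in idx_of]
    ids = [s for s in ids if s in idx_of]
    labels = labels[: len(ids)]
    matrix = np.stack(
        [np.where(r.dosages[take] < 0, 0, r.dosages[take]) for r in damaging], axis=1
    ).astype(float)
    n_pcs = min(5, matrix.shape[1] - 1)
    pcs = (qcmod.PCAProjector(n_pcs).fit_transform(matrix) if n_pcs >= 1
           else np.zeros((len(ids), 0)))
    rows = []
    genes = sorted({r.gene for r in damaging})
    for gene in genes:
        cols = [i for i, r in enumerate(damaging) if r.gene == gene]
        afs = [ann.control_af(damaging[i], "filtering") for i in cols]
        llr, p, flag = rep.cmc_burden_test(matrix[:, cols], afs, labels, pcs)
        rows.append({"gene": gene, "llr": llr, "p": p, "flag": flag})
    return pd.DataFrame(rows, columns=["gene", "llr", "p", "flag"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute both prioritization strategies end to end.

    Writes per-stage TSV reports plus a ``funnel.json`` of variant counts
    into ``config.outdir``; returns the funnel dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corpus = load_corpus(config.indir)
    cohort: Cohort = corpus["cohort"]
    funnel: dict = {"input_variants": len(corpus["records"])}

    records, qc_table = stage_qc(corpus["records"], config.thresholds)
    fio.write_report(qc_table, outdir / "qc.tsv")
    funnel["qc_passed"] = len(records)

    records = stage_annotate(records, corpus["annotations"])
    by_key = {r.key: r for r in records}

    # strategy 1: linkage loci shared variants
    linkage_df, loci = stage_linkage(records, corpus, cohort, config, scope="CD")
    fio.write_report(linkage_df, outdir / "linkage_shared.tsv")
    funnel["linkage_loci"] = len(loci)
    funnel["linkage_shared_variants"] = int(linkage_df["key"].nunique())

    # strategy 2: family prioritization per scope
    prior = {}
    for scope in ("IBD", "CD"):
        prior[scope] = stage_famprior(records, cohort, config, scope)
        fio.write_report(prior[scope], outdir / f"famprior_{scope}.tsv")
        funnel[f"famprior_{scope}"] = len(prior[scope])

    rare_keys = sorted(set(prior["IBD"]["key"]) | set(prior["CD"]["key"]))
    funnel["famprior_union"] = len(rare_keys)

    # gene dropping + segregation per scope
    gd_pmatrix = {}
    for scope in ("IBD", "CD"):
        gd_df = stage_genedrop(prior[scope], by_key, cohort, config, scope)
        fio.write_report(gd_df, outdir / f"genedrop_{scope}.tsv")
        gd_pmatrix[scope] = gd_df.set_index("key")["genedrop_p"]
        seg_df = stage_segregation(prior[scope], by_key, cohort, config, scope)
        fio.write_report(seg_df, outdir / f"segregation_{scope}.tsv")
        funnel[f"segregation_pass_{scope}"] = (
            int(seg_df["passes_third"].sum()) if len(seg_df) else 0
        )

    # replication on everything prioritized
    all_keys = sorted(set(linkage_df["key"]) | set(rare_keys))
    rep_df = stage_replication(all_keys, corpus["replication"])
    fio.write_report(rep_df, outdir / "replication_results.tsv")

    cc_matrix = rep_df.pivot_table(index="key", columns="phenotype", values="p")
    gd_matrix = pd.DataFrame(gd_pmatrix)
    budget, alpha = stage_correct(
        int(linkage_df["key"].nunique()), len(rare_keys), cc_matrix, gd_matrix
    )
    funnel["total_tests"] = budget.total_tests
    funnel["alpha"] = alpha

    min_p = ({} if rep_df.empty
             else rep_df[rep_df["min"].astype(bool)].set_index("key")["p"].to_dict())
    for key, row in gd_matrix.min(axis=1).items():
        min_p[key] = min(min_p.get(key, 1.0), row)
    n_sig, hits = rep.count_significant(min_p, alpha)
    funnel["significant_variants"] = n_sig
    fio.write_report(
        pd.DataFrame({"key": hits}), outdir / "significant.tsv", columns=["key"]
    )

    if config.run_burden:
        burden_df = stage_burden(records, cohort, config)
        fio.write_report(burden_df, outdir / "burden.tsv")
        funnel["burden_genes"] = len(burden_df)

    with open(outdir / "funnel.json", "w") as fh:
        json.dump(funnel, fh, indent=1, sort_keys=True)
    for stage, count in funnel.items():
        log.info("%s: %s", stage, count)
    return funnel
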