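"""Synthetic study inputs: multiplex pedigrees, genotypes with quality
fields, annotations, LOD tables and case/control replication counts.

Everything is generated from a seeded :class:`numpy.random.Generator`, so a
fixed seed reproduces the corpus byte-for-byte.  Founder genotypes are drawn
Binomial(2, AF) and transmitted by the same Mendelian drop used by the
gene-dropping module; planted variants may instead be seeded into chosen
founders of chosen families to create guaranteed sharing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genedrop import drop_family
from .model import (
    Cohort,
    Family,
    Individual,
    Phenotype,
    Sex,
    variant_key,
)
from .replication import CCCohort, _case_af_from_or

__all__ = [
    "PedigreeSpec",
    "VariantSpec",
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_cohort",
    "simulate_genotypes",
    "assign_phenotypes",
    "simulate_lod_table",
    "simulate_replication",
    "generate_corpus",
]

_SUBTYPES = (Phenotype.CD, Phenotype.UC, Phenotype.IBDU)


@dataclass(frozen=True)
class PedigreeSpec:
    n_generations: int = 3
    sibship_size: int = 3
    n_reproducing: int = 2
    seq_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.n_generations < 2 or self.sibship_size < 1:
            raise ValueError("impossible pedigree spec")


@dataclass
class VariantSpec:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    founder_af: float
    consequence: str = "missense"
    carol: Optional[str] = "damaging"
    cadd: Optional[float] = 25.0
    effect: Optional[str] = None
    af_aj: Optional[float] = None
    af_nfe: Optional[float] = None
    af_paj: Optional[float] = None
    af_aj_wgs: Optional[float] = None
    odds_ratio: float = 1.0
    family_or: Optional[float] = None  # penetrance OR within families; None -> odds_ratio
    target_families: tuple[str, ...] = ()
    min_planted_carriers: int = 2
    vqsr_tranche: float = 90.0

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def effective_family_or(self) -> float:
        return self.odds_ratio if self.family_or is None else self.family_or


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 30
    n_lfams: int = 4
    n_sporadic_cases: int = 40
    n_controls: int = 30
    pedigree: PedigreeSpec = dc_field(default_factory=PedigreeSpec)
    baseline_prevalence: float = 0.1
    familial_sd: float = 1.5
    subtype_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # CD, UC, IBDU
    mean_depth: float = 40.0
    variants: list[VariantSpec] = dc_field(default_factory=list)
    replication_cohorts: tuple[CCCohort, ...] = (
        CCCohort("IBD", 1867, 3616),
        CCCohort("CD", 1286, 3035),
        CCCohort("UC", 544, 3575),
    )


def simulate_pedigree(spec: PedigreeSpec, rng: np.random.Generator,
                      family_id: str = "F1") -> Family:
    """Build a multi-generation pedigree with married-in founder spouses."""
    fam = Family(family_id)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{family_id}_{counter[0]}"

    def add(father: Optional[str], mother: Optional[str], sex: Sex) -> Individual:
        ind = Individual(
            id=new_id(), family_id=family_id, father_id=father, mother_id=mother,
            sex=sex, phenotype=Phenotype.UNKNOWN,
            sequenced=bool(rng.random() < spec.seq_prob),
        )
        fam.add(ind)
        return ind

    pa = add(None, None, Sex.MALE)
    ma = add(None, None, Sex.FEMALE)
    current = [(pa.id, ma.id)]
    for gen in range(1, spec.n_generations):
        next_couples = []
        for father, mother in current:
            kids = [
                add(father, mother, Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
                for _ in range(spec.sibship_size)
            ]
            if gen < spec.n_generations - 1:
                n_rep = min(spec.n_reproducing, len(kids))
                chosen = rng.choice(len(kids), size=n_rep, replace=False)
                for ci in sorted(chosen):
                    kid = kids[ci]
                    spouse = add(None, None,
                                 Sex.FEMALE if kid.sex is Sex.MALE else Sex.MALE)
                    if kid.sex is Sex.MALE:
                        next_couples.append((kid.id, spouse.id))
                    else:
                        next_couples.append((spouse.id, kid.id))
        current = next_couples
    fam.validate()
    return fam


def _singleton(iid: str, phenotype: Phenotype, rng: np.random.Generator,
               sex: Optional[Sex] = None) -> Family:
    fam = Family(iid)
    fam.add(Individual(
        id=iid, family_id=iid,
        sex=sex or (Sex.MALE if rng.random() < 0.5 else Sex.FEMALE),
        phenotype=phenotype, sequenced=True,
    ))
    return fam


def _draw_subtype(rng: np.random.Generator, probs: Sequence[float]) -> Phenotype:
    return _SUBTYPES[rng.choice(3, p=np.asarray(probs) / np.sum(probs))]


def simulate_cohort(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None) -> Cohort:
    """Families plus sporadic cases and controls, phenotypes unassigned for
    family members (set later by :func:`assign_phenotypes`)."""
    rng = rng or np.random.default_rng(config.seed)
    cohort = Cohort()
    for i in range(config.n_families):
        cohort.add_family(simulate_pedigree(config.pedigree, rng, f"F{i + 1}"))
    for i in range(config.n_sporadic_cases):
        sub = _draw_subtype(rng, config.subtype_probs)
        cohort.add_family(_singleton(f"S{i + 1}", sub, rng))
    for i in range(config.n_controls):
        cohort.add_family(_singleton(f"C{i + 1}", Phenotype.UNAFFECTED, rng))
    return cohort


def assign_phenotypes(cohort: Cohort, config: SimulationConfig,
                      dosages: Optional[dict[str, dict[str, int]]] = None,
                      rng: Optional[np.random.Generator] = None) -> Cohort:
    """Assign phenotypes by a logistic liability model with a shared familial
    term; subtypes drawn from the configured proportions.

    ``dosages`` maps variant key -> individual id -> dosage for planted risk
    variants (per-allele log-OR effects from the matching
    :class:`VariantSpec`).  Families named in ``config`` lfam targets are
    topped up so that at least four sequenced members are affected.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if not 0.0 < config.baseline_prevalence < 1.0:
        raise ValueError("prevalence outside (0, 1)")
    beta0 = float(np.log(config.baseline_prevalence / (1 - config.baseline_prevalence)))
    effects = {v.key: float(np.log(v.effective_family_or)) for v in config.variants}
    target_fids = {fid for v in config.variants for fid in v.target_families}

    lfam_ids = {f"F{i + 1}" for i in range(min(config.n_lfams, config.n_families))}
    for fid, fam in cohort.families.items():
        if len(fam) == 1:
            continue  # sporadic case or control: phenotype already set
        # in target families the planted variant explains the clustering
        familial = 0.0 if fid in target_fids else rng.normal(0.0, config.familial_sd)
        liabilities: dict[str, float] = {}
        for m in fam:
            logit = beta0 + familial
            deterministic = False
            if dosages:
                for key, per_ind in dosages.items():
                    eff = effects.get(key, 0.0)
                    d = per_ind.get(m.id, 0)
                    if d > 0 and np.isinf(eff):
                        deterministic = True
                    else:
                        logit += eff * d
            liabilities[m.id] = (np.inf if deterministic
                                 else logit + rng.logistic(0.0, 1.0))
            m.phenotype = (
                (Phenotype.CD if deterministic
                 else _draw_subtype(rng, config.subtype_probs))
                if liabilities[m.id] > 0 else Phenotype.UNAFFECTED
            )
        if fid in lfam_ids:
            # ascertainment forcing: top-up sequenced affecteds to >= 4
            seq = [m for m in fam if m.sequenced]
            affected = [m for m in seq if m.phenotype.is_ibd_affected]
            need = 4 - len(affected)
            if need > 0:
                pool = sorted(
                    (m for m in seq if not m.phenotype.is_ibd_affected),
                    key=lambda m: -liabilities[m.id],
                )
                for m in pool[:need]:
                    m.phenotype = _draw_subtype(rng, config.subtype_probs)
    return cohort


# ---------------------------------------------------------------------------
# genotypes

def _plant_founder_carriers(fam: Family, rng: np.random.Generator,
                            min_carriers: int = 2) -> dict[str, int]:
    """Seed one heterozygous founder and drop; retried until at least
    ``min_carriers`` sequenced members carry (guaranteed sharing)."""
    founders = fam.founders
    best: dict[str, int] = {}
    best_n = -1
    for _ in range(1000):
        dosages = {m.id: 0 for m in fam}
        carrier = founders[int(rng.integers(len(founders)))]
        dosages[carrier.id] = 1
        order = [m for m in fam.topological_order() if not m.is_founder]
        for m in order:
            from_f = int(rng.random() < dosages[m.father_id] / 2.0)
            from_m = int(rng.random() < dosages[m.mother_id] / 2.0)
            dosages[m.id] = from_f + from_m
        n_seq_carriers = sum(
            1 for m in fam if m.sequenced and dosages[m.id] > 0
        )
        if n_seq_carriers >= min_carriers:
            return dosages
        if n_seq_carriers > best_n:
            best, best_n = dosages, n_seq_carriers
    return best


def simulate_dosages(cohort: Cohort, spec: VariantSpec,
                     rng: np.random.Generator) -> dict[str, int]:
    """Per-individual dosages for one variant across the whole cohort."""
    out: dict[str, int] = {}
    for fid, fam in cohort.families.items():
        if fid in spec.target_families:
            out.update(_plant_founder_carriers(fam, rng, spec.min_planted_carriers))
        else:
            out.update(drop_family(fam, spec.founder_af, rng))
    return out


def _quality_fields(dosage: int, mean_depth: float,
                    rng: np.random.Generator) -> tuple[int, int, int]:
    depth = max(int(rng.poisson(mean_depth)), 1)
    frac = {0: 0.01, 1: 0.5, 2: 0.99}[dosage]
    ad_alt = int(rng.binomial(depth, frac))
    gq = int(min(99, max(1, rng.normal(80, 15))))
    return gq, depth - ad_alt, ad_alt


def simulate_genotypes(cohort: Cohort, variants: Sequence[VariantSpec],
                       rng: np.random.Generator,
                       mean_depth: float = 40.0
                       ) -> tuple[list[str], dict[str, dict[str, int]], list[dict]]:
    """Draw dosages and synthesize GQ/AD for every variant.

    Returns (sample order, dosages per variant key, per-sample quality rows
    aligned with the VCF writer).
    """
    samples = [m.id for m in cohort if m.sequenced]
    all_dosages: dict[str, dict[str, int]] = {}
    quality: list[dict] = []
    for spec in variants:
        dosages = simulate_dosages(cohort, spec, rng)
        all_dosages[spec.key] = dosages
        q = {}
        for s in samples:
            q[s] = _quality_fields(dosages.get(s, 0), mean_depth, rng)
        quality.append(q)
    return samples, all_dosages, quality


def write_vcf(path: str | Path, samples: Sequence[str],
              variants: Sequence[VariantSpec],
              dosages: dict[str, dict[str, int]],
              quality: Sequence[dict]) -> None:
    """Write a plain-text VCF v4.2 with GT:GQ:AD and a TRANCHE INFO tag."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    ordered = sorted(range(len(variants)),
                     key=lambda i: (variants[i].chrom, variants[i].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=TRANCHE,Number=1,Type=Float,Description="VQSR truth tranche">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        chroms = []
        for i in ordered:
            if variants[i].chrom not in chroms:
                chroms.append(variants[i].chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in ordered:
            v = variants[i]
            cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                    f"TRANCHE={v.vqsr_tranche:g}", "GT:GQ:AD"]
            for s in samples:
                d = dosages[v.key].get(s, 0)
                gq, ad_ref, ad_alt = quality[i][s]
                cols.append(f"{gt_of[d]}:{gq}:{ad_ref},{ad_alt}")
            fh.write("\t".join(cols) + "\n")


def write_annotations(path: str | Path, variants: Sequence[VariantSpec]) -> None:
    rows = []
    for v in variants:
        rows.append({
            "key": v.key, "gene": v.gene, "consequence": v.consequence,
            "effect_hgvs": v.effect, "carol": v.carol, "cadd": v.cadd,
            "af_aj": v.af_aj, "af_nfe": v.af_nfe, "af_paj": v.af_paj,
            "af_aj_wgs": v.af_aj_wgs,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# LOD tables

def simulate_lod_table(cohort: Cohort, locus_chrom: str, locus_start: int,
                       locus_end: int, sharing_families: Sequence[str],
                       rng: np.random.Generator, peak_lod: float = 2.074,
                       grid_step: int = 1_000_000,
                       chrom_length: int = 90_000_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy LOD outputs: a cohort LOD curve and a per-family mean-LOD table.

    Families in ``sharing_families`` receive strictly positive mean LOD over
    the planted locus; all other families non-positive values, so the
    contributing-family filter recovers exactly the sharing set.  The curve
    peaks at ``peak_lod`` inside the locus and stays below 1.0 elsewhere.
    """
    sharing = set(sharing_families)
    fam_rows = []
    for fid, fam in cohort.families.items():
        if len(fam) == 1:
            continue
        if fid in sharing:
            lod = float(rng.uniform(0.1, 0.8))
        else:
            lod = float(rng.uniform(-0.4, 0.0))
        fam_rows.append({"family_id": fid, "chrom": locus_chrom,
                         "start_bp": locus_start, "end_bp": locus_end,
                         "mean_lod": round(lod, 4)})

    bps = np.arange(grid_step, chrom_length + 1, grid_step)
    center = 0.5 * (locus_start + locus_end)
    half_width = max(0.5 * (locus_end - locus_start), grid_step)
    base = rng.uniform(-0.5, 0.8, size=bps.size)
    bump = peak_lod * np.exp(-0.5 * ((bps - center) / half_width) ** 2)
    curve = np.maximum(base, bump)
    curve_rows = pd.DataFrame({
        "chrom": locus_chrom, "bp": bps, "lod": np.round(curve, 4),
    })
    return curve_rows, pd.DataFrame(fam_rows)


# ---------------------------------------------------------------------------
# replication

def simulate_replication(variants: Sequence[VariantSpec],
                         cohorts: Sequence[CCCohort],
                         rng: np.random.Generator) -> pd.DataFrame:
    """Binomial allele counts per arm at the implied AFs for each phenotype.

    Rows where the alternate allele is seen at most once across cases and
    controls are dropped, mirroring the availability rule of the external
    dataset.
    """
    rows = []
    for v in variants:
        control_af = max(af for af in (v.af_aj, v.af_nfe, v.af_paj, 0.0)
                         if af is not None)
        for cohort in cohorts:
            case_alleles = 2 * cohort.n_cases
            ctrl_alleles = 2 * cohort.n_controls
            if control_af <= 0.0:
                case_alt = ctrl_alt = 0
            else:
                case_af = _case_af_from_or(control_af, v.odds_ratio)
                case_alt = int(rng.binomial(case_alleles, case_af))
                ctrl_alt = int(rng.binomial(ctrl_alleles, control_af))
            if case_alt + ctrl_alt <= 1:
                continue
            rows.append({
                "key": v.key, "phenotype": cohort.phenotype,
                "case_alt": case_alt, "case_ref": case_alleles - case_alt,
                "ctrl_alt": ctrl_alt, "ctrl_ref": ctrl_alleles - ctrl_alt,
            })
    return pd.DataFrame(
        rows, columns=["key", "phenotype", "case_alt", "case_ref",
                       "ctrl_alt", "ctrl_ref"],
    )


# ---------------------------------------------------------------------------
# corpus

def generate_corpus(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write a complete synthetic study corpus.

    Emits ``cohort.ped``, ``variants.vcf``, ``annotations.tsv``,
    ``lod_curve.tsv``, ``lod_families.tsv``, ``genes.tsv``,
    ``replication.tsv`` and ``truth.json``; returns the truth dict.
    """
    from .io import write_pedigree

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    cohort = simulate_cohort(config, rng)

    # draw genotypes for planted variants first so phenotypes can depend on them
    samples, all_dosages, quality = simulate_genotypes(
        cohort, config.variants, rng, config.mean_depth
    )
    planted = {
        v.key: all_dosages[v.key] for v in config.variants
        if v.effective_family_or != 1.0 or v.target_families
    }
    assign_phenotypes(cohort, config, planted, rng)

    write_pedigree(cohort, outdir / "cohort.ped")
    write_vcf(outdir / "variants.vcf", samples, config.variants, all_dosages, quality)
    write_annotations(outdir / "annotations.tsv", config.variants)

    genes = {}
    for v in config.variants:
        g = genes.setdefault(v.gene, {"gene": v.gene, "chrom": v.chrom,
                                      "start": v.pos, "end": v.pos})
        g["start"] = min(g["start"], v.pos - 5000)
        g["end"] = max(g["end"], v.pos + 5000)
    pd.DataFrame(list(genes.values())).to_csv(outdir / "genes.tsv", sep="\t", index=False)

    # linkage toys: plant a locus around the first linkage-target variant
    link_targets = [v for v in config.variants if v.target_families]
    if link_targets:
        v0 = link_targets[0]
        sharing = list(v0.target_families)
        locus = (v0.chrom, max(1, v0.pos - 3_000_000), v0.pos + 3_000_000)
    else:
        sharing = []
        locus = ("16", 48_000_000, 54_000_000)
    curve, fam_lod = simulate_lod_table(cohort, locus[0], locus[1], locus[2],
                                        sharing, rng)
    curve.to_csv(outdir / "lod_curve.tsv", sep="\t", index=False)
    fam_lod.to_csv(outdir / "lod_families.tsv", sep="\t", index=False)

    replication = simulate_replication(config.variants, config.replication_cohorts, rng)
    replication.to_csv(outdir / "replication.tsv", sep="\t", index=False)

    truth = {
        "seed": config.seed,
        "n_families": config.n_families,
        "samples": samples,
        "planted_variants": [
            {"key": v.key, "gene": v.gene, "founder_af": v.founder_af,
             "odds_ratio": v.odds_ratio, "target_families": list(v.target_families)}
            for v in config.variants if v.odds_ratio != 1.0 or v.target_families
        ],
        "linkage_locus": {"chrom": locus[0], "start_bp": locus[1],
                          "end_bp": locus[2], "sharing_families": sharing},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
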