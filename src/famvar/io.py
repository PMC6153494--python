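"""Readers and writers for pedigrees, VCFs, annotation tables, LOD tables
and result reports.

All tabular interchange is plain TSV.  Pedigrees use an extended PED
layout::

    FID IID FATHER MOTHER SEX PHENO [SUBTYPE] [SEQ]

with ``PHENO`` 1=unaffected, 2=affected, 0/-9=unknown; ``SUBTYPE`` one of
``CD``/``UC``/``IBDU`` for affecteds (``.`` otherwise); ``SEQ`` 1/0 for the
exome-sequenced flag (defaults to 1).  Missing parents referenced by id are
materialized as unknown-phenotype founders.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    Cohort,
    Consequence,
    Family,
    GeneticMap,
    Individual,
    LinkageTable,
    PedigreeError,
    Phenotype,
    Sex,
    VariantRecord,
)

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_vcf",
    "read_annotations",
    "attach_annotations",
    "read_genetic_map",
    "read_lod_table",
    "read_gene_intervals",
    "read_replication_table",
    "write_report",
    "read_report",
]

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {
    Phenotype.UNAFFECTED: ("1", "."),
    Phenotype.UNKNOWN: ("0", "."),
    Phenotype.CD: ("2", "CD"),
    Phenotype.UC: ("2", "UC"),
    Phenotype.IBDU: ("2", "IBDU"),
}


def _parse_pheno(code: str, subtype: str) -> Phenotype:
    if code == "1":
        return Phenotype.UNAFFECTED
    if code == "2":
        sub = subtype.upper()
        if sub in ("CD", "UC", "IBDU"):
            return Phenotype(sub)
        return Phenotype.IBDU  # affected, subtype unstated
    return Phenotype.UNKNOWN


def read_pedigree(path: str | Path) -> Cohort:
    """Read an extended PED file into a :class:`Cohort`.

    Referenced-but-absent parents are synthesized as unsequenced
    unknown-phenotype founders.  Raises :class:`PedigreeError` on cycles or
    individuals listing exactly one parent.
    """
    rows: dict[str, list[list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns, got {len(fields)}")
            rows.setdefault(fields[0], []).append(fields)

    cohort = Cohort()
    for fid, members in rows.items():
        fam = Family(fid)
        for fields in members:
            _, iid, father, mother, sex, pheno = fields[:6]
            subtype = fields[6] if len(fields) > 6 else "."
            seq = fields[7] if len(fields) > 7 else "1"
            father_id = None if father in ("0", ".", "") else father
            mother_id = None if mother in ("0", ".", "") else mother
            fam.add(Individual(
                id=iid,
                family_id=fid,
                father_id=father_id,
                mother_id=mother_id,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                phenotype=_parse_pheno(pheno, subtype),
                sequenced=(seq != "0"),
            ))
        # materialize referenced-but-absent parents as founders
        for ind in list(fam):
            if (ind.father_id is None) != (ind.mother_id is None):
                raise PedigreeError(
                    f"individual {ind.id!r} in family {fid!r} lists exactly one parent"
                )
            for pid, psex in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if pid is not None and pid not in fam:
                    fam.add(Individual(
                        id=pid, family_id=fid, sex=psex,
                        phenotype=Phenotype.UNKNOWN, sequenced=False,
                    ))
        fam.validate()
        cohort.add_family(fam)
    cohort.validate()
    return cohort


def write_pedigree(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in cohort.families.values():
            for ind in fam.topological_order():
                pheno, subtype = _PHENO_OUT[ind.phenotype]
                fh.write("\t".join([
                    fam.id, ind.id,
                    ind.father_id or "0", ind.mother_id or "0",
                    _SEX_OUT[ind.sex], pheno, subtype,
                    "1" if ind.sequenced else "0",
                ]) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, tranche_tag: str = "TRANCHE") -> list[VariantRecord]:
    """Read a VCF into per-alternate-allele :class:`VariantRecord` objects.

    Multiallelic sites are split at read time, AD collapsed to
    (ref, this-alt).  Missing GQ/AD FORMAT fields are flagged
    (``gq_missing``/``ad_missing``) with -1 fill, and a warning is issued
    once per file.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    records: list[VariantRecord] = []
    warned: set[str] = set()

    for v in vcf:
        try:
            raw_gq = v.format("GQ")
        except Exception:
            raw_gq = None
        if raw_gq is None:
            gq = np.full(n, -1, dtype=np.int32)
            gq_missing = True
        else:
            gq = np.asarray(raw_gq, dtype=float).reshape(n)
            gq = np.where(np.isfinite(gq), gq, -1).astype(np.int32)
            gq_missing = False
        try:
            raw_ad = v.format("AD")
        except Exception:
            raw_ad = None
        if raw_ad is None or np.ndim(raw_ad) != 2:
            ad = None
            ad_missing = True
        else:
            ad = np.asarray(raw_ad, dtype=float)
            ad = np.where(np.isfinite(ad), ad, -1).astype(np.int32)
            ad_missing = False

        tranche = v.INFO.get(tranche_tag)
        genotypes = v.genotypes  # [[a, b, phased], ...]

        for alt_idx, alt in enumerate(v.ALT, start=1):
            dosages = np.full(n, MISSING, dtype=np.int8)
            for i, gt in enumerate(genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                if len(alleles) == len(gt) - 1 and alleles:
                    dosages[i] = sum(1 for a in alleles if a == alt_idx)
            if ad is None:
                ad_ref = np.full(n, -1, dtype=np.int32)
                ad_alt = np.full(n, -1, dtype=np.int32)
            else:
                ad_ref = ad[:, 0].copy()
                ad_alt = ad[:, alt_idx].copy() if ad.shape[1] > alt_idx else np.full(n, -1, np.int32)
            rec = VariantRecord(
                chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=alt,
                samples=samples, dosages=dosages, gq=gq,
                ad_ref=ad_ref, ad_alt=ad_alt,
                vqsr_tranche=float(tranche) if tranche is not None else None,
            )
            if gq_missing:
                rec.flags.add("gq_missing")
            if ad_missing:
                rec.flags.add("ad_missing")
            for flag in rec.flags - warned:
                warnings.warn(f"{path}: FORMAT field absent ({flag}); genotype QC unevaluable")
                warned.add(flag)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# annotation table

ANNOTATION_COLUMNS = [
    "key", "gene", "consequence", "effect_hgvs", "carol", "cadd",
    "af_aj", "af_nfe", "af_paj", "af_aj_wgs",
]


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "gene": str}, na_values=["."])
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df.set_index("key", drop=False)


def attach_annotations(records: Iterable[VariantRecord], table: pd.DataFrame) -> None:
    """Merge annotation rows onto variant records in place (matched by key)."""

    def _opt(x) -> Optional[float]:
        return None if pd.isna(x) else float(x)

    for rec in records:
        if rec.key not in table.index:
            rec.flags.add("unannotated")
            continue
        row = table.loc[rec.key]
        rec.gene = None if pd.isna(row["gene"]) else str(row["gene"])
        rec.effect = None if pd.isna(row["effect_hgvs"]) else str(row["effect_hgvs"])
        try:
            rec.consequence = Consequence(str(row["consequence"]))
        except ValueError:
            rec.consequence = Consequence.OTHER
        rec.carol = None if pd.isna(row["carol"]) else str(row["carol"])
        rec.cadd = _opt(row["cadd"])
        rec.af_aj = _opt(row["af_aj"])
        rec.af_nfe = _opt(row["af_nfe"])
        rec.af_paj = _opt(row["af_paj"])
        rec.af_aj_wgs = _opt(row["af_aj_wgs"])


# ---------------------------------------------------------------------------
# maps, LOD tables, intervals

def read_genetic_map(path: str | Path) -> GeneticMap:
    """TSV with columns chrom, bp, cM."""
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(
        (str(r.chrom), int(r.bp), float(r.cM)) for r in df.itertuples()
    )


def read_lod_table(path: str | Path) -> LinkageTable:
    """TSV with columns family_id, chrom, start_bp, end_bp, mean_lod."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "chrom": str})
    table = LinkageTable()
    for r in df.itertuples():
        table.add(r.family_id, r.chrom, r.start_bp, r.end_bp, r.mean_lod)
    return table


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    need = {"gene", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"gene interval table missing columns: {sorted(need - set(df.columns))}")
    return df


def read_replication_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns key, phenotype, case_alt, case_ref, ctrl_alt, ctrl_ref."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "phenotype": str})
    need = {"key", "phenotype", "case_alt", "case_ref", "ctrl_alt", "ctrl_ref"}
    if not need <= set(df.columns):
        raise ValueError(f"replication table missing columns: {sorted(need - set(df.columns))}")
    return df


# ---------------------------------------------------------------------------
# reports

def write_report(results: pd.DataFrame | Iterable[dict], path: str | Path,
                 columns: Optional[list[str]] = None) -> None:
    """Write a TSV report; an empty result set yields a header-only file."""
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    if columns is not None:
        if df.empty:
            df = pd.DataFrame(columns=columns)
        else:
            df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])
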