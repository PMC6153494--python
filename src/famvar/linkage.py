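"""Linkage-adjacent computations: genetic-map interpolation, LD pruning,
linkage-map SNP selection, pedigree trimming, locus selection and the
contributing-family shared-variant filter.

Multipoint NPL statistics themselves are consumed as input (LOD curves and
per-family LOD tables); this module implements the selection and filtering
logic applied downstream of them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import control_af, is_damaging
from .model import (
    MISSING,
    Cohort,
    Family,
    GeneticMap,
    Individual,
    LinkageTable,
    Locus,
    VariantRecord,
)

__all__ = [
    "MapSNP",
    "interpolate_cm",
    "ld_prune",
    "build_linkage_map",
    "trim_pedigree",
    "select_loci",
    "contributing_families",
    "linkage_shared_variants",
]


@dataclass(frozen=True)
class MapSNP:
    key: str
    chrom: str
    pos: int
    cm: float
    af: float

    @property
    def maf(self) -> float:
        return min(self.af, 1.0 - self.af)

    @property
    def heterozygosity(self) -> float:
        return 2.0 * self.af * (1.0 - self.af)


def interpolate_cm(bp: int, gmap: GeneticMap, chrom: str) -> float:
    """Linear interpolation of genetic position; flat extrapolation at the ends."""
    bps, cms = gmap.anchors(chrom)
    return float(np.interp(bp, bps, cms))


def ld_prune(dosages: np.ndarray, ids: Sequence[str], window: int = 50,
             step: int = 5, r2_max: float = 0.2) -> list[str]:
    """Greedy windowed LD pruning on a samples x SNPs dosage matrix.

    SNPs must be position-ordered.  Within each window, later SNPs with
    squared correlation above ``r2_max`` to an earlier kept SNP are dropped;
    the window then advances by ``step``.  Monomorphic SNPs (undefined r²)
    are dropped with a warning.
    """
    X = np.asarray(dosages, dtype=float)
    X[X == MISSING] = np.nan
    ids = list(ids)
    n_snps = X.shape[1]
    if n_snps != len(ids):
        raise ValueError("ids and dosage columns differ in length")

    removed = np.zeros(n_snps, dtype=bool)
    with np.errstate(invalid="ignore"):
        variances = np.nanvar(X, axis=0)
    mono = ~(variances > 0)
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs dropped before LD pruning")
        removed |= mono

    def r2(i: int, j: int) -> float:
        mask = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
        if mask.sum() < 2:
            return 0.0
        a, b = X[mask, i], X[mask, j]
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    start = 0
    while start < n_snps:
        idx = [i for i in range(start, min(start + window, n_snps)) if not removed[i]]
        for a_pos, i in enumerate(idx):
            if removed[i]:
                continue
            for j in idx[a_pos + 1:]:
                if not removed[j] and r2(i, j) > r2_max:
                    removed[j] = True
        if start + window >= n_snps:
            break
        start += step
    return [ids[i] for i in range(n_snps) if not removed[i]]


def build_linkage_map(snps: Iterable[MapSNP], window_cm: float = 0.3) -> list[MapSNP]:
    """Retain one SNP per occupied fixed cM window per chromosome.

    Windows are anchored at each chromosome's first SNP position.  Within a
    window the SNP with maximum heterozygosity wins; ties break to the
    lowest MAF, then to the smallest genomic position.
    """
    by_chrom: dict[str, list[MapSNP]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)
    out: list[MapSNP] = []
    for chrom in sorted(by_chrom):
        chrom_snps = sorted(by_chrom[chrom], key=lambda s: (s.cm, s.pos))
        cm0 = chrom_snps[0].cm
        windows: dict[int, MapSNP] = {}
        for snp in chrom_snps:
            w = math.floor((snp.cm - cm0) / window_cm)
            best = windows.get(w)
            if best is None or _beats(snp, best):
                windows[w] = snp
        out.extend(windows[w] for w in sorted(windows))
    return out


def _beats(a: MapSNP, b: MapSNP) -> bool:
    return (-a.heterozygosity, a.maf, a.pos) < (-b.heterozygosity, b.maf, b.pos)


def trim_pedigree(family: Family, scope: str = "IBD",
                  include_ibdu_in_cd: bool = False) -> tuple[Family, bool]:
    """Trim a pedigree to sequenced scope-affected members and their
    connecting ancestors.

    Iteratively removes individuals who are neither retained affecteds nor
    parents of a remaining member.  Returns the trimmed family and an
    informative flag (>= 2 retained affecteds).
    """
    family.validate()
    keep = {m.id for m in family}
    affected = {
        m.id for m in family.affected(scope, True, include_ibdu_in_cd)
    }
    changed = True
    while changed:
        changed = False
        parents = set()
        for iid in keep:
            m = family[iid]
            if m.father_id in keep:
                parents.add(m.father_id)
            if m.mother_id in keep:
                parents.add(m.mother_id)
        for iid in list(keep):
            if iid not in affected and iid not in parents:
                keep.discard(iid)
                changed = True
    trimmed = Family(family.id)
    for m in family.topological_order():
        if m.id in keep:
            trimmed.add(Individual(
                id=m.id, family_id=family.id,
                father_id=m.father_id if m.father_id in keep else None,
                mother_id=m.mother_id if m.mother_id in keep else None,
                sex=m.sex, phenotype=m.phenotype, sequenced=m.sequenced,
            ))
    informative = len(affected & keep) >= 2
    return trimmed, informative


def select_loci(chrom: Sequence[str], bp: Sequence[int], lod: Sequence[float],
                threshold: float = 1.5) -> list[Locus]:
    """Maximal contiguous runs of the LOD curve at or above *threshold*.

    The curve is given on the linkage-map grid as parallel chrom/bp/LOD
    arrays; each locus carries its peak LOD.
    """
    chrom = [str(c) for c in chrom]
    bp = np.asarray(bp, dtype=np.int64)
    lod = np.asarray(lod, dtype=float)
    loci: list[Locus] = []
    run_start = None
    for i in range(len(lod) + 1):
        in_run = i < len(lod) and lod[i] >= threshold and (
            run_start is None or chrom[i] == chrom[run_start]
        )
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            seg = slice(run_start, i)
            loci.append(Locus(
                chrom=chrom[run_start],
                start_bp=int(bp[seg][0]), end_bp=int(bp[seg.stop - 1]),
                peak_lod=float(lod[seg].max()),
            ))
            run_start = i if (i < len(lod) and lod[i] >= threshold) else None
    return loci


def contributing_families(table: LinkageTable, locus: Locus,
                          family_ids: Optional[Iterable[str]] = None) -> set[str]:
    """Families with mean per-family LOD strictly above 0 across the locus."""
    fids = set(family_ids) if family_ids is not None else table.family_ids()
    out: set[str] = set()
    for fid in fids:
        mean = table.mean_lod(fid, locus)
        if mean is None:
            warnings.warn(f"family {fid} has no LOD values at locus {locus}; excluded")
            continue
        if mean > 0:
            out.add(fid)
    return out


def _family_carriers(v: VariantRecord, family: Family, scope: str,
                     include_ibdu_in_cd: bool = False) -> int:
    """Count sequenced scope-affected members carrying >= 1 alternate allele."""
    idx = {s: i for i, s in enumerate(v.samples)}
    n = 0
    for m in family.affected(scope, True, include_ibdu_in_cd):
        i = idx.get(m.id)
        if i is not None and v.dosages[i] not in (MISSING, 0):
            n += 1
    return n


def linkage_shared_variants(variants: Iterable[VariantRecord], loci: Sequence[Locus],
                            cohort: Cohort, table: LinkageTable,
                            gene_intervals: pd.DataFrame, scope: str = "IBD",
                            af_max: float = 0.05, min_carriers: int = 2,
                            min_families: int = 2,
                            include_ibdu_in_cd: bool = False) -> pd.DataFrame:
    """Shared-variant filter over linkage loci.

    Keeps rare (control AF < ``af_max``) damaging variants in genes
    overlapping a selected locus that are carried by at least
    ``min_carriers`` scope-affected members in each of at least
    ``min_families`` families contributing to that locus's linkage signal.
    Returns one row per (variant, locus) with the contributing-family count.
    """
    gene_loci: dict[str, list[Locus]] = {}
    for row in gene_intervals.itertuples():
        for locus in loci:
            if locus.overlaps(row.chrom, row.start, row.end):
                gene_loci.setdefault(row.gene, []).append(locus)

    rows = []
    for v in variants:
        if v.gene is None or v.gene not in gene_loci:
            continue
        if control_af(v, "filtering") >= af_max:
            continue
        if not is_damaging(v.consequence, v.carol, v.cadd):
            continue
        for locus in gene_loci[v.gene]:
            contrib = contributing_families(table, locus)
            n_fams = sum(
                1 for fid in contrib
                if _family_carriers(v, cohort.families[fid], scope, include_ibdu_in_cd)
                >= min_carriers
            )
            if n_fams >= min_families:
                rows.append({
                    "key": v.key, "gene": v.gene, "consequence": v.consequence.value,
                    "effect": v.effect, "control_af": control_af(v, "filtering"),
                    "locus": f"{locus.chrom}:{locus.start_bp}-{locus.end_bp}",
                    "n_families": n_fams,
                })
    return pd.DataFrame(
        rows, columns=["key", "gene", "consequence", "effect", "control_af",
                       "locus", "n_families"],
    )
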