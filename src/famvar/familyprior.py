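"""Within-family rare-variant sharing, segregation filtering against
unaffected relatives, and exact conditional transmission probabilities.

The conditional probability machinery assumes the variant is very rare:
exactly one carrier founder, heterozygous, with every other founder
homozygous reference.  Probabilities are computed by exhaustive enumeration
of the carrier founder (uniform over founders consistent with the observed
carriers) and of all Mendelian transmission patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotate import control_af, is_damaging
from .model import MISSING, Cohort, Family, Phenotype, VariantRecord

__all__ = [
    "SharingResult",
    "SegregationResult",
    "select_lfams",
    "family_carrier_fraction",
    "prioritize_rare_family_variants",
    "eligible_unaffecteds",
    "segregation_filter",
    "conditional_unaffected_prob",
    "segregation_power",
    "InconsistentPedigreeError",
]


class InconsistentPedigreeError(ValueError):
    """No single-carrier-founder labeling is consistent with observed carriers."""


@dataclass(frozen=True)
class SharingResult:
    key: str
    family_id: str
    scope: str
    n_affected_carriers: int
    n_affected: int

    @property
    def fraction(self) -> float:
        return self.n_affected_carriers / self.n_affected

    @property
    def passes_75(self) -> bool:
        return self.fraction >= 0.75


@dataclass(frozen=True)
class SegregationResult:
    key: str
    family_id: str
    n_unaffected_carriers: int
    n_unaffected: int
    conditional_prob: Optional[float] = None

    @property
    def passes_third(self) -> bool:
        return self.n_unaffected_carriers * 3 <= self.n_unaffected


def select_lfams(cohort: Cohort, scope: str, min_affected: int = 4,
                 include_ibdu_in_cd: bool = False) -> list[Family]:
    """Families with at least *min_affected* sequenced scope-affected members."""
    return [
        fam for fam in cohort.families.values()
        if fam.is_lfam(scope, min_affected, include_ibdu_in_cd)
    ]


def family_carrier_fraction(v: VariantRecord, family: Family, scope: str,
                            include_ibdu_in_cd: bool = False) -> SharingResult:
    """Fraction of evaluable sequenced affecteds carrying the alternate allele.

    Affecteds with a missing genotype are excluded from the denominator
    (the record is flagged when this happens).
    """
    idx = {s: i for i, s in enumerate(v.samples)}
    n_affected = 0
    n_carriers = 0
    for m in family.affected(scope, True, include_ibdu_in_cd):
        i = idx.get(m.id)
        if i is None or v.dosages[i] == MISSING:
            v.flags.add("affected_genotype_missing")
            continue
        n_affected += 1
        if v.dosages[i] > 0:
            n_carriers += 1
    if n_affected == 0:
        raise ValueError(
            f"no evaluable affected genotypes for {v.key} in family {family.id}"
        )
    return SharingResult(v.key, family.id, scope, n_carriers, n_affected)


def prioritize_rare_family_variants(variants: Iterable[VariantRecord],
                                    lfams: Sequence[Family], scope: str,
                                    af_max: float = 0.005,
                                    min_fraction: float = 0.75,
                                    include_ibdu_in_cd: bool = False) -> pd.DataFrame:
    """Very-rare damaging variants shared by >= 75% of affecteds in >= 1 lfam.

    Returns one row per variant with per-family provenance (semicolon-joined
    ``family:carriers/affected`` entries) and the distinct-lfam count.
    """
    rows = []
    for v in variants:
        if control_af(v, "filtering") >= af_max:
            continue
        if not is_damaging(v.consequence, v.carol, v.cadd):
            continue
        passing: list[SharingResult] = []
        for fam in lfams:
            try:
                res = family_carrier_fraction(v, fam, scope, include_ibdu_in_cd)
            except ValueError:
                continue
            if res.passes_75 and res.fraction >= min_fraction:
                passing.append(res)
        if passing:
            rows.append({
                "key": v.key, "gene": v.gene,
                "consequence": v.consequence.value, "effect": v.effect,
                "control_af": control_af(v, "filtering"),
                "n_lfams": len(passing),
                "families": ";".join(
                    f"{r.family_id}:{r.n_affected_carriers}/{r.n_affected}"
                    for r in passing
                ),
            })
    return pd.DataFrame(
        rows, columns=["key", "gene", "consequence", "effect", "control_af",
                       "n_lfams", "families"],
    )


def eligible_unaffecteds(family: Family, scope: str = "IBD",
                         include_ibdu_in_cd: bool = False) -> list[str]:
    """Sequenced unaffected siblings or offspring of affecteds, excluding
    parents of any affected (obligate-carrier proxy)."""
    affect = {m.id for m in family.affected(scope, False, include_ibdu_in_cd)}
    parents_of_affected = set()
    for iid in affect:
        m = family[iid]
        parents_of_affected.update(p for p in (m.father_id, m.mother_id) if p)
    out = []
    for m in family:
        if m.phenotype is not Phenotype.UNAFFECTED or not m.sequenced:
            continue
        if m.id in parents_of_affected:
            continue
        is_offspring = m.father_id in affect or m.mother_id in affect
        is_sibling = any(
            (m.father_id is not None and m.father_id == family[a].father_id)
            and (m.mother_id is not None and m.mother_id == family[a].mother_id)
            for a in affect
        )
        if is_offspring or is_sibling:
            out.append(m.id)
    return sorted(out)


def segregation_filter(v: VariantRecord, family: Family, scope: str = "IBD",
                       min_unaffected: int = 2,
                       include_ibdu_in_cd: bool = False) -> Optional[SegregationResult]:
    """Apply the <= 1/3 unaffected-carrier rule over eligible unaffecteds.

    Returns ``None`` (family skipped) when fewer than *min_unaffected*
    eligible unaffecteds have a called genotype.
    """
    eligible = eligible_unaffecteds(family, scope, include_ibdu_in_cd)
    idx = {s: i for i, s in enumerate(v.samples)}
    evaluable = [
        iid for iid in eligible
        if iid in idx and v.dosages[idx[iid]] != MISSING
    ]
    if len(evaluable) < min_unaffected:
        return None
    carriers = sum(1 for iid in evaluable if v.dosages[idx[iid]] > 0)
    return SegregationResult(v.key, family.id, carriers, len(evaluable))


# ---------------------------------------------------------------------------
# exact conditional transmission probabilities

def _transmission_prob(child: int, d_f: int, d_m: int) -> float:
    """P(child dosage | parent dosages) under Mendelian transmission."""
    def bern(d: int) -> tuple[float, float]:
        p1 = d / 2.0
        return (1.0 - p1, p1)
    pf, pm = bern(d_f), bern(d_m)
    if child == 0:
        return pf[0] * pm[0]
    if child == 1:
        return pf[0] * pm[1] + pf[1] * pm[0]
    if child == 2:
        return pf[1] * pm[1]
    return 0.0


def _joint_prob(family: Family, founder_dosages: Mapping[str, int],
                observed: Mapping[str, int]) -> float:
    """P(observed dosages) given fixed founder dosages, by enumeration of all
    Mendelian transmission outcomes for unobserved members."""
    order = [m for m in family.topological_order() if not m.is_founder]
    for iid, d in founder_dosages.items():
        if iid in observed and observed[iid] != d:
            return 0.0

    def recurse(i: int, dosages: dict[str, int]) -> float:
        if i == len(order):
            return 1.0
        m = order[i]
        d_f = dosages[m.father_id]
        d_m = dosages[m.mother_id]
        total = 0.0
        targets = (observed[m.id],) if m.id in observed else (0, 1, 2)
        for c in targets:
            p = _transmission_prob(c, d_f, d_m)
            if p == 0.0:
                continue
            dosages[m.id] = c
            total += p * recurse(i + 1, dosages)
            del dosages[m.id]
        return total

    return recurse(0, dict(founder_dosages))


def conditional_unaffected_prob(family: Family,
                                affected_genotypes: Mapping[str, int],
                                unaffected_genotypes: Mapping[str, int]) -> float:
    """P(unaffected genotype vector | affected genotype vector).

    Assumes a single heterozygous carrier founder (all other founders
    homozygous reference), chosen uniformly over founders consistent with
    the observed affected genotypes; transmission patterns are enumerated
    exhaustively.  Observed carriers must be heterozygous.
    """
    for who, genos in (("affected", affected_genotypes),
                       ("unaffected", unaffected_genotypes)):
        for iid, d in genos.items():
            if iid not in family:
                raise KeyError(f"{who} individual {iid!r} not in family {family.id!r}")
            if d not in (0, 1):
                raise ValueError(
                    f"observed carriers must be heterozygous; {iid} has dosage {d}"
                )
    overlap = set(affected_genotypes) & set(unaffected_genotypes)
    if overlap:
        raise ValueError(f"individuals in both observation sets: {sorted(overlap)}")

    founders = family.founders
    num = 0.0
    den = 0.0
    both = {**affected_genotypes, **unaffected_genotypes}
    for f in founders:
        fd = {m.id: (1 if m.id == f.id else 0) for m in founders}
        p_aff = _joint_prob(family, fd, affected_genotypes)
        if p_aff > 0.0:
            den += p_aff
            num += _joint_prob(family, fd, both)
    if den == 0.0:
        raise InconsistentPedigreeError(
            f"no single carrier founder consistent with the affected genotypes "
            f"in family {family.id!r}"
        )
    return num / den


def segregation_power(family: Family, affected_genotypes: Mapping[str, int],
                      unaffected_ids: Sequence[str], alpha: float = 0.05) -> bool:
    """Whether complete non-transmission to the unaffecteds would reach *alpha*.

    The minimal achievable conditional probability is that of every eligible
    unaffected being a non-carrier; the family has power iff it is below
    *alpha*.
    """
    all_zero = {iid: 0 for iid in unaffected_ids}
    return conditional_unaffected_prob(family, affected_genotypes, all_zero) < alpha
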