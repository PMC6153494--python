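"""Core domain types: individuals, families, cohorts, variants, maps and loci.

Coordinates are 1-based and fully closed throughout, matching VCF
conventions.  Variant identity is the underscore-joined key
``chrom_pos_ref_alt`` (e.g. ``16_50763778_G_GC``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = [
    "Sex",
    "Phenotype",
    "Individual",
    "Family",
    "Cohort",
    "VariantRecord",
    "GeneticMap",
    "Locus",
    "LinkageTable",
    "PedigreeError",
    "variant_key",
    "MISSING",
]

#: sentinel dosage for a missing genotype call
MISSING: int = -1


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, half-specified parents...)."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(str, Enum):
    CD = "CD"
    UC = "UC"
    IBDU = "IBDU"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"

    @property
    def is_ibd_affected(self) -> bool:
        return self in _IBD_AFFECTED


_IBD_AFFECTED = frozenset({Phenotype.CD, Phenotype.UC, Phenotype.IBDU})

#: analysis scopes: "CD" counts CD only, "IBD" counts CD+UC+IBDU
SCOPES = ("CD", "IBD")


def affected_in_scope(phenotype: Phenotype, scope: str, include_ibdu_in_cd: bool = False) -> bool:
    """Whether *phenotype* counts as affected for the analysis *scope*.

    The composite IBD scope covers CD, UC and unclassified IBD.  Whether
    unclassified cases count toward CD-specific analyses is configurable
    (default: they do not).
    """
    if scope == "IBD":
        return phenotype.is_ibd_affected
    if scope == "CD":
        if phenotype is Phenotype.CD:
            return True
        return include_ibdu_in_cd and phenotype is Phenotype.IBDU
    raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN
    sequenced: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def is_affected(self, scope: str = "IBD", include_ibdu_in_cd: bool = False) -> bool:
        return affected_in_scope(self.phenotype, scope, include_ibdu_in_cd)


class Family:
    """A pedigree: a set of individuals with resolved parent links."""

    def __init__(self, id: str, members: Iterable[Individual] = ()):
        self.id = id
        self.members: dict[str, Individual] = {}
        for ind in members:
            self.add(ind)

    def add(self, ind: Individual) -> None:
        if ind.id in self.members:
            raise PedigreeError(f"duplicate individual id {ind.id!r} in family {self.id!r}")
        self.members[ind.id] = ind

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        return self.members[iid]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self if not m.is_founder]

    def validate(self) -> None:
        """Check structural invariants; raise :class:`PedigreeError` if violated."""
        for m in self:
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"individual {m.id!r} in family {self.id!r} lists exactly one parent"
                )
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"parent {pid!r} of {m.id!r} not present in family {self.id!r}"
                    )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children; raises on a cycle."""
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, chain: tuple[str, ...]) -> None:
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError(
                    f"cyclic pedigree in family {self.id!r} involving {iid!r}"
                )
            state[iid] = 0
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    if pid == iid:
                        raise PedigreeError(
                            f"individual {iid!r} lists itself as a parent"
                        )
                    visit(pid, chain + (iid,))
            state[iid] = 1
            order.append(ind)

        for iid in self.members:
            visit(iid, ())
        return order

    def children_of(self, iid: str) -> list[Individual]:
        return [m for m in self if iid in (m.father_id, m.mother_id)]

    def affected(self, scope: str = "IBD", sequenced_only: bool = True,
                 include_ibdu_in_cd: bool = False) -> list[Individual]:
        return [
            m for m in self
            if m.is_affected(scope, include_ibdu_in_cd)
            and (m.sequenced or not sequenced_only)
        ]

    def unaffected(self, sequenced_only: bool = True) -> list[Individual]:
        return [
            m for m in self
            if m.phenotype is Phenotype.UNAFFECTED and (m.sequenced or not sequenced_only)
        ]

    def is_lfam(self, scope: str = "IBD", min_affected: int = 4,
                include_ibdu_in_cd: bool = False) -> bool:
        """Large family: at least *min_affected* sequenced scope-affected members."""
        return len(self.affected(scope, True, include_ibdu_in_cd)) >= min_affected


class Cohort:
    """Families plus singleton sporadic cases and controls."""

    def __init__(self, families: Iterable[Family] = ()):
        self.families: dict[str, Family] = {}
        for fam in families:
            self.add_family(fam)

    def add_family(self, fam: Family) -> None:
        if fam.id in self.families:
            raise PedigreeError(f"duplicate family id {fam.id!r}")
        self.families[fam.id] = fam

    def __len__(self) -> int:
        return sum(len(f) for f in self.families.values())

    def __iter__(self) -> Iterator[Individual]:
        for fam in self.families.values():
            yield from fam

    @property
    def individuals(self) -> dict[str, Individual]:
        out: dict[str, Individual] = {}
        for ind in self:
            if ind.id in out:
                raise PedigreeError(f"sample id {ind.id!r} appears in more than one family")
            out[ind.id] = ind
        return out

    @property
    def multiplex_families(self) -> list[Family]:
        """Families with at least two IBD-affected members."""
        return [f for f in self.families.values() if len(f.affected("IBD", False)) >= 2]

    @property
    def sporadic_cases(self) -> list[Individual]:
        """Affected individuals in families with exactly one affected member."""
        out = []
        for fam in self.families.values():
            aff = fam.affected("IBD", False)
            if len(aff) == 1:
                out.extend(aff)
        return out

    @property
    def controls(self) -> list[Individual]:
        """Unaffected members of families with no affected member."""
        out = []
        for fam in self.families.values():
            if not fam.affected("IBD", False):
                out.extend(m for m in fam if m.phenotype is Phenotype.UNAFFECTED)
        return out

    def founder_count(self) -> int:
        return sum(len(f.founders) for f in self.families.values())

    def validate(self) -> None:
        for fam in self.families.values():
            fam.validate()
        self.individuals  # global id uniqueness


def variant_key(chrom: str | int, pos: int, ref: str, alt: str) -> str:
    """Render the canonical underscore-joined variant key.

    >>> variant_key(16, 50763778, "G", "GC")
    '16_50763778_G_GC'
    """
    if int(pos) < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    ref = str(ref).upper()
    alt = str(alt).upper()
    if not ref or not alt:
        raise ValueError("empty allele string")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical ({ref})")
    return f"{chrom}_{pos}_{ref}_{alt}"


class Consequence(str, Enum):
    FRAMESHIFT = "frameshift"
    START_LOSS = "start_loss"
    STOP_GAIN = "stop_gain"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    MISSENSE = "missense"
    OTHER = "other"


#: consequence classes treated as damaging regardless of scores
HIGH_IMPACT = frozenset({
    Consequence.FRAMESHIFT,
    Consequence.START_LOSS,
    Consequence.STOP_GAIN,
    Consequence.SPLICE_ACCEPTOR,
    Consequence.SPLICE_DONOR,
})


@dataclass
class VariantRecord:
    """One alternate allele at one site, with per-sample genotypes.

    ``dosages`` counts copies of the alternate allele per sample (after any
    minor-allele orientation flip); ``MISSING`` (-1) marks uncalled
    genotypes.  ``gq``/``ad_ref``/``ad_alt`` use -1 where the FORMAT field
    was absent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    samples: list[str] = field(default_factory=list)
    dosages: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    gq: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    ad_ref: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    ad_alt: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int32))
    vqsr_tranche: Optional[float] = None
    gene: Optional[str] = None
    effect: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    carol: Optional[str] = None  # "damaging" | "benign" | None
    cadd: Optional[float] = None
    af_aj: Optional[float] = None
    af_nfe: Optional[float] = None
    af_paj: Optional[float] = None
    af_aj_wgs: Optional[float] = None
    flags: set = field(default_factory=set)

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def dosage_of(self, sample: str) -> int:
        return int(self.dosages[self.samples.index(sample)])

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def call_rate(self) -> float:
        if self.dosages.size == 0:
            return 0.0
        return float(np.mean(self.called_mask()))

    def copy(self) -> "VariantRecord":
        new = VariantRecord(
            chrom=self.chrom, pos=self.pos, ref=self.ref, alt=self.alt,
            samples=list(self.samples),
            dosages=self.dosages.copy(), gq=self.gq.copy(),
            ad_ref=self.ad_ref.copy(), ad_alt=self.ad_alt.copy(),
            vqsr_tranche=self.vqsr_tranche, gene=self.gene, effect=self.effect,
            consequence=self.consequence, carol=self.carol, cadd=self.cadd,
            af_aj=self.af_aj, af_nfe=self.af_nfe, af_paj=self.af_paj,
            af_aj_wgs=self.af_aj_wgs, flags=set(self.flags),
        )
        return new


class GeneticMap:
    """Piecewise-linear bp -> cM map per chromosome."""

    def __init__(self, anchors: Iterable[tuple[str, int, float]]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        buckets: dict[str, list[tuple[int, float]]] = {}
        for chrom, bp, cm in anchors:
            buckets.setdefault(str(chrom), []).append((int(bp), float(cm)))
        for chrom, pts in buckets.items():
            pts.sort()
            bps = np.array([p[0] for p in pts], dtype=np.int64)
            cms = np.array([p[1] for p in pts], dtype=float)
            if np.any(np.diff(cms) < 0):
                raise ValueError(f"cM not non-decreasing with bp on chromosome {chrom}")
            self._by_chrom[chrom] = (bps, cms)

    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._by_chrom[str(chrom)]
        except KeyError:
            raise KeyError(f"no genetic-map anchors for chromosome {chrom!r}") from None


@dataclass(frozen=True)
class Locus:
    chrom: str
    start_bp: int
    end_bp: int
    peak_lod: float

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return str(chrom) == self.chrom and start <= self.end_bp and end >= self.start_bp


class LinkageTable:
    """Per-family mean LOD scores over genomic intervals."""

    def __init__(self) -> None:
        # (family_id, chrom) -> list of (start, end, mean_lod)
        self._rows: dict[tuple[str, str], list[tuple[int, int, float]]] = {}

    def add(self, family_id: str, chrom: str, start_bp: int, end_bp: int, mean_lod: float) -> None:
        self._rows.setdefault((family_id, str(chrom)), []).append(
            (int(start_bp), int(end_bp), float(mean_lod))
        )

    def family_ids(self) -> set[str]:
        return {fid for fid, _ in self._rows}

    def mean_lod(self, family_id: str, locus: Locus) -> Optional[float]:
        """Mean per-family LOD over intervals overlapping *locus*; None if no data."""
        rows = self._rows.get((family_id, locus.chrom), [])
        vals = [
            lod for start, end, lod in rows
            if start <= locus.end_bp and end >= locus.start_bp
        ]
        if not vals:
            return None
        return float(np.mean(vals))
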