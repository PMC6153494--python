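"""Gene-dropping simulation: null distributions of within-cohort allele
frequency, empirical enrichment p-values and the normal-approximation power
calculation.

Founder genotypes are drawn Binomial(2, control AF); alleles are then
transmitted down the pedigree with heterozygous parents transmitting either
allele with probability 1/2.  Replicates are vectorized: every family is
dropped once per replicate and the cohort AF is computed over sequenced
phenotype-cases outside the index family.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model import Cohort, Family

__all__ = [
    "GeneDropConfig",
    "GeneDropResult",
    "drop_family",
    "drop_family_matrix",
    "simulate_cohort_af",
    "genedrop_pvalue",
    "genedrop_power",
]


@dataclass(frozen=True)
class GeneDropConfig:
    n_sims: int = 100_000
    seed: int = 0
    exclude_family: Optional[str] = None
    scope: str = "IBD"
    include_ibdu_in_cd: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


@dataclass
class GeneDropResult:
    simulated_afs: np.ndarray
    observed_af: Optional[float] = None
    p_value: Optional[float] = None
    n_case_alleles: int = 0

    @property
    def n_sims(self) -> int:
        return self.simulated_afs.size


def drop_family_matrix(family: Family, founder_af: float,
                       rng: np.random.Generator, n_sims: int = 1) -> dict[str, np.ndarray]:
    """Drop a family *n_sims* times; returns per-member dosage vectors.

    Founders are seeded independently Binomial(2, af); children receive one
    allele from each parent, heterozygous parents transmitting either allele
    with probability 1/2 (a parent with dosage d transmits the alternate
    allele with probability d/2).
    """
    if not 0.0 <= founder_af <= 1.0:
        raise ValueError(f"founder AF {founder_af} outside [0, 1]")
    order = family.topological_order()  # raises on cycles
    dosages: dict[str, np.ndarray] = {}
    for m in order:
        if m.is_founder:
            dosages[m.id] = rng.binomial(2, founder_af, size=n_sims).astype(np.int8)
        else:
            from_f = (rng.random(n_sims) < dosages[m.father_id] / 2.0)
            from_m = (rng.random(n_sims) < dosages[m.mother_id] / 2.0)
            dosages[m.id] = (from_f.astype(np.int8) + from_m.astype(np.int8))
    return dosages


def drop_family(family: Family, founder_af: float,
                rng: np.random.Generator) -> dict[str, int]:
    """Single gene-drop replicate; per-member alternate-allele dosages."""
    mat = drop_family_matrix(family, founder_af, rng, n_sims=1)
    return {iid: int(v[0]) for iid, v in mat.items()}


def simulate_cohort_af(cohort: Cohort, founder_af: float,
                       config: GeneDropConfig) -> GeneDropResult:
    """Null distribution of the cohort allele frequency by gene dropping.

    Per replicate every family is dropped independently and the AF is
    computed over sequenced scope-affected individuals excluding the index
    family.  Per-family RNG substreams are derived from the seed and the
    family id, so results are invariant to family processing order.
    """
    case_ids: dict[str, list[str]] = {}
    for fid, fam in cohort.families.items():
        if fid == config.exclude_family:
            continue
        ids = [m.id for m in fam.affected(config.scope, True, config.include_ibdu_in_cd)]
        if ids:
            case_ids[fid] = ids
    n_cases = sum(len(v) for v in case_ids.values())
    if n_cases == 0:
        raise ValueError("no phenotype cases outside the index family")

    alt_total = np.zeros(config.n_sims, dtype=np.int64)
    for fid in sorted(case_ids):
        # stable per-family substream: invariant to processing order and process
        sub = np.random.SeedSequence((config.seed, zlib.crc32(fid.encode())))
        rng = np.random.default_rng(sub)
        dosages = drop_family_matrix(cohort.families[fid], founder_af, rng, config.n_sims)
        for iid in case_ids[fid]:
            alt_total += dosages[iid]
    afs = alt_total / (2.0 * n_cases)
    return GeneDropResult(simulated_afs=afs, n_case_alleles=2 * n_cases)


def genedrop_pvalue(observed_af: float, result: GeneDropResult) -> float:
    """Empirical upper-tail p-value with the (k+1)/(n+1) correction."""
    if not 0.0 <= observed_af <= 1.0:
        raise ValueError(f"observed AF {observed_af} outside [0, 1]")
    k = int(np.sum(result.simulated_afs >= observed_af))
    p = (k + 1) / (result.n_sims + 1)
    result.observed_af = observed_af
    result.p_value = p
    return p


def observed_cohort_af(cohort: Cohort, variant, config: GeneDropConfig) -> float:
    """Observed AF among sequenced scope-cases outside the index family."""
    from .model import MISSING

    idx = {s: i for i, s in enumerate(variant.samples)}
    alt = 0
    alleles = 0
    for fid, fam in cohort.families.items():
        if fid == config.exclude_family:
            continue
        for m in fam.affected(config.scope, True, config.include_ibdu_in_cd):
            i = idx.get(m.id)
            if i is None or variant.dosages[i] == MISSING:
                continue
            alt += int(variant.dosages[i])
            alleles += 2
    if alleles == 0:
        raise ValueError("no called case genotypes outside the index family")
    return alt / alleles


def genedrop_power(founder_af: float, cohort_af_grid, alpha: float,
                   cohort: Cohort, config: GeneDropConfig) -> np.ndarray:
    """Power to detect enrichment at each hypothesized cohort AF.

    From the null distribution of simulated AFs, q = P(sim AF < cohort AF);
    the count of simulated frequencies below the cohort frequency is
    modeled Binomial(n_sims, q), approximated Normal, and power is
    P(K / n_sims >= 1 - alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    null = simulate_cohort_af(cohort, founder_af, config)
    n = null.n_sims
    grid = np.atleast_1d(np.asarray(cohort_af_grid, dtype=float))
    powers = np.empty(grid.size)
    for i, af in enumerate(grid):
        q = float(np.mean(null.simulated_afs < af))
        if q <= 0.0:
            powers[i] = 0.0
        elif q >= 1.0:
            powers[i] = 1.0
        else:
            mu = n * q
            sd = np.sqrt(n * q * (1.0 - q))
            powers[i] = float(stats.norm.sf(n * (1.0 - alpha), loc=mu, scale=sd))
    return powers
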