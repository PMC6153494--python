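"""Genotype-, variant- and sample-level quality control.

Covers per-genotype quality filters, Hardy-Weinberg and call-rate variant
filters, X-homozygosity sex verification, kinship-coefficient relationship
classification (with the expected-kinship pedigree recursion as an oracle),
and the PCA ancestry ellipsoid with proximal-control ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import MISSING, Family, VariantRecord

__all__ = [
    "QCThresholds",
    "KinshipBins",
    "AncestryModel",
    "genotype_qc",
    "apply_genotype_qc",
    "hwe_chi2",
    "variant_qc",
    "infer_sex",
    "classify_kinship",
    "pedigree_kinship",
    "PCAProjector",
    "fit_ancestry_ellipsoid",
    "rank_proximal_controls",
    "genotype_concordance",
]


@dataclass(frozen=True)
class QCThresholds:
    min_gq: int = 30
    min_alt_depth: int = 3
    ab_p_min: float = 0.001
    min_call_rate: float = 0.75
    hwe_p_min: float = 5e-8
    max_tranche_snp: float = 99.5
    max_tranche_indel: float = 99.0
    missing_quality_fails: bool = False


def _allele_balance_p(ad_ref: int, ad_alt: int) -> float:
    """Two-sided chi-square p (with continuity correction) for het balance vs 1:1."""
    n = ad_ref + ad_alt
    if n == 0:
        return 1.0
    # continuity-corrected chi-square against equal expectation
    expected = n / 2.0
    stat = 2 * (max(abs(ad_ref - expected) - 0.5, 0.0)) ** 2 / expected
    return float(stats.chi2.sf(stat, df=1))


def genotype_qc(dosage: int, gq: int, ad_ref: int, ad_alt: int,
                thresholds: QCThresholds = QCThresholds()) -> tuple[bool, Optional[str]]:
    """Evaluate one called genotype; returns (pass, fail-reason).

    Fails on GQ below threshold, alternate depth below threshold for
    carriers, or het allele balance departing from 1:1.  Missing quality
    fields make the call unevaluable: pass-through by default, fail when
    ``missing_quality_fails`` is set.
    """
    if dosage == MISSING:
        return False, "missing"
    if gq < 0 or (dosage >= 1 and (ad_ref < 0 or ad_alt < 0)):
        if thresholds.missing_quality_fails:
            return False, "unevaluable"
        return True, "unevaluable"
    if gq < thresholds.min_gq:
        return False, "gq"
    if dosage >= 1 and ad_alt < thresholds.min_alt_depth:
        return False, "depth"
    if dosage == 1 and _allele_balance_p(ad_ref, ad_alt) < thresholds.ab_p_min:
        return False, "allele_balance"
    return True, None


def apply_genotype_qc(record: VariantRecord,
                      thresholds: QCThresholds = QCThresholds()) -> VariantRecord:
    """Set failing genotypes to missing; returns the (mutated) record."""
    for i, dosage in enumerate(record.dosages):
        if dosage == MISSING:
            continue
        ok, _ = genotype_qc(int(dosage), int(record.gq[i]),
                            int(record.ad_ref[i]), int(record.ad_alt[i]), thresholds)
        if not ok:
            record.dosages[i] = MISSING
    return record


def hwe_chi2(n_rr: int, n_ra: int, n_aa: int) -> float:
    """1-df chi-square p-value of genotype counts against HWE expectation."""
    n = n_rr + n_ra + n_aa
    if n <= 0:
        raise ValueError("all-zero genotype counts")
    p = (2 * n_aa + n_ra) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0  # monomorphic: no departure possible
    exp = np.array([q * q * n, 2 * p * q * n, p * p * n])
    obs = np.array([n_rr, n_ra, n_aa], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(stat, df=1))


def variant_qc(record: VariantRecord,
               thresholds: QCThresholds = QCThresholds()) -> tuple[bool, list[str]]:
    """Variant-level filter; returns (pass, failing reasons).

    Assumes genotype QC already applied (failed genotypes set missing).
    Checks call rate, HWE and the class-specific VQSR tranche bound.
    """
    reasons: list[str] = []
    if record.call_rate() < thresholds.min_call_rate:
        reasons.append("call_rate")
    called = record.dosages[record.called_mask()]
    if called.size:
        counts = [int(np.sum(called == d)) for d in (0, 1, 2)]
        if hwe_chi2(*counts) < thresholds.hwe_p_min:
            reasons.append("hwe")
    if record.vqsr_tranche is not None:
        bound = thresholds.max_tranche_indel if record.is_indel else thresholds.max_tranche_snp
        if record.vqsr_tranche > bound:
            reasons.append("tranche")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# sex

def infer_sex(x_hom_rate: float, n_variants: int = 1000, min_variants: int = 100,
              female_max: float = 0.8, male_min: float = 0.9) -> str:
    """Call sex from the X-chromosome homozygosity rate at common variants."""
    if n_variants < min_variants:
        raise ValueError(
            f"too few X variants ({n_variants} < {min_variants}) for a sex call"
        )
    if x_hom_rate >= male_min:
        return "male"
    if x_hom_rate <= female_max:
        return "female"
    return "ambiguous"


# ---------------------------------------------------------------------------
# kinship

@dataclass(frozen=True)
class KinshipBins:
    """Kinship-coefficient cut points; lower bound inclusive, upper exclusive."""

    dup: float = 0.354
    first: float = 0.177
    second: float = 0.0884
    third: float = 0.0442

    def __post_init__(self) -> None:
        if not (self.dup > self.first > self.second > self.third > 0):
            raise ValueError("kinship cut points must be strictly decreasing and positive")


def classify_kinship(phi: float, bins: KinshipBins = KinshipBins()) -> str:
    """Map a kinship coefficient to a relationship class."""
    if phi > bins.dup:
        return "duplicate"
    if phi >= bins.first:
        return "first"
    if phi >= bins.second:
        return "second"
    if phi >= bins.third:
        return "third"
    return "unrelated"


def pedigree_kinship(family: Family) -> dict[tuple[str, str], float]:
    """Expected kinship coefficients from the pedigree by the standard recursion.

    phi(i,i) = 0.5 * (1 + phi(f, m)); for non-founder i not an ancestor of j,
    phi(i,j) = 0.5 * (phi(f_i, j) + phi(m_i, j)); founders are mutually
    unrelated.  Returns a symmetric dict keyed by ordered id pairs.
    """
    order = family.topological_order()  # raises on cycle
    depth: dict[str, int] = {}
    for ind in order:
        if ind.is_founder:
            depth[ind.id] = 0
        else:
            depth[ind.id] = 1 + max(depth[ind.father_id], depth[ind.mother_id])

    phi: dict[tuple[str, str], float] = {}

    def get(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in phi:
            return phi[key]
        ia, ib = family[a], family[b]
        if a == b:
            val = 0.5 if ia.is_founder else 0.5 * (1 + get(ia.father_id, ia.mother_id))
        else:
            # recurse on the deeper individual so we never recurse into an ancestor
            if depth[a] < depth[b]:
                ia, ib = ib, ia
            if ia.is_founder:
                val = 0.0
            else:
                val = 0.5 * (get(ia.father_id, ib.id) + get(ia.mother_id, ib.id))
        phi[key] = val
        return val

    ids = [m.id for m in order]
    for i, a in enumerate(ids):
        for b in ids[i:]:
            get(a, b)
    return phi


# ---------------------------------------------------------------------------
# ancestry

class PCAProjector:
    """Centered PCA with projection of held-out samples onto training loadings."""

    def __init__(self, n_components: int = 5):
        self.n_components = n_components
        self.mean_: Optional[np.ndarray] = None
        self.components_: Optional[np.ndarray] = None

    def fit(self, genotypes: np.ndarray) -> "PCAProjector":
        X = np.asarray(genotypes, dtype=float)
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        self.components_ = vt[: self.n_components]
        return self

    def transform(self, genotypes: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("fit before transform")
        return (np.asarray(genotypes, dtype=float) - self.mean_) @ self.components_.T

    def fit_transform(self, genotypes: np.ndarray) -> np.ndarray:
        return self.fit(genotypes).transform(genotypes)


@dataclass
class AncestryModel:
    n_pcs: int
    mean: np.ndarray
    covariance: np.ndarray
    coverage: float
    d2_threshold: float
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.covariance)

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.mean
        return np.einsum("ij,jk,ik->i", d, self._cov_inv, d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.d2_threshold


def fit_ancestry_ellipsoid(points: np.ndarray, n_pcs: int = 5, coverage: float = 0.90,
                           outlier_quantile: float = 1 - 1e-3,
                           max_iter: int = 50) -> AncestryModel:
    """Fit a Gaussian ellipsoid to PC coordinates after iterated outlier trimming.

    Repeatedly fits mean/covariance and drops points whose squared
    Mahalanobis distance exceeds the ``outlier_quantile`` chi-square
    quantile, until no point is dropped.  The membership threshold is the
    ``coverage`` chi-square quantile with ``n_pcs`` degrees of freedom.
    """
    X = np.asarray(points, dtype=float)[:, :n_pcs]
    if X.shape[0] <= n_pcs:
        raise ValueError(f"need more than {n_pcs} points to fit {n_pcs} PCs")
    keep = np.ones(X.shape[0], dtype=bool)
    cut = stats.chi2.ppf(outlier_quantile, df=n_pcs)
    for _ in range(max_iter):
        mean = X[keep].mean(axis=0)
        cov = np.cov(X[keep], rowvar=False)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                "singular covariance in ancestry fit; try fewer PCs"
            ) from None
        d = X - mean
        d2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
        new_keep = keep & (d2 <= cut)
        if new_keep.sum() <= n_pcs:
            break
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return AncestryModel(
        n_pcs=n_pcs, mean=mean, covariance=cov, coverage=coverage,
        d2_threshold=float(stats.chi2.ppf(coverage, df=n_pcs)),
        _cov_inv=cov_inv,
    )


def rank_proximal_controls(model: AncestryModel, candidates: np.ndarray,
                           ids: Sequence[str], k: int = 500) -> list[str]:
    """The k candidate ids nearest the fitted center by Mahalanobis distance."""
    ids = list(ids)
    pts = np.atleast_2d(np.asarray(candidates, dtype=float))[:, : model.n_pcs]
    if len(ids) != pts.shape[0]:
        raise ValueError("ids and candidate coordinates differ in length")
    if k > len(ids):
        warnings.warn(f"k={k} exceeds {len(ids)} candidates; returning all")
        k = len(ids)
    d2 = model.mahalanobis_sq(pts)
    order = sorted(range(len(ids)), key=lambda i: (d2[i], ids[i]))
    return [ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# concordance

def genotype_concordance(a: Iterable[int], b: Iterable[int]) -> float:
    """Fraction of equal calls among pairwise co-observed (non-missing) sites."""
    a = np.asarray(list(a))
    b = np.asarray(list(b))
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    mask = (a != MISSING) & (b != MISSING)
    if not mask.any():
        raise ValueError("no co-observed sites")
    return float(np.mean(a[mask] == b[mask]))
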