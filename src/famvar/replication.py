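"""Case/control replication statistics: Fisher allele tests, simulation-based
power, correlation-informed multiple-testing correction, and the CMC
gene-burden test."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCCohort",
    "ReplicationResult",
    "TestBudget",
    "fisher_allele_test",
    "min_phenotype_result",
    "cc_power",
    "find_or_for_power",
    "effective_dataset_count",
    "bonferroni_threshold",
    "count_significant",
    "cmc_burden_test",
    "compare_af_distributions",
]

PHENOTYPE_PRIORITY = ("IBD", "CD", "UC")


@dataclass(frozen=True)
class CCCohort:
    phenotype: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort counts must be positive")


@dataclass(frozen=True)
class ReplicationResult:
    key: str
    phenotype: str
    p: float
    odds_ratio: Optional[float]
    case_af: float
    control_af: float
    or_flag: Optional[str] = None


@dataclass(frozen=True)
class TestBudget:
    __test__ = False  # not a pytest class despite the name

    n_linkage_variants: int
    n_rare_variants: int
    eff_cc_datasets: int
    eff_gd_datasets: int

    @property
    def total_tests(self) -> int:
        return (self.n_linkage_variants * self.eff_cc_datasets
                + self.n_rare_variants * (self.eff_cc_datasets + self.eff_gd_datasets))


def fisher_allele_test(case_alt: int, case_ref: int, ctrl_alt: int,
                       ctrl_ref: int) -> tuple[float, Optional[float], Optional[str]]:
    """Two-sided Fisher exact test on a 2x2 allele-count table.

    Returns (p, odds ratio, flag).  The OR is the cross-product ratio; a
    0.5 continuity correction is applied only when some cell is zero
    (flagged ``continuity``).  With both alternate counts zero, p = 1 and
    the OR is undefined.
    """
    cells = (case_alt, case_ref, ctrl_alt, ctrl_ref)
    if any(c < 0 for c in cells):
        raise ValueError("negative count")
    if case_alt + case_ref == 0 or ctrl_alt + ctrl_ref == 0:
        raise ValueError("empty study arm")
    if case_alt == 0 and ctrl_alt == 0:
        return 1.0, None, "undefined"
    _, p = stats.fisher_exact([[case_alt, case_ref], [ctrl_alt, ctrl_ref]],
                              alternative="two-sided")
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)
        return float(p), (a * d) / (b * c), "continuity"
    return float(p), (case_alt * ctrl_ref) / (case_ref * ctrl_alt), None


def min_phenotype_result(results: Iterable[ReplicationResult],
                         priority: Sequence[str] = PHENOTYPE_PRIORITY) -> ReplicationResult:
    """The per-phenotype result with the smallest p; ties break by priority."""
    results = list(results)
    if not results:
        raise ValueError("no phenotype results supplied")
    rank = {ph: i for i, ph in enumerate(priority)}
    return min(results, key=lambda r: (r.p, rank.get(r.phenotype, len(rank))))


# ---------------------------------------------------------------------------
# vectorized two-sided Fisher p (for power simulation)

def _fisher_p_vec(case_alt: np.ndarray, ctrl_alt: np.ndarray,
                  case_alleles: int, ctrl_alleles: int) -> np.ndarray:
    """Two-sided Fisher p for many 2x2 allele tables with fixed arm totals.

    For each table the conditional distribution of the case alternate count
    is hypergeometric given the total alternate count; the two-sided p sums
    the probabilities of all outcomes no more likely than the observed one
    (with the standard small relative tolerance for ties).
    """
    from scipy.special import gammaln

    case_alt = np.asarray(case_alt, dtype=np.int64)
    ctrl_alt = np.asarray(ctrl_alt, dtype=np.int64)
    n_tot = case_alt + ctrl_alt
    N = case_alleles + ctrl_alleles
    lo = np.maximum(0, n_tot - ctrl_alleles)
    hi = np.minimum(n_tot, case_alleles)
    width = int(np.max(hi - lo)) + 1
    support = lo[:, None] + np.arange(width)[None, :]
    valid = support <= hi[:, None]
    support = np.where(valid, support, lo[:, None])

    def logcomb(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    denom = logcomb(N, n_tot)
    pmf = np.exp(logcomb(case_alleles, support)
                 + logcomb(ctrl_alleles, n_tot[:, None] - support)
                 - denom[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs_pmf = np.exp(logcomb(case_alleles, case_alt)
                     + logcomb(ctrl_alleles, ctrl_alt) - denom)
    take = pmf <= obs_pmf[:, None] * (1.0 + 1e-7)
    return np.minimum(np.sum(np.where(take, pmf, 0.0), axis=1), 1.0)


def _case_af_from_or(control_af: float, odds_ratio: float) -> float:
    odds = control_af / (1.0 - control_af) * odds_ratio
    return odds / (1.0 + odds)


def cc_power(control_af: float, odds_ratio: float, cohort: CCCohort, alpha: float,
             n_sims: int = 10_000, rng: Optional[np.random.Generator] = None,
             log_or_sd: float = 0.0) -> float:
    """Power of the Fisher allele test by simulation.

    Per replicate the case AF is derived from the control AF and the odds
    ratio on the odds scale, allele counts are drawn Binomial(2n, AF) per
    arm, and the two-sided Fisher test is applied; power is the fraction of
    replicates reaching ``alpha``.  ``log_or_sd`` > 0 draws the per-replicate
    log odds ratio from Normal(log OR, sd) instead of holding it fixed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < control_af < 1.0:
        raise ValueError("control AF must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    case_alleles = 2 * cohort.n_cases
    ctrl_alleles = 2 * cohort.n_controls
    if log_or_sd > 0:
        ors = np.exp(rng.normal(np.log(odds_ratio), log_or_sd, size=n_sims))
        case_afs = np.array([_case_af_from_or(control_af, o) for o in ors])
    else:
        case_af = _case_af_from_or(control_af, odds_ratio)
        if case_af >= 1.0:
            raise ValueError("case AF >= 1 under the supplied odds ratio")
        case_afs = np.full(n_sims, case_af)
    case_alt = rng.binomial(case_alleles, case_afs)
    ctrl_alt = rng.binomial(ctrl_alleles, control_af, size=n_sims)
    p = _fisher_p_vec(case_alt, ctrl_alt, case_alleles, ctrl_alleles)
    return float(np.mean(p < alpha))


def find_or_for_power(control_af: float, cohort: CCCohort, alpha: float,
                      target: float = 0.80, n_sims: int = 10_000,
                      seed: int = 0, or_cap: float = 64.0,
                      precision: float = 0.05) -> float:
    """Smallest odds ratio achieving *target* power, by bisection.

    Power is monotone in the odds ratio; each evaluation reuses the same
    replicate stream (common random numbers) for stability.  The result is
    rounded to one decimal place.  Raises if the target is unreachable
    below ``or_cap``.
    """
    if not 0.0 < target < 1.0:
        if target == 0.0:
            return 1.0
        raise ValueError("target power must be in (0, 1)")

    def power_at(orr: float) -> float:
        rng = np.random.default_rng(seed)
        return cc_power(control_af, orr, cohort, alpha, n_sims=n_sims, rng=rng)

    lo, hi = 1.0, 2.0
    while power_at(hi) < target:
        lo, hi = hi, hi * 2.0
        if hi > or_cap:
            raise ValueError(f"target power {target} unreachable below OR {or_cap}")
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= target:
            hi = mid
        else:
            lo = mid
    return round(hi, 1)


# ---------------------------------------------------------------------------
# multiple testing

def effective_dataset_count(pvalues: Mapping[str, Sequence[float]] | pd.DataFrame,
                            sig_level: float = 0.05,
                            min_shared: int = 3) -> int:
    """Number of effectively independent datasets.

    Datasets (columns of aligned per-variant p-values) are joined into one
    component whenever their Spearman rank correlation is significant at
    ``sig_level``; the effective count is the number of connected
    components.  Pairs with fewer than ``min_shared`` jointly observed
    variants are skipped with a warning.
    """
    df = pd.DataFrame(dict(pvalues)) if not isinstance(pvalues, pd.DataFrame) else pvalues
    names = sorted(df.columns)
    if len(names) < 2:
        return len(names)
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = df[[a, b]].dropna()
            if len(pair) < min_shared:
                warnings.warn(f"datasets {a}/{b}: only {len(pair)} shared variants; skipped")
                continue
            rho, p = stats.spearmanr(pair[a], pair[b])
            if np.isfinite(p) and p < sig_level:
                parent[find(a)] = find(b)
    return len({find(n) for n in names})


def bonferroni_threshold(budget: TestBudget, family_alpha: float = 0.05) -> float:
    """family_alpha divided by the total test count."""
    if budget.total_tests < 1:
        raise ValueError("total test count must be >= 1")
    return family_alpha / budget.total_tests


def count_significant(min_pvalues: Mapping[str, float], alpha: float) -> tuple[int, list[str]]:
    """Variants whose minimum p-value is below *alpha*."""
    hits = sorted(k for k, p in min_pvalues.items() if p < alpha)
    return len(hits), hits


# ---------------------------------------------------------------------------
# CMC gene burden

def cmc_burden_test(dosages: np.ndarray, afs: Sequence[float], labels: np.ndarray,
                    pcs: np.ndarray, af_split: float = 0.01,
                    af_max: float = 0.05) -> tuple[float, float, Optional[str]]:
    """Combined multivariate and collapsing burden test for one gene.

    Variants (columns of the samples x variants dosage matrix, only
    damaging variants supplied) are collapsed into two per-sample carrier
    indicators by AF bin (< ``af_split``, and [``af_split``, ``af_max``)).
    A logistic model of case status on the indicators plus the first five
    ancestry PCs is compared against the PCs-only null by a log-likelihood
    ratio test (chi-square, one df per non-degenerate indicator).

    Returns (LLR, p, flag); with no carriers in either bin, p = 1.
    """
    import statsmodels.api as sm

    X = np.asarray(dosages, dtype=float)
    y = np.asarray(labels, dtype=float)
    afs = np.asarray(afs, dtype=float)
    if X.shape[1] != afs.size:
        raise ValueError("afs and dosage columns differ in length")
    very_rare = afs < af_split
    rare = (afs >= af_split) & (afs < af_max)
    ind = []
    for mask in (very_rare, rare):
        if mask.any():
            carrier = (np.nan_to_num(X[:, mask], nan=0.0) > 0).any(axis=1).astype(float)
            if 0 < carrier.sum() < len(carrier):
                ind.append(carrier)
    if not ind:
        return 0.0, 1.0, "no_carriers"

    base = sm.add_constant(np.asarray(pcs, dtype=float), has_constant="add")
    full = np.column_stack([base] + ind)
    flag = None

    def _penalized_llf(X: np.ndarray) -> float:
        # weak-ridge logistic fallback for separated / collinear designs
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000,
                                 fit_intercept=False)
        clf.fit(X, y)
        prob = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))

    try:
        with np.errstate(all="ignore"):
            ll0 = sm.Logit(y, base).fit(disp=0, maxiter=200).llf
            ll1 = sm.Logit(y, full).fit(disp=0, maxiter=200).llf
        if not (np.isfinite(ll0) and np.isfinite(ll1)):
            raise ValueError("non-finite log-likelihood")
    except Exception:
        flag = "separation"
        ll0 = _penalized_llf(base)
        ll1 = _penalized_llf(full)
    llr = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(llr, df=len(ind)))
    return float(llr), p, flag


def compare_af_distributions(afs_a: Sequence[float], afs_b: Sequence[float]) -> float:
    """Two-sided rank-sum p-value comparing two AF samples."""
    a = np.asarray(afs_a, dtype=float)
    b = np.asarray(afs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
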