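import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from famvar.model import Family, Individual, PedigreeError
from famvar.qc import (
    AncestryModel,
    KinshipBins,
    PCAProjector,
    QCThresholds,
    classify_kinship,
    fit_ancestry_ellipsoid,
    genotype_concordance,
    genotype_qc,
    hwe_chi2,
    infer_sex,
    pedigree_kinship,
    rank_proximal_controls,
    variant_qc,
)

from conftest import F, M, UNK, make_family, make_variant


class TestGenotypeQC:
    def test_perfect_het_passes(self):
        ok, reason = genotype_qc(1, 99, 10, 10)
        assert ok and reason is None

    def test_unbalanced_het_fails(self):
        # oracle: continuity-corrected chi-square of 20:1 against 1:1
        n, k = 21, 20
        stat = 2 * (abs(k - n / 2) - 0.5) ** 2 / (n / 2)
        assert stats.chi2.sf(stat, 1) < 0.001
        ok, reason = genotype_qc(1, 99, 1, 20)
        assert not ok and reason == "allele_balance"

    def test_low_alt_depth_hom(self):
        ok, reason = genotype_qc(2, 99, 0, 2)
        assert not ok and reason == "depth"

    def test_low_gq(self):
        assert genotype_qc(1, 29, 10, 10) == (False, "gq")
        assert genotype_qc(1, 30, 10, 10)[0]

    def test_missing_quality_passthrough_and_fail_modes(self):
        assert genotype_qc(1, -1, 10, 10)[0]
        strict = QCThresholds(missing_quality_fails=True)
        assert genotype_qc(1, -1, 10, 10, strict) == (False, "unevaluable")


class TestHWE:
    def test_exact_proportions(self):
        assert hwe_chi2(25, 50, 25) == pytest.approx(1.0)

    def test_no_hets_fails(self):
        # oracle: chi-square statistic equals n for (n/2, 0, n/2)
        obs = np.array([50.0, 0.0, 50.0])
        n = obs.sum()
        exp = np.array([0.25, 0.5, 0.25]) * n
        stat = ((obs - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(n)
        assert hwe_chi2(50, 0, 50) == pytest.approx(stats.chi2.sf(n, 1))
        assert hwe_chi2(50, 0, 50) < 5e-8

    def test_monomorphic_is_one(self):
        assert hwe_chi2(100, 0, 0) == 1.0
        assert hwe_chi2(0, 0, 100) == 1.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            hwe_chi2(0, 0, 0)


class TestVariantQC:
    def test_snp_tranche_boundary(self):
        v = make_variant([0, 1, 2, 0], vqsr_tranche=99.5)
        assert variant_qc(v)[0]
        v = make_variant([0, 1, 2, 0], vqsr_tranche=99.6)
        ok, reasons = variant_qc(v)
        assert not ok and reasons == ["tranche"]

    def test_indel_tranche(self):
        v = make_variant([0, 1, 2, 0], ref="A", alt="AT", vqsr_tranche=99.3)
        ok, reasons = variant_qc(v)
        assert not ok and "tranche" in reasons

    def test_call_rate(self):
        v = make_variant([0, 1] * 5 + [-1] * 10)
        ok, reasons = variant_qc(v)
        assert not ok and "call_rate" in reasons

    def test_monotone_in_thresholds(self):
        v = make_variant([0, 1, 2, -1], vqsr_tranche=99.4)
        strict = QCThresholds(min_call_rate=0.9, max_tranche_snp=99.0)
        relaxed = QCThresholds(min_call_rate=0.5, max_tranche_snp=99.5)
        assert not variant_qc(v, strict)[0]
        assert variant_qc(v, relaxed)[0]


class TestInferSex:
    def test_calls(self):
        assert infer_sex(0.99) == "male"
        assert infer_sex(0.65) == "female"
        assert infer_sex(0.85) == "ambiguous"

    def test_hwe_derived_female_rate(self, rng):
        # expected female hom rate at common X variants under HWE
        afs = rng.uniform(0.05, 0.5, size=500)
        hom = (1 - afs) ** 2 + afs ** 2
        assert infer_sex(float(hom.mean())) == "female"

    def test_too_few_variants(self):
        with pytest.raises(ValueError):
            infer_sex(0.9, n_variants=10)


class TestKinshipClassification:
    @pytest.mark.parametrize("phi,expected", [
        (0.40, "duplicate"),
        (0.25, "first"),
        (0.354, "first"),     # boundary: lower bound inclusive
        (0.12, "second"),
        (0.05, "third"),
        (0.01, "unrelated"),
        (-0.02, "unrelated"),
    ])
    def test_bins(self, phi, expected):
        assert classify_kinship(phi) == expected

    @given(st.floats(min_value=-0.5, max_value=0.5,
                     allow_nan=False, allow_infinity=False))
    def test_total_partition(self, phi):
        assert classify_kinship(phi) in {
            "duplicate", "first", "second", "third", "unrelated"}

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            KinshipBins(dup=0.1, first=0.2, second=0.05, third=0.01)


class TestPedigreeKinship:
    def test_parent_offspring(self, trio):
        phi = pedigree_kinship(trio)
        assert phi[("dad", "kid")] == pytest.approx(0.25)

    def test_full_and_half_sibs(self):
        fam = make_family("H", [
            ("d", None, None, M, UNK, True),
            ("m1", None, None, F, UNK, True),
            ("m2", None, None, F, UNK, True),
            ("s1", "d", "m1", M, UNK, True),
            ("s2", "d", "m1", M, UNK, True),
            ("h1", "d", "m2", M, UNK, True),
        ])
        phi = pedigree_kinship(fam)
        assert phi[("s1", "s2")] == pytest.approx(0.25)
        assert phi[("h1", "s1")] == pytest.approx(0.125)

    def test_first_cousins(self, three_gen):
        phi = pedigree_kinship(three_gen)
        assert phi[("c1", "c2")] == pytest.approx(0.0625)
        assert classify_kinship(0.0625) == "third"

    def test_self_kinship_founder(self, trio):
        phi = pedigree_kinship(trio)
        assert phi[("dad", "dad")] == pytest.approx(0.5)

    def test_cycle_raises(self):
        fam = Family("C")
        fam.add(Individual(id="x", family_id="C", father_id="y", mother_id="z"))
        fam.add(Individual(id="y", family_id="C", father_id="x", mother_id="z"))
        fam.add(Individual(id="z", family_id="C"))
        with pytest.raises(PedigreeError):
            pedigree_kinship(fam)

    def test_matches_gene_drop_ibd_sharing(self, three_gen, rng):
        # independent oracle: drop unique founder alleles, measure allele sharing
        n_reps = 20000
        founders = [m.id for m in three_gen.founders]
        order = [m for m in three_gen.topological_order() if not m.is_founder]
        labels = {}
        for i, fid in enumerate(founders):
            labels[fid] = np.stack([np.full(n_reps, 2 * i), np.full(n_reps, 2 * i + 1)])
        for m in order:
            pick_f = rng.integers(0, 2, n_reps)
            pick_m = rng.integers(0, 2, n_reps)
            labels[m.id] = np.stack([
                labels[m.father_id][pick_f, np.arange(n_reps)],
                labels[m.mother_id][pick_m, np.arange(n_reps)],
            ])
        phi = pedigree_kinship(three_gen)
        for a, b in [("c1", "c2"), ("p1", "c1"), ("p1", "p2")]:
            share = np.zeros(n_reps)
            for i in range(2):
                for j in range(2):
                    share += labels[a][i] == labels[b][j]
            est = share.mean() / 4.0
            expected = phi[(a, b) if a <= b else (b, a)]
            se = share.std() / 4.0 / np.sqrt(n_reps)
            assert abs(est - expected) < max(4 * se, 0.01)


class TestAncestryEllipsoid:
    def test_threshold_matches_chi2_quantile(self, rng):
        pts = rng.normal(size=(500, 5))
        model = fit_ancestry_ellipsoid(pts)
        assert model.d2_threshold == pytest.approx(stats.chi2.ppf(0.90, 5))

    def test_coverage_near_nominal(self, rng):
        mean = np.array([1.0, -2.0, 0.0, 3.0, 0.5])
        A = rng.normal(size=(5, 5)) * 0.3 + np.eye(5)
        train = rng.normal(size=(2000, 5)) @ A.T + mean
        model = fit_ancestry_ellipsoid(train)
        test = rng.normal(size=(4000, 5)) @ A.T + mean
        frac = model.contains(test).mean()
        se = np.sqrt(0.9 * 0.1 / 4000)
        assert abs(frac - 0.90) < 5 * se + 0.01

    def test_center_is_member(self, rng):
        pts = rng.normal(size=(100, 5))
        model = fit_ancestry_ellipsoid(pts)
        assert model.mahalanobis_sq(model.mean[None, :])[0] == pytest.approx(0.0)
        assert model.contains(model.mean[None, :])[0]

    def test_singular_covariance_raises(self):
        pts = np.zeros((50, 5))
        pts[:, 0] = np.arange(50)
        with pytest.raises(ValueError, match="fewer PCs|singular"):
            fit_ancestry_ellipsoid(pts)

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError):
            fit_ancestry_ellipsoid(rng.normal(size=(4, 5)))


class TestProximalControls:
    def test_center_candidate_first(self, rng):
        pts = rng.normal(size=(200, 5))
        model = fit_ancestry_ellipsoid(pts)
        cands = rng.normal(size=(50, 5)) * 3
        cands[17] = model.mean
        ids = [f"c{i}" for i in range(50)]
        ranked = rank_proximal_controls(model, cands, ids, k=10)
        assert ranked[0] == "c17"

    def test_k_equals_n_is_permutation(self, rng):
        pts = rng.normal(size=(100, 5))
        model = fit_ancestry_ellipsoid(pts)
        cands = rng.normal(size=(30, 5))
        ids = [f"c{i}" for i in range(30)]
        assert sorted(rank_proximal_controls(model, cands, ids, k=30)) == sorted(ids)

    def test_k_exceeding_n_warns(self, rng):
        pts = rng.normal(size=(100, 5))
        model = fit_ancestry_ellipsoid(pts)
        with pytest.warns(UserWarning):
            out = rank_proximal_controls(model, rng.normal(size=(5, 5)),
                                         list("abcde"), k=10)
        assert len(out) == 5

    def test_mixture_label_recovery(self, rng):
        # two well-separated Gaussians; selection should favor the fitted one
        comp_a = rng.normal(0, 1, size=(300, 5))
        comp_b = rng.normal(8, 1, size=(300, 5))
        model = fit_ancestry_ellipsoid(comp_a)
        cands = np.vstack([comp_a + rng.normal(0, 0.1, comp_a.shape), comp_b])
        ids = [f"a{i}" for i in range(300)] + [f"b{i}" for i in range(300)]
        chosen = rank_proximal_controls(model, cands, ids, k=300)
        frac_a = sum(1 for c in chosen if c.startswith("a")) / 300
        assert frac_a > 0.95


class TestConcordance:
    def test_identical(self):
        assert genotype_concordance([0, 1, 2, 1], [0, 1, 2, 1]) == 1.0

    def test_998(self):
        a = [0] * 500
        b = [0] * 499 + [1]
        assert genotype_concordance(a, b) == pytest.approx(0.998)

    def test_missing_excluded_pairwise(self):
        assert genotype_concordance([0, -1, 2], [0, 1, -1]) == 1.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            genotype_concordance([-1, -1], [0, 1])


class TestPCAProjector:
    def test_projection_consistency(self, rng):
        X = rng.binomial(2, 0.3, size=(80, 40)).astype(float)
        proj = PCAProjector(5).fit(X)
        direct = proj.transform(X)
        again = proj.transform(X[:10])
        np.testing.assert_allclose(direct[:10], again)
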