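import itertools

import numpy as np
import pytest

from famvar.familyprior import (
    InconsistentPedigreeError,
    conditional_unaffected_prob,
    eligible_unaffecteds,
    family_carrier_fraction,
    prioritize_rare_family_variants,
    segregation_filter,
    segregation_power,
    select_lfams,
)
from famvar.model import Cohort

from conftest import CD, F, M, UC, UNAFF, UNK, make_family, make_variant


def lfam(fid="L1", n_cd=4, n_uc=0, n_unaff=0):
    rows = [("d", None, None, M, UNK, False), ("m", None, None, F, UNK, False)]
    for i in range(n_cd):
        rows.append((f"cd{i}", "d", "m", M, CD, True))
    for i in range(n_uc):
        rows.append((f"uc{i}", "d", "m", F, UC, True))
    for i in range(n_unaff):
        rows.append((f"u{i}", "d", "m", M, UNAFF, True))
    return make_family(fid, rows)


class TestSelectLfams:
    def test_four_cd_is_both(self):
        cohort = Cohort([lfam(n_cd=4)])
        assert len(select_lfams(cohort, "CD")) == 1
        assert len(select_lfams(cohort, "IBD")) == 1

    def test_mixed_subtypes_ibd_only(self):
        cohort = Cohort([lfam(n_cd=2, n_uc=2)])
        assert select_lfams(cohort, "CD") == []
        assert len(select_lfams(cohort, "IBD")) == 1

    def test_three_affecteds_neither(self):
        cohort = Cohort([lfam(n_cd=3)])
        assert select_lfams(cohort, "CD") == []
        assert select_lfams(cohort, "IBD") == []

    def test_unsequenced_affecteds_not_counted(self):
        fam = lfam(n_cd=3)
        fam.add(type(fam["cd0"])(id="cd9", family_id=fam.id, father_id="d",
                                 mother_id="m", sex=M, phenotype=CD,
                                 sequenced=False))
        assert select_lfams(Cohort([fam]), "CD") == []


class TestCarrierFraction:
    def family_with_carriers(self, n_affected, n_carriers):
        fam = lfam(n_cd=n_affected)
        samples = [f"cd{i}" for i in range(n_affected)]
        dosages = [1] * n_carriers + [0] * (n_affected - n_carriers)
        return fam, make_variant(dosages, samples=samples)

    @pytest.mark.parametrize("n_aff,n_car,passes", [
        (8, 6, True),   # exactly 0.75
        (5, 4, True),   # 0.8
        (4, 2, False),  # 0.5
        (4, 3, True),
    ])
    def test_thresholds(self, n_aff, n_car, passes):
        fam, v = self.family_with_carriers(n_aff, n_car)
        res = family_carrier_fraction(v, fam, "CD")
        assert res.fraction == pytest.approx(n_car / n_aff)
        assert res.passes_75 is passes

    def test_missing_genotype_excluded_from_denominator(self):
        fam, v = self.family_with_carriers(5, 4)
        v.dosages[4] = -1  # the non-carrier becomes missing
        res = family_carrier_fraction(v, fam, "CD")
        assert (res.n_affected_carriers, res.n_affected) == (4, 4)
        assert "affected_genotype_missing" in v.flags

    def test_monotone_adding_carrier(self):
        fam, v = self.family_with_carriers(8, 6)
        assert family_carrier_fraction(v, fam, "CD").passes_75
        v.dosages[6] = 1
        assert family_carrier_fraction(v, fam, "CD").passes_75

    def test_zero_evaluable_raises(self):
        fam, v = self.family_with_carriers(4, 2)
        v.dosages[:] = -1
        with pytest.raises(ValueError):
            family_carrier_fraction(v, fam, "CD")


class TestPrioritize:
    def make(self, af, carol="damaging", cadd=30.0, carriers=3, n_affected=4):
        fam = lfam(n_cd=n_affected)
        samples = [f"cd{i}" for i in range(n_affected)]
        v = make_variant([1] * carriers + [0] * (n_affected - carriers),
                         samples=samples, af_aj=af)
        from famvar.model import Consequence

        v.consequence = Consequence.MISSENSE
        v.carol = carol
        v.cadd = cadd
        v.gene = "G"
        return fam, v

    def test_passing_variant_included(self):
        fam, v = self.make(0.004)
        out = prioritize_rare_family_variants([v], [fam], "CD")
        assert len(out) == 1 and out.iloc[0]["n_lfams"] == 1

    def test_af_boundary_excluded(self):
        fam, v = self.make(0.01)
        assert prioritize_rare_family_variants([v], [fam], "CD").empty

    def test_not_damaging_excluded(self):
        fam, v = self.make(0.004, carol="benign")
        assert prioritize_rare_family_variants([v], [fam], "CD").empty

    def test_two_lfams_reported_once(self):
        fam1, _ = self.make(0.004)
        fam2 = lfam("L2", n_cd=4)
        samples = [f"cd{i}" for i in range(4)]
        v = make_variant([1, 1, 1, 0], samples=samples, af_aj=0.004)
        from famvar.model import Consequence

        v.consequence = Consequence.FRAMESHIFT
        v.gene = "G"
        # same sample ids serve both families here
        out = prioritize_rare_family_variants([v], [fam1, fam2], "CD")
        assert len(out) == 1
        assert out.iloc[0]["n_lfams"] == 2


class TestEligibleUnaffecteds:
    def test_parents_of_affected_excluded(self):
        fam = make_family("E1", [
            ("gp", None, None, M, UNK, True),
            ("gm", None, None, F, UNK, True),
            ("aff", "gp", "gm", M, CD, True),
            ("sib", "gp", "gm", F, UNAFF, True),
            ("spouse", None, None, F, UNAFF, True),
            ("child", "aff", "spouse", M, UNAFF, True),
        ])
        assert eligible_unaffecteds(fam, "IBD") == ["child", "sib"]

    def test_unrelated_unaffected_excluded(self):
        fam = make_family("E2", [
            ("d", None, None, M, UNK, False),
            ("m", None, None, F, UNK, False),
            ("aff", "d", "m", M, CD, True),
            ("inlaw", None, None, F, UNAFF, True),
        ])
        assert eligible_unaffecteds(fam, "IBD") == []


class TestSegregationFilter:
    def family(self, n_unaffected):
        rows = [("d", None, None, M, CD, True), ("m", None, None, F, UNAFF, False)]
        for i in range(n_unaffected):
            rows.append((f"u{i}", "d", "m", M, UNAFF, True))
        return make_family("SF", rows)

    def variant(self, fam, carriers):
        samples = [m.id for m in fam if m.sequenced]
        return make_variant([1 if s in carriers else 0 for s in samples],
                            samples=samples)

    @pytest.mark.parametrize("n_unaff,n_carr,passes", [
        (5, 1, True),
        (9, 3, True),   # exactly 1/3 passes (inclusive rule)
        (5, 2, False),  # 0.4
        (2, 0, True),
        (3, 1, True),
    ])
    def test_third_rule(self, n_unaff, n_carr, passes):
        fam = self.family(n_unaff)
        v = self.variant(fam, {f"u{i}" for i in range(n_carr)})
        res = segregation_filter(v, fam, "IBD")
        assert res is not None
        assert res.passes_third is passes

    def test_too_few_unaffecteds_skipped(self):
        fam = self.family(1)
        v = self.variant(fam, set())
        assert segregation_filter(v, fam, "IBD") is None


class TestConditionalProb:
    def test_single_unaffected_noncarrier(self):
        fam = make_family("C1", [
            ("aff", None, None, M, CD, True),
            ("sp", None, None, F, UNAFF, True),
            ("u1", "aff", "sp", M, UNAFF, True),
        ])
        p = conditional_unaffected_prob(fam, {"aff": 1}, {"u1": 0})
        assert p == pytest.approx(0.5)

    def test_two_unaffected_noncarriers(self):
        fam = make_family("C2", [
            ("aff", None, None, M, CD, True),
            ("sp", None, None, F, UNAFF, True),
            ("u1", "aff", "sp", M, UNAFF, True),
            ("u2", "aff", "sp", F, UNAFF, True),
        ])
        p = conditional_unaffected_prob(fam, {"aff": 1}, {"u1": 0, "u2": 0})
        assert p == pytest.approx(0.25)

    def test_sums_to_one_over_unaffected_vectors(self, three_gen):
        affected = {"p1": 1, "c1": 1, "c2": 1}
        unaff_ids = ["p2", "s1"]
        total = 0.0
        for combo in itertools.product([0, 1], repeat=len(unaff_ids)):
            total += conditional_unaffected_prob(
                three_gen, affected, dict(zip(unaff_ids, combo)))
        assert total == pytest.approx(1.0)

    def test_inconsistent_raises(self):
        # two carriers in disjoint founder lineages: no single carrier founder
        fam = make_family("C3", [
            ("d1", None, None, M, UNK, True),
            ("m1", None, None, F, UNK, True),
            ("d2", None, None, M, UNK, True),
            ("m2", None, None, F, UNK, True),
            ("k1", "d1", "m1", M, CD, True),
            ("k2", "d2", "m2", M, CD, True),
        ])
        with pytest.raises(InconsistentPedigreeError):
            conditional_unaffected_prob(fam, {"k1": 1, "k2": 1, "d1": 0, "m1": 0,
                                              "d2": 0, "m2": 0}, {})

    def test_hom_observation_rejected(self, trio):
        with pytest.raises(ValueError):
            conditional_unaffected_prob(trio, {"kid": 2}, {})

    def test_matches_enumeration_oracle(self, three_gen):
        # oracle: enumerate founder origin x all 4^k meiosis outcomes on
        # allele labels, independent of the implementation's recursion
        fam = three_gen
        founders = [m.id for m in fam.founders]
        nonfounders = [m for m in fam.topological_order() if not m.is_founder]
        affected = {"p1": 1, "c1": 1}
        unaffected = {"c2": 0, "p2": 0}

        def oracle(obs):
            total = 0.0
            for carrier in founders:
                alleles = {f: ("V", "r") if f == carrier else ("r", "r")
                           for f in founders}
                for picks in itertools.product([0, 1], repeat=2 * len(nonfounders)):
                    a = dict(alleles)
                    for i, m in enumerate(nonfounders):
                        a[m.id] = (a[m.father_id][picks[2 * i]],
                                   a[m.mother_id][picks[2 * i + 1]])
                    ok = all(
                        (a[iid].count("V")) == d for iid, d in obs.items()
                    )
                    if ok:
                        total += (0.25) ** len(nonfounders)
            return total / len(founders)

        expected = oracle({**affected, **unaffected}) / oracle(affected)
        got = conditional_unaffected_prob(fam, affected, unaffected)
        assert got == pytest.approx(expected)

    def test_matches_rejection_sampling(self, rng):
        # forward gene-drop conditioned by rejection on the affected genotypes
        fam = make_family("R1", [
            ("d", None, None, M, UNK, True),
            ("m", None, None, F, UNK, True),
            ("a1", "d", "m", M, CD, True),
            ("a2", "d", "m", F, CD, True),
            ("u1", "d", "m", M, UNAFF, True),
            ("u2", "d", "m", F, UNAFF, True),
        ])
        affected = {"a1": 1, "a2": 1}
        unaffected = {"u1": 0, "u2": 1}
        founders = [m.id for m in fam.founders]
        nonf = [m for m in fam.topological_order() if not m.is_founder]
        n = 200_000
        carrier = rng.choice(len(founders), size=n)
        dos = {f: (carrier == i).astype(int) for i, f in enumerate(founders)}
        for m in nonf:
            t_f = (rng.random(n) < dos[m.father_id] / 2).astype(int)
            t_m = (rng.random(n) < dos[m.mother_id] / 2).astype(int)
            dos[m.id] = t_f + t_m
        cond = np.ones(n, dtype=bool)
        for iid, d in affected.items():
            cond &= dos[iid] == d
        match = cond.copy()
        for iid, d in unaffected.items():
            match &= dos[iid] == d
        mc = match.sum() / cond.sum()
        exact = conditional_unaffected_prob(fam, affected, unaffected)
        se = np.sqrt(exact * (1 - exact) / cond.sum())
        assert abs(mc - exact) < 4 * se + 1e-3


class TestSegregationPower:
    def test_two_meioses_no_power(self):
        fam = make_family("P1", [
            ("aff", None, None, M, CD, True),
            ("sp", None, None, F, UNAFF, True),
            ("u1", "aff", "sp", M, UNAFF, True),
            ("u2", "aff", "sp", F, UNAFF, True),
        ])
        assert not segregation_power(fam, {"aff": 1}, ["u1", "u2"])

    def test_five_meioses_has_power(self):
        rows = [("aff", None, None, M, CD, True), ("sp", None, None, F, UNAFF, True)]
        rows += [(f"u{i}", "aff", "sp", M, UNAFF, True) for i in range(5)]
        fam = make_family("P2", rows)
        # minimal achievable probability is 2^-5 = 0.03125 < 0.05
        assert segregation_power(fam, {"aff": 1}, [f"u{i}" for i in range(5)])
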