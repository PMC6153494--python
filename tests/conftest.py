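import numpy as np
import pytest

from famvar.model import Cohort, Family, Individual, Phenotype, Sex, VariantRecord


def make_family(fid, rows):
    """rows: (iid, father, mother, sex, phenotype, sequenced)."""
    fam = Family(fid)
    for iid, father, mother, sex, phen, seq in rows:
        fam.add(Individual(
            id=iid, family_id=fid, father_id=father, mother_id=mother,
            sex=sex, phenotype=phen, sequenced=seq,
        ))
    fam.validate()
    return fam


M, F, U = Sex.MALE, Sex.FEMALE, Sex.UNKNOWN
CD, UC, IBDU = Phenotype.CD, Phenotype.UC, Phenotype.IBDU
UNAFF, UNK = Phenotype.UNAFFECTED, Phenotype.UNKNOWN


@pytest.fixture
def trio():
    return make_family("T1", [
        ("dad", None, None, M, UNAFF, True),
        ("mum", None, None, F, UNAFF, True),
        ("kid", "dad", "mum", M, CD, True),
    ])


@pytest.fixture
def sib_family():
    """Two CD-affected sibs, one unaffected sib."""
    return make_family("S1", [
        ("dad", None, None, M, UNK, True),
        ("mum", None, None, F, UNK, True),
        ("a1", "dad", "mum", M, CD, True),
        ("a2", "dad", "mum", F, CD, True),
        ("u1", "dad", "mum", M, UNAFF, True),
    ])


@pytest.fixture
def three_gen():
    """Grandparents -> two sibs (one married in) -> cousins."""
    return make_family("G1", [
        ("gp1", None, None, M, UNK, False),
        ("gm1", None, None, F, UNK, False),
        ("p1", "gp1", "gm1", M, CD, True),
        ("p2", "gp1", "gm1", F, UNAFF, True),
        ("s1", None, None, F, UNAFF, True),
        ("s2", None, None, M, UNAFF, True),
        ("c1", "p1", "s1", M, CD, True),
        ("c2", "p2", "s2", F, CD, True),
    ])


def make_variant(dosages, samples=None, gq=99, ad=None, **kwargs):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.size
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    gq_arr = np.full(n, gq, dtype=np.int32)
    if ad is None:
        ad_ref = np.where(dosages == 2, 0, 20).astype(np.int32)
        ad_alt = np.where(dosages == 0, 0, 20).astype(np.int32)
    else:
        ad_ref = np.asarray([a[0] for a in ad], dtype=np.int32)
        ad_alt = np.asarray([a[1] for a in ad], dtype=np.int32)
    defaults = dict(chrom="1", pos=1000, ref="A", alt="G")
    defaults.update(kwargs)
    return VariantRecord(samples=list(samples), dosages=dosages, gq=gq_arr,
                         ad_ref=ad_ref, ad_alt=ad_alt, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten small families with sequenced affecteds, for gene-drop tests."""
    cohort = Cohort()
    for i in range(10):
        fid = f"F{i}"
        cohort.add_family(make_family(fid, [
            (f"{fid}_d", None, None, M, UNK, False),
            (f"{fid}_m", None, None, F, UNK, False),
            (f"{fid}_a1", f"{fid}_d", f"{fid}_m", M, CD, True),
            (f"{fid}_a2", f"{fid}_d", f"{fid}_m", F, UC, True),
            (f"{fid}_u1", f"{fid}_d", f"{fid}_m", M, UNAFF, True),
        ]))
    return cohort
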