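import numpy as np
import pytest

from famvar.cohort import FOUNDER, Individual, Pedigree, PhenotypeClass, VariantRecord


def make_individual(iid, fid="FAM", father=FOUNDER, mother=FOUNDER, sex="unknown",
                    pheno=PhenotypeClass.UNKNOWN, obligate=False, age=None,
                    sequenced=True):
    return Individual(
        individual_id=iid, family_id=fid, father_id=father, mother_id=mother,
        sex=sex, phenotype_class=pheno, obligate_carrier=obligate,
        screening_age=age, sequenced=sequenced,
    )


def make_pedigree(fid, members):
    ped = Pedigree(family_id=fid)
    for m in members:
        ped.add(m)
    return ped


@pytest.fixture
def trio_pedigree():
    """Affected parent, untyped spouse, two affected children."""
    return make_pedigree(
        "T",
        [
            make_individual("P", "T", sex="male", pheno=PhenotypeClass.DEFINITE_IA),
            make_individual("S", "T", sex="female", sequenced=False),
            make_individual("C1", "T", father="P", mother="S",
                            pheno=PhenotypeClass.DEFINITE_IA),
            make_individual("C2", "T", father="P", mother="S",
                            pheno=PhenotypeClass.DEFINITE_IA),
        ],
    )


@pytest.fixture
def family_d_like():
    """Three definite cases plus one possible-IA sibling (non-carrier), an
    obligate carrier, and one screened unaffected."""
    return make_pedigree(
        "D",
        [
            make_individual("GP", "D", sex="male", pheno=PhenotypeClass.DEFINITE_IA),
            make_individual("GM", "D", sex="female", sequenced=False),
            make_individual("P1", "D", father="GP", mother="GM", sex="female",
                            obligate=True, age=64),
            make_individual("P2", "D", father="GP", mother="GM", sex="male",
                            pheno=PhenotypeClass.DEFINITE_IA),
            make_individual("S1", "D", sex="male", sequenced=False),
            make_individual("C1", "D", father="S1", mother="P1",
                            pheno=PhenotypeClass.DEFINITE_IA),
            make_individual("C11", "D", father="S1", mother="P1",
                            pheno=PhenotypeClass.POSSIBLE_IA),
            make_individual("U1", "D", father="S1", mother="P1",
                            pheno=PhenotypeClass.UNAFFECTED_SCREENED, age=52),
        ],
    )


def variant_with(genotypes, chrom="1", pos=1000, ref="G", alt="A"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=genotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
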